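"""Embedding geometry: PCA views, hyper circle fit, anatomical alignment and
the Fisher-Lee circular correlation."""

import numpy as np
import pandas as pd
import pytest
from scipy.optimize import least_squares
from scipy.signal import medfilt

import ringcompass as rc
from ringcompass.core import TraceMatrix, circular_distance, wrap_angle
from ringcompass.rpcspace import (
    align_embedding,
    anatomy_stats,
    fisher_lee_correlation,
    fit_circle,
    pca_neuron_embedding,
    pca_state_space,
)


def _ring_traces(n=24, frames=500, phase=None):
    alpha = wrap_angle(2 * np.pi * np.arange(n) / n)
    if phase is None:
        phase = np.linspace(-np.pi, np.pi, frames, endpoint=False)
    values = 0.5 * (1 + np.cos(phase[None, :] - alpha[:, None]))
    return TraceMatrix(values, 5.0, np.arange(n)), alpha, phase


class TestStateSpacePCA:
    def test_rank2_signal_fully_captured(self):
        traces, _, _ = _ring_traces()
        _, evr = pca_state_space(traces, k=2)
        assert evr.sum() == pytest.approx(1.0, abs=1e-9)

    def test_noise_roi_lowers_but_does_not_zero(self):
        traces, _, _ = _ring_traces()
        rng = np.random.default_rng(0)
        noisy = TraceMatrix(
            np.vstack([traces.values, rng.normal(0, 0.5, traces.n_frames)]),
            5.0,
            np.arange(traces.n_rois + 1),
        )
        _, evr = pca_state_space(noisy, k=2)
        assert 0.5 < evr.sum() < 1.0

    def test_variance_fraction_matches_noise_budget(self, compact_session, compact_params):
        """On preprocessed default-noise traces the two-component variance
        matches the signal/(signal+noise) prediction from the known noise."""
        p = compact_params
        # noiseless twin of the same session gives the per-ROI signal power
        twin = rc.simulate_session(
            rc.SessionParams(**{**p.__dict__, "noise_sd": 0.0})
        )
        ring_rows = compact_session.rois.is_ring.to_numpy()
        signal = medfilt(twin.traces.values[ring_rows], (1, 3))
        sig_var = signal.var(axis=1)
        rng = np.random.default_rng(1)
        noise_var = medfilt(
            rng.normal(0, p.noise_sd, (200, 3000)), (1, 3)
        ).var()
        predicted = np.mean(sig_var / (sig_var + noise_var))
        ring_ids = compact_session.rois.roi_id[ring_rows].to_numpy()
        traces = rc.traceprep.preprocess(compact_session.raw).subset(ring_ids)
        _, evr = pca_state_space(traces, k=2)
        assert abs(evr.sum() - predicted) < 0.03

    def test_too_few_rois_rejected(self):
        with pytest.raises(ValueError):
            pca_state_space(TraceMatrix(np.ones((1, 10)), 5.0, [0]), k=2)


class TestNeuronEmbedding:
    def test_uniform_ring_maps_to_circle(self):
        traces, _, _ = _ring_traces()
        coords, evr = pca_neuron_embedding(traces)
        radii = np.hypot(*coords.T)
        assert radii.std() / radii.mean() < 1e-6
        assert evr.sum() == pytest.approx(1.0, abs=1e-9)

    def test_duplicated_roi_coincides(self):
        traces, _, _ = _ring_traces()
        dup = TraceMatrix(
            np.vstack([traces.values, traces.values[3]]),
            5.0,
            np.arange(traces.n_rois + 1),
        )
        coords, _ = pca_neuron_embedding(dup)
        assert np.allclose(coords[3], coords[-1], atol=1e-9)

    def test_synthetic_default_radial_cv(self, compact_result):
        emb = compact_result["embedding"]["embedding"]
        radii = np.hypot(*emb.coords.T)
        assert radii.std() / radii.mean() < 0.15


class TestCircleFit:
    def test_exact_circle_recovered(self):
        theta = np.linspace(0, 2 * np.pi, 40, endpoint=False)
        pts = np.column_stack([2 + 3 * np.cos(theta), -1 + 3 * np.sin(theta)])
        fit = fit_circle(pts)
        assert np.allclose(fit.center, [2, -1], atol=1e-9)
        assert fit.radius == pytest.approx(3.0, abs=1e-9)

    def test_rotation_equivariance(self):
        theta = np.linspace(0, 2 * np.pi, 25, endpoint=False)
        pts = np.column_stack([2 + 3 * np.cos(theta), -1 + 3 * np.sin(theta)])
        rot = np.deg2rad(30)
        R = np.array([[np.cos(rot), -np.sin(rot)], [np.sin(rot), np.cos(rot)]])
        fit = fit_circle(pts @ R.T)
        assert np.allclose(fit.center, R @ np.array([2, -1]), atol=1e-9)
        assert fit.radius == pytest.approx(3.0, abs=1e-9)

    def test_noisy_circle_matches_geometric_oracle(self):
        """Hyper algebraic fit agrees with iterative geometric least squares
        on noisy circles (center error < 0.02 r)."""
        rng = np.random.default_rng(0)
        for _ in range(50):
            r = rng.uniform(1, 5)
            c = rng.uniform(-3, 3, 2)
            theta = rng.uniform(0, 2 * np.pi, 100)
            pts = c + np.column_stack(
                [r * np.cos(theta), r * np.sin(theta)]
            ) + rng.normal(0, 0.05 * r, (100, 2))

            def geo_residual(p):
                return np.hypot(pts[:, 0] - p[0], pts[:, 1] - p[1]) - p[2]

            oracle = least_squares(
                geo_residual, x0=[*pts.mean(0), np.hypot(*pts.std(0))]
            ).x
            fit = fit_circle(pts)
            assert np.hypot(*(fit.center - oracle[:2])) < 0.02 * r
            assert abs(fit.radius - oracle[2]) < 0.02 * r

    def test_collinear_points_rejected(self):
        pts = np.column_stack([np.arange(5.0), 2 * np.arange(5.0)])
        with pytest.raises(ValueError, match="collinear"):
            fit_circle(pts)


def _ring_rois(alpha, radius=50.0):
    return pd.DataFrame(
        {
            "roi_id": np.arange(alpha.size),
            "x_lr": radius * np.sin(alpha),
            "y_rc": -radius * np.cos(alpha),
            "z": np.zeros(alpha.size),
        }
    )


class TestAlignment:
    def setup_method(self):
        self.alpha = wrap_angle(2 * np.pi * np.arange(32) / 32)
        self.coords = np.column_stack(
            [np.cos(self.alpha), np.sin(self.alpha)]
        )
        self.rois = _ring_rois(self.alpha)

    def test_aligned_embedding_is_identity(self):
        emb = align_embedding(self.coords, self.rois)
        assert abs(emb.transform["rotation_rad"]) < np.deg2rad(0.11)
        assert not emb.transform["reflected"]
        assert max(emb.anchor_angles) < np.deg2rad(0.2)
        assert np.abs(circular_distance(emb.alpha, self.alpha)).max() < 0.01

    def test_rotation_recovered(self):
        rot = np.deg2rad(30)
        R = np.array([[np.cos(rot), -np.sin(rot)], [np.sin(rot), np.cos(rot)]])
        emb = align_embedding(self.coords @ R.T, self.rois)
        assert emb.transform["rotation_rad"] == pytest.approx(
            -rot, abs=np.deg2rad(0.11)
        )
        assert np.abs(circular_distance(emb.alpha, self.alpha)).max() < 0.01

    def test_reflection_detected(self):
        mirrored = self.coords.copy()
        mirrored[:, 1] *= -1
        emb = align_embedding(mirrored, self.rois)
        assert emb.transform["reflected"]
        assert np.abs(circular_distance(emb.alpha, self.alpha)).max() < 0.01

    def test_anatomy_rotation_equivariance(self):
        """Rotating the ROI anatomy about the vertical axis by delta rotates
        the assigned alpha by delta (the anatomical angle convention is
        clockwise-positive viewed from above)."""
        delta = np.deg2rad(40)
        rois = self.rois.copy()
        x, y = rois.x_lr.to_numpy(), rois.y_rc.to_numpy()
        # clockwise-from-above anatomy rotation by delta: theta -> theta +
        # delta, which in the (x_lr, y_rc) plane is the standard rotation
        rois["x_lr"] = np.cos(delta) * x - np.sin(delta) * y
        rois["y_rc"] = np.sin(delta) * x + np.cos(delta) * y
        emb = align_embedding(self.coords, rois)
        shift = circular_distance(emb.alpha, self.alpha)
        assert np.allclose(shift, shift[0], atol=1e-6)
        assert abs(circular_distance(shift[0], delta)) < np.deg2rad(0.2)

    def test_unpolarized_anatomy_rejected(self):
        rois = self.rois.copy()
        rois["x_lr"] = 0.0
        rois["y_rc"] = 0.0
        with pytest.raises(ValueError, match="unpolarized"):
            align_embedding(self.coords, rois)

    def test_normalized_output_circle(self, compact_result):
        emb = compact_result["embedding"]["embedding"]
        fit = fit_circle(emb.coords)
        assert np.hypot(*fit.center) < 0.02
        assert abs(fit.radius - 1.0) < 0.02


def _fisher_lee_bruteforce(theta, phi):
    n = len(theta)
    num = den_t = den_p = 0.0
    for i in range(n):
        for j in range(i + 1, n):
            st, sp = np.sin(theta[i] - theta[j]), np.sin(phi[i] - phi[j])
            num += st * sp
            den_t += st * st
            den_p += sp * sp
    return num / np.sqrt(den_t * den_p)


class TestFisherLee:
    def test_identity_gives_one(self):
        theta = np.linspace(-3, 3, 40)
        assert fisher_lee_correlation(theta, theta) == pytest.approx(1.0)

    def test_matches_bruteforce_on_random_sets(self):
        rng = np.random.default_rng(5)
        for _ in range(20):
            n = rng.integers(8, 40)
            theta = rng.uniform(-np.pi, np.pi, n)
            phi = rng.uniform(-np.pi, np.pi, n)
            assert fisher_lee_correlation(theta, phi) == pytest.approx(
                _fisher_lee_bruteforce(theta, phi), abs=1e-12
            )

    def test_null_distribution_is_small(self):
        rng = np.random.default_rng(6)
        hits = 0
        for _ in range(20):
            theta = rng.uniform(-np.pi, np.pi, 200)
            phi = rng.uniform(-np.pi, np.pi, 200)
            if abs(fisher_lee_correlation(theta, phi)) < 0.2:
                hits += 1
        assert hits >= 18


class TestAnatomyStats:
    def test_perfect_ring_is_organized(self):
        alpha = wrap_angle(2 * np.pi * np.arange(40) / 40)
        rois = _ring_rois(alpha)
        emb = align_embedding(
            np.column_stack([np.cos(alpha), np.sin(alpha)]), rois
        )
        stats = anatomy_stats(emb, rois, n_shuffles=100,
                              rng=np.random.default_rng(0))
        assert stats.rho_t > 0.999
        for axis in ("x_lr", "y_rc"):
            assert (
                stats.sinusoid_fit_residuals[axis]
                < np.percentile(stats.shuffle_residuals[axis], 1)
            )
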