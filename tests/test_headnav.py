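"""Heading integration, coupling statistics, triggered dynamics, regressors."""

import itertools

import numpy as np
import pytest
from scipy.stats import rankdata

import ringcompass as rc
from ringcompass.core import HeadingTrace, PhaseTrace, SwimEvent
from ringcompass.headnav import (
    build_regressors,
    classify_motor_rois,
    compare_conditions,
    crossval_phase_regression,
    integrate_heading,
    phase_heading_coupling,
    phase_occupancy_at_swims,
    triggered_average,
    window_delta_regression,
)


def _phase(unwrapped, rate=5.0):
    unwrapped = np.asarray(unwrapped, float)
    return PhaseTrace(
        wrapped=rc.core.wrap_angle(unwrapped),
        unwrapped=unwrapped,
        vector_norm=np.ones_like(unwrapped),
        rate=rate,
    )


def _events(onsets, lateralities, cls=None):
    out = []
    for k, (t, lat) in enumerate(zip(onsets, lateralities)):
        out.append(
            SwimEvent(
                onset_s=t, offset_s=t + 0.2, laterality=lat,
                swim_class=cls[k] if cls else None,
            )
        )
    return out


class TestIntegrateHeading:
    def test_no_events_constant_zero(self):
        h = integrate_heading([], 400.0, 10.0)
        assert np.all(h.heading == 0)

    def test_telescoping_swims_cancel(self):
        ev = _events([1.0, 5.0], [0.5, -0.5])
        h = integrate_heading(ev, 400.0, 10.0)
        assert h.heading[-1] == pytest.approx(0.0)
        assert h.heading[int(2 * 400)] == pytest.approx(0.5)

    def test_linearity_and_permutation_invariance(self):
        lats = [0.3, -0.2, 0.7, 0.1]
        ev1 = _events([1, 2, 3, 4], lats)
        ev2 = _events([1, 2, 3, 4], lats[::-1])
        h1 = integrate_heading(ev1, 400.0, 6.0)
        h2 = integrate_heading(ev2, 400.0, 6.0)
        assert h1.heading[-1] == pytest.approx(h2.heading[-1])
        assert h1.heading[-1] == pytest.approx(sum(lats))


class TestCoupling:
    def test_perfect_anticorrelation(self):
        rng = np.random.default_rng(0)
        h = np.cumsum(rng.normal(0, 0.1, 3000))
        phase = _phase(-h)
        heading = HeadingTrace(h, 5.0)
        res = phase_heading_coupling(
            phase, heading, rng=np.random.default_rng(1)
        )
        assert np.allclose(res.window_correlations, -1.0, atol=1e-9)
        assert res.p_value < 0.05

    def test_session_shorter_than_window_rejected(self):
        with pytest.raises(ValueError, match="window"):
            phase_heading_coupling(
                _phase(np.zeros(100)), HeadingTrace(np.zeros(100), 5.0)
            )

    def test_independent_walks_mostly_non_significant(self):
        """Independent phase/heading random walks compared with the
        conservative non-overlapping window variant are usually
        indistinguishable from the epoch shuffle."""
        rng = np.random.default_rng(2)
        non_sig = 0
        n_runs = 12
        for k in range(n_runs):
            phase = _phase(np.cumsum(rng.normal(0, 0.1, 36_000)))
            heading = HeadingTrace(np.cumsum(rng.normal(0, 0.1, 36_000)), 5.0)
            res = phase_heading_coupling(
                phase, heading, window_step_s=300.0,
                rng=np.random.default_rng(k),
            )
            non_sig += res.p_value > 0.05
        assert non_sig >= 9


class TestTriggeredAverage:
    def test_constant_phase_gives_zero_curve(self):
        ev = _events([60, 120, 180], [0.5] * 3, cls=["left"] * 3)
        out = triggered_average(_phase(np.full(2000, 3.0)), ev)
        assert np.allclose(out["left"].mean, 0.0)
        assert out["left"].n_events == 3

    def test_step_phase_plateaus_at_step_size(self):
        rate, delta = 5.0, 0.8
        unwrapped = np.zeros(3000)
        onsets = [100.0, 200.0, 300.0, 400.0]
        for t in onsets:
            unwrapped[int(t * rate):] += delta
        ev = _events(onsets, [-0.5] * 4, cls=["left"] * 4)
        out = triggered_average(_phase(unwrapped), ev)
        lags = out["left"].lags
        assert np.allclose(out["left"].mean[lags > 1.0], delta, atol=1e-9)
        assert np.allclose(out["left"].mean[lags < -0.5], 0.0, atol=1e-9)

    def test_class_below_min_events_omitted(self):
        ev = _events([60, 120], [0.5] * 2, cls=["right"] * 2)
        with pytest.warns(UserWarning, match="omitted"):
            out = triggered_average(_phase(np.zeros(2000)), ev)
        assert out == {}


class TestPhaseOccupancy:
    def test_uniform_onset_phases_pass_rayleigh(self):
        rng = np.random.default_rng(3)
        rejections = 0
        for k in range(20):
            unwrapped = rng.uniform(-np.pi, np.pi, 3000)
            onsets = rng.uniform(2, 500, 60)
            ev = _events(onsets, rng.normal(0, 0.3, 60), cls=["left"] * 60)
            out = phase_occupancy_at_swims(_phase(unwrapped), ev)
            rejections += out["per_class"]["left"]["rayleigh_p"] < 0.05
        assert rejections <= 3

    def test_phase_locked_onsets_rejected(self):
        unwrapped = np.zeros(3000)  # phase always 0
        onsets = np.linspace(5, 500, 50)
        ev = _events(onsets, [0.5] * 50, cls=["right"] * 50)
        out = phase_occupancy_at_swims(_phase(unwrapped), ev)
        assert out["per_class"]["right"]["rayleigh_p"] < 0.01

    def test_identical_class_distributions_not_different(self):
        rng = np.random.default_rng(4)
        angles = rng.uniform(-np.pi, np.pi, 3000)
        onsets = rng.uniform(2, 500, 90)
        cls = ["left", "right", "forward"] * 30
        ev = _events(onsets, rng.normal(0, 0.3, 90), cls=cls)
        out = phase_occupancy_at_swims(_phase(angles), ev)
        assert out["cross_class"]["p"] > 0.05


class TestDeltaRegression:
    def _session_like(self, gain=-0.7, n_events=30, rate=5.0):
        rng = np.random.default_rng(5)
        onsets = np.sort(rng.uniform(5, 500, n_events))
        onsets = onsets[np.diff(np.concatenate([[0], onsets])) > 2]
        lats = rng.normal(0, 0.5, onsets.size)
        unwrapped = np.zeros(3000)
        heading = np.zeros(3000)
        for t, lat in zip(onsets, lats):
            unwrapped[int(t * rate):] += gain * lat
            heading[int(t * rate):] += lat
        ev = _events(onsets, lats)
        return _phase(unwrapped), HeadingTrace(heading, rate), ev

    def test_slope_recovers_gain_exactly_on_construction(self):
        phase, heading, ev = self._session_like(gain=-0.7)
        res = window_delta_regression(phase, heading, ev)
        assert res["slope"] == pytest.approx(-0.7, rel=1e-9)

    def test_forward_only_swims_degenerate(self):
        rate = 5.0
        ev = _events(np.arange(10, 200, 25.0), [0.0] * 8)
        with pytest.raises(ValueError, match="degenerate"):
            window_delta_regression(
                _phase(np.zeros(3000)), HeadingTrace(np.zeros(3000), rate), ev
            )

    def test_slope_invariant_to_phase_offset(self):
        phase, heading, ev = self._session_like()
        shifted = _phase(phase.unwrapped + 12.3)
        a = window_delta_regression(phase, heading, ev)
        b = window_delta_regression(shifted, heading, ev)
        assert a["slope"] == pytest.approx(b["slope"], abs=1e-12)


def _mwu_exact_enumeration(a, b):
    """Brute-force two-sided Mann-Whitney p over all rank assignments."""
    pooled = np.concatenate([a, b])
    ranks = rankdata(pooled)
    n_a = len(a)
    u_obs = ranks[:n_a].sum() - n_a * (n_a + 1) / 2
    mid = n_a * len(b) / 2
    count = total = 0
    for combo in itertools.combinations(range(len(pooled)), n_a):
        u = ranks[list(combo)].sum() - n_a * (n_a + 1) / 2
        count += abs(u - mid) >= abs(u_obs - mid) - 1e-12
        total += 1
    return count / total


class TestCompareConditions:
    def test_identical_paired_vectors_give_p_one(self):
        res = compare_conditions([1, 2, 3, 4, 5], [1, 2, 3, 4, 5], paired=True)
        assert res["p_value"] == 1.0
        assert res["degenerate"]

    def test_mannwhitney_matches_exact_enumeration(self):
        rng = np.random.default_rng(6)
        a = rng.normal(0, 1, 8)
        b = rng.normal(2.5, 1, 8)
        res = compare_conditions(a, b, paired=False)
        assert res["p_value"] == pytest.approx(
            _mwu_exact_enumeration(a, b), abs=1e-9
        )

    def test_gain_independent_sessions_not_significant(self):
        """Sessions whose phase gain ignores the visual gain condition show
        no condition differences (the closed-loop null result)."""
        rng = np.random.default_rng(7)
        slopes = {g: rng.normal(-0.7, 0.05, 6) for g in (0.5, 1.0, 2.0)}
        sig = 0
        for g1, g2 in itertools.combinations(slopes, 2):
            res = compare_conditions(slopes[g1], slopes[g2], paired=True)
            sig += res["p_value"] < 0.05
        assert sig == 0


class TestRegressors:
    def test_no_events_gives_zero_regressor(self):
        regs = build_regressors([], 5.0, 100)
        assert np.allclose(regs.regressors["left_swims"], 0.0)

    def test_single_event_is_sampled_exponential(self):
        ev = _events([10.0], [-0.5], cls=["left"])
        regs = build_regressors(ev, 5.0, 200, tau_s=3.0)
        r = regs.regressors["left_swims"]
        i = int(10.0 * 5.0)
        assert np.argmax(r) == i
        assert r[i] == pytest.approx(1.0)
        decay = np.exp(-np.arange(200 - i) / (3.0 * 5.0))
        assert np.allclose(r[i:], decay, atol=1e-9)

    def test_trace_equal_to_regressor_has_unit_correlation(self):
        ev = _events([10.0, 40.0], [0.6, 0.7], cls=["right", "right"])
        regs = build_regressors(ev, 5.0, 400)
        r = regs.regressors["right_swims"]
        assert np.corrcoef(r, r)[0, 1] == pytest.approx(1.0)


class TestMotorClassification:
    def _setup(self):
        rng = np.random.default_rng(8)
        onsets = np.sort(rng.uniform(2, 500, 60))
        cls = ["left" if k % 2 else "right" for k in range(onsets.size)]
        ev = _events(onsets, [(-0.5 if c == "left" else 0.5) for c in cls], cls=cls)
        regs = build_regressors(ev, 5.0, 3000)
        return rng, regs

    def test_rules(self):
        rng, regs = self._setup()
        left = regs.regressors["left_swims"]
        right = regs.regressors["right_swims"]
        values = np.vstack(
            [
                left + rng.normal(0, 0.05, left.size),  # left ROI
                left + right,  # correlated with both -> none
                rng.normal(0, 1, left.size),  # noise -> none
            ]
        )
        traces = rc.core.TraceMatrix(values, 5.0, np.arange(3))
        out = classify_motor_rois(traces, regs)
        assert out[0] == "left"
        assert out[2] == "none"

    def test_dual_supra_threshold_is_none(self):
        rng, regs = self._setup()
        both = (
            regs.regressors["left_swims"] + regs.regressors["right_swims"]
        )
        traces = rc.core.TraceMatrix(both[None, :], 5.0, [0])
        corr_l = np.corrcoef(both, regs.regressors["left_swims"])[0, 1]
        corr_r = np.corrcoef(both, regs.regressors["right_swims"])[0, 1]
        if corr_l > 0.7 and corr_r > 0.7:  # the intended construction
            assert classify_motor_rois(traces, regs)[0] == "none"


class TestCrossvalRegression:
    def test_exact_linear_combination_gives_unit_correlation(self):
        rng = np.random.default_rng(9)
        onsets = np.sort(rng.uniform(2, 590, 80))
        ev = _events(
            onsets, rng.normal(0, 0.5, 80),
            cls=["left" if x < 0 else "right" for x in rng.normal(0, 1, 80)],
        )
        regs = build_regressors(ev, 5.0, 3000)
        y = np.cumsum(
            2.0 * regs.regressors["angular_velocity"]
        ) / 5.0
        phase = _phase(y)
        out = crossval_phase_regression(
            phase, regs, models={"motor": ("angular_velocity",)},
            n_draws=20, rng=np.random.default_rng(0),
        )
        assert np.all(out["motor"] > 0.95)

    def test_independent_phase_centered_at_zero(self):
        rng = np.random.default_rng(10)
        ev = _events(
            np.sort(rng.uniform(2, 590, 60)), rng.normal(0, 0.5, 60),
            cls=["left"] * 60,
        )
        regs = build_regressors(ev, 5.0, 3000)
        phase = _phase(np.cumsum(rng.normal(0, 0.2, 3000)))
        out = crossval_phase_regression(
            phase, regs, models={"motor": ("angular_velocity",)},
            n_draws=100, rng=np.random.default_rng(1),
        )
        assert abs(np.median(out["motor"])) < 0.2

    def test_combined_model_beats_single_predictors(self):
        """With motor-driven phase plus gaze-coupled wobble, the two-
        predictor model crossvalidates at least as well as either single
        predictor."""
        params = rc.SessionParams(
            n_neurons=16, duration_s=900.0, seed=12, gaze_coupling=-0.5,
            saccade_rate_hz=0.2, noise_sd=0.0, distractor_fraction=0.0,
        )
        s = rc.simulate_session(params)
        from conftest import true_alpha_embedding

        emb = true_alpha_embedding(s)
        phase = rc.phasedyn.compute_phase(s.traces.subset(emb.roi_ids), emb)
        regs = build_regressors(
            s.truth.swim_events, params.imaging_rate_hz, params.n_frames,
            gaze=s.gaze,
        )
        out = crossval_phase_regression(
            phase, regs, n_draws=60, rng=np.random.default_rng(2)
        )
        both = np.median(out["both"])
        assert both >= np.median(out["motor"]) - 0.02
        assert both >= np.median(out["gaze"]) - 0.02

    def test_short_recording_rejected(self):
        regs = build_regressors([], 5.0, 100)
        with pytest.raises(ValueError, match="epoch"):
            crossval_phase_regression(_phase(np.zeros(100)), regs)
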