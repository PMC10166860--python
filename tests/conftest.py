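"""Shared fixtures: compact synthetic sessions reused across test modules."""

import numpy as np
import pytest

import ringcompass as rc
from ringcompass.rpcspace import RpcEmbedding


def true_alpha_embedding(session):
    """Unit-circle embedding built from the ground-truth ring angles."""
    ring = session.rois[session.rois.is_ring].set_index("roi_id")
    alpha = ring["true_alpha"].to_numpy()
    return RpcEmbedding(
        coords=np.column_stack([np.cos(alpha), np.sin(alpha)]),
        alpha=alpha,
        roi_ids=ring.index.to_numpy(),
        transform={},
        anchor_angles=(0.0, 0.0),
    )


@pytest.fixture(scope="session")
def compact_params():
    return rc.SessionParams(n_neurons=32, duration_s=300.0, seed=7)


@pytest.fixture(scope="session")
def compact_session(compact_params):
    return rc.simulate_session(compact_params)


@pytest.fixture(scope="session")
def compact_result(compact_session):
    import warnings

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return rc.run_pipeline(rc.bundle_from_synthetic(compact_session))


@pytest.fixture(scope="session")
def sweep_ring():
    """Noiseless kernel-free ring whose phase sweeps the circle uniformly
    (three revolutions) - full and even coverage for profile/tuning tests."""
    params = rc.SessionParams(
        n_neurons=32, duration_s=300.0, seed=13, noise_sd=0.0,
        calcium_tau_s=0.0, distractor_fraction=0.0, roi_jitter_um=0.0,
        include_gaze=False,
    )
    rois = rc.synthio.place_ring_rois(params, np.random.default_rng(0))
    ring = rois[rois.is_ring]
    truth = rc.synthio.GroundTruth(
        true_phase=np.linspace(0, 6 * np.pi, params.n_frames, endpoint=False),
        true_heading=np.zeros(params.n_behavior_frames),
        true_alpha=ring.true_alpha.to_numpy(),
        swim_events=[],
    )
    traces = rc.synthio.render_calcium(
        truth, rois, params, np.random.default_rng(1)
    )
    emb = RpcEmbedding(
        coords=np.column_stack(
            [np.cos(truth.true_alpha), np.sin(truth.true_alpha)]
        ),
        alpha=truth.true_alpha,
        roi_ids=ring.roi_id.to_numpy(),
        transform={},
        anchor_angles=(0.0, 0.0),
    )
    return traces, emb, truth


@pytest.fixture(scope="session")
def clean_session():
    """Noiseless, kernel-free session with instantaneous phase steps."""
    params = rc.SessionParams(
        n_neurons=32, duration_s=300.0, seed=11, noise_sd=0.0,
        calcium_tau_s=0.0, phase_ramp_tau_s=0.0, tail_noise_sd=0.0,
        include_gaze=False, roi_jitter_um=0.0, distractor_fraction=0.0,
    )
    return rc.simulate_session(params)
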