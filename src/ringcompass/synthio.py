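"""Synthetic ring-attractor sessions with known ground truth.

The generator emulates a head-restrained larval-zebrafish recording: a ring of
sinusoidally tuned neurons in the horizontal plane whose activity bump rotates
with every directional swim, rendered through a slow calcium indicator, plus a
bout-structured tail trace and an optional piecewise-constant gaze trace.  The
known ground truth (phase, heading, ring angles, swim classes) makes every
downstream stage of the pipeline testable without experimental data.

The bump is imposed kinematically - there is no connectivity-based attractor
simulation.  After each swim the true phase relaxes exponentially (default
1 s) to its new set point rather than jumping, mimicking the smooth bump
translation seen in the data; between swims it is constant.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.signal import lfilter

from .core import (
    GazeTrace,
    RawFluorescence,
    SwimEvent,
    TailTrace,
    TraceMatrix,
    wrap_angle,
)

__all__ = [
    "SessionParams",
    "GroundTruth",
    "SyntheticSession",
    "simulate_swim_sequence",
    "synthesize_tail_trace",
    "simulate_gaze_trace",
    "place_ring_rois",
    "render_calcium",
    "simulate_session",
    "make_mirrored_skeletons",
    "simulate_mirrored_plane",
]


@dataclass
class SessionParams:
    """Parameters of a synthetic session.

    The defaults are the study conditions used throughout the test-suite:
    80 ring neurons imaged at 5 Hz for 600 s, raised-cosine tuning of unit
    amplitude, GCaMP6s-like 1.8 s indicator decay, additive noise of
    0.15 (relative to the unit tuning peak), Poisson swims at 0.3 Hz with a
    1 s refractory gap (an actively swimming fish, so the bump samples the
    whole ring within a session), and the symmetric trimodal laterality
    mixture that the behavior module is designed to invert.

    ``phase_gain`` is signed: the phase increment per swim is
    ``phase_gain * laterality``.  With the positive-=-rightward laterality
    convention the default of -1.0 makes left swims increase the phase
    (clockwise bump rotation), as observed.
    """

    n_neurons: int = 80
    duration_s: float = 600.0
    imaging_rate_hz: float = 5.0
    behavior_rate_hz: float = 400.0
    tuning_shape: str = "raised_cosine"  # or "von_mises"
    kappa: float = 2.0
    amplitude: float = 1.0
    noise_sd: float = 0.15
    calcium_tau_s: float = 1.8
    phase_ramp_tau_s: float = 1.0
    swim_rate_hz: float = 0.3
    swim_refractory_s: float = 1.0
    # trimodal laterality mixture: central (forward) + two symmetric side lobes
    lat_central_sd: float = 0.10
    lat_side_mean: float = 0.60
    lat_side_sd: float = 0.20
    lat_weights: tuple = (0.5, 0.25, 0.25)  # (forward, right, left)
    turn_persistence: float = 0.8  # P(same side as previous directional swim)
    phase_gain: float = -0.7
    distractor_fraction: float = 0.3
    motor_distractor_fraction: float = 0.5
    include_gaze: bool = True
    saccade_rate_hz: float = 0.05
    saccade_sd: float = 0.3
    gaze_coupling: float = -0.2
    # bout kinematics; the carrier covers an integer number of cycles inside
    # the 70 ms laterality window, so the windowed mean is insensitive to
    # small onset-detection delays
    bout_carrier_hz: float = 2.0 / 0.070
    bout_amplitude: float = 0.6
    bout_env_tau_s: float = 0.25
    bout_duration_range_s: tuple = (0.15, 0.30)
    tail_noise_sd: float = 0.01
    # rendering of raw fluorescence from activity
    baseline_fluorescence: float = 100.0
    bleach_tau_s: float | None = None
    ring_radius_um: float = 50.0
    roi_jitter_um: float = 2.0
    seed: int = 0

    def validate(self) -> None:
        if self.n_neurons < 8:
            raise ValueError("need at least 8 ring neurons")
        for name in ("duration_s", "imaging_rate_hz", "behavior_rate_hz"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.swim_rate_hz < 0 or self.noise_sd < 0:
            raise ValueError("rates and noise must be non-negative")
        if self.tuning_shape not in ("raised_cosine", "von_mises"):
            raise ValueError(f"unknown tuning shape {self.tuning_shape!r}")
        w = np.asarray(self.lat_weights, float)
        if w.size != 3 or np.any(w < 0) or w.sum() <= 0:
            raise ValueError("lat_weights must be 3 non-negative values")
        if not 0 <= self.distractor_fraction < 1:
            raise ValueError("distractor_fraction must be in [0, 1)")

    @property
    def n_distractors(self) -> int:
        f = self.distractor_fraction
        return int(round(self.n_neurons * f / (1.0 - f))) if f > 0 else 0

    @property
    def n_frames(self) -> int:
        return int(round(self.duration_s * self.imaging_rate_hz))

    @property
    def n_behavior_frames(self) -> int:
        return int(round(self.duration_s * self.behavior_rate_hz))


@dataclass
class GroundTruth:
    """Everything the generator knows that the pipeline must recover."""

    true_phase: np.ndarray  # rad, per imaging frame, unwrapped
    true_heading: np.ndarray  # rad, per behavior frame
    true_alpha: np.ndarray  # rad, per ring ROI
    swim_events: list  # of SwimEvent, class recorded at generation


@dataclass
class SyntheticSession:
    traces: TraceMatrix  # rendered activity (dF/F-like units)
    raw: RawFluorescence  # baseline * (1 + activity), pipeline input
    rois: pd.DataFrame
    tail: TailTrace
    gaze: GazeTrace | None
    truth: GroundTruth
    params: SessionParams


def _laterality_mixture_draw(params: SessionParams, rng, size: int):
    """Sample (laterality, class) from the symmetric trimodal mixture.

    Directional swims chain: a directional swim repeats the side of the
    previous directional swim with probability ``turn_persistence``
    (zebrafish larvae chain same-direction turns, which is what carries the
    bump around the whole ring).  The marginal mixture stays symmetric.
    """
    w = np.asarray(params.lat_weights, float)
    w = w / w.sum()
    p_forward = w[0]
    lat = np.empty(size)
    classes = np.empty(size, dtype=object)
    side = None  # +1 right, -1 left
    for k in range(size):
        if rng.random() < p_forward:
            lat[k] = rng.normal(0.0, params.lat_central_sd)
            classes[k] = "forward"
            continue
        if side is None:
            side = 1 if rng.random() < w[1] / (w[1] + w[2]) else -1
        elif rng.random() >= params.turn_persistence:
            side = -side
        lat[k] = side * rng.normal(params.lat_side_mean, params.lat_side_sd)
        classes[k] = "right" if side > 0 else "left"
    return lat, classes


def simulate_swim_sequence(params: SessionParams, rng=None) -> list:
    """Poisson-timed swim bouts with trimodal laterality.

    Events falling within ``swim_refractory_s`` of the previous kept bout are
    discarded (bouts do not overlap in real fish).  The generating mixture
    component is recorded as the true class.
    """
    params.validate()
    if rng is None:
        rng = np.random.default_rng(params.seed)
    if params.swim_rate_hz == 0:
        return []
    n = rng.poisson(params.swim_rate_hz * params.duration_s)
    lo, hi = params.bout_duration_range_s
    onsets = np.sort(rng.uniform(0.0, params.duration_s - hi, n))
    durations = rng.uniform(lo, hi, n)
    lat, classes = _laterality_mixture_draw(params, rng, n)
    events, last = [], -np.inf
    for k in range(n):
        if onsets[k] - last < params.swim_refractory_s:
            continue
        events.append(
            SwimEvent(
                onset_s=float(onsets[k]),
                offset_s=float(onsets[k] + durations[k]),
                laterality=float(lat[k]),
                swim_class=str(classes[k]),
            )
        )
        last = onsets[k]
    return events


def synthesize_tail_trace(
    events: list, params: SessionParams, rng=None
) -> TailTrace:
    """Render swim bouts as a tail-angle trace.

    Within a bout the tail angle is the laterality index plus a decaying
    25 Hz oscillation whose mean over the first 70 ms is removed, so that the
    windowed mean used by the behavior module equals the event's laterality
    exactly.  Between bouts the trace is near-zero noise.
    """
    if rng is None:
        rng = np.random.default_rng(params.seed + 1)
    n = params.n_behavior_frames
    dt = 1.0 / params.behavior_rate_hz
    trace = (
        rng.normal(0.0, params.tail_noise_sd, n)
        if params.tail_noise_sd > 0
        else np.zeros(n)
    )
    n70 = max(1, int(round(0.070 * params.behavior_rate_hz)))
    prev_end = -np.inf
    for ev in events:
        if ev.onset_s < prev_end:
            warnings.warn("overlapping bouts merged in tail trace")
        i0 = int(round(ev.onset_s * params.behavior_rate_hz))
        i1 = min(n, int(round(ev.offset_s * params.behavior_rate_hz)))
        if i1 <= i0:
            continue
        t = np.arange(i1 - i0) * dt
        osc = (
            params.bout_amplitude
            * np.sin(2 * np.pi * params.bout_carrier_hz * t)
            * np.exp(-t / params.bout_env_tau_s)
        )
        osc -= osc[: min(n70, osc.size)].mean()
        trace[i0:i1] += ev.laterality + osc
        prev_end = ev.offset_s
    return TailTrace(angle=trace, rate=params.behavior_rate_hz)


def simulate_gaze_trace(params: SessionParams, rng=None) -> GazeTrace:
    """Piecewise-constant gaze with Poisson step saccades.

    Eye position is resampled from N(0, saccade_sd) at each saccade, a
    bounded, mean-reverting stand-in for real fixations (positive =
    rightward, matching the laterality convention).
    """
    if rng is None:
        rng = np.random.default_rng(params.seed + 2)
    n = params.n_behavior_frames
    k = rng.poisson(params.saccade_rate_hz * params.duration_s)
    times = np.sort(rng.uniform(0.0, params.duration_s, k))
    values = rng.normal(0.0, params.saccade_sd, k)
    gaze = np.zeros(n)
    idx = np.round(times * params.behavior_rate_hz).astype(int)
    for i, v in zip(idx, values):
        gaze[i:] = v
    return GazeTrace(angle=gaze, rate=params.behavior_rate_hz, saccade_times=times)


def place_ring_rois(params: SessionParams, rng=None) -> pd.DataFrame:
    """Anatomical ROI table: ring neurons on a horizontal ellipse, distractors
    outside it.

    Ring angles uniformly cover (-pi, pi] and the anatomical position follows
    the convention: a ROI with alpha = 0 is caudal-most, alpha = +pi/2 is the
    leftmost (positive ``x_lr``).  Row order is shuffled so selection stages
    cannot rely on ordering.
    """
    params.validate()
    if rng is None:
        rng = np.random.default_rng(params.seed + 3)
    n, nd = params.n_neurons, params.n_distractors
    alpha = wrap_angle(2 * np.pi * np.arange(n) / n)
    r = params.ring_radius_um
    jit = params.roi_jitter_um
    x = r * np.sin(alpha) + rng.normal(0, jit, n)
    y = -r * np.cos(alpha) + rng.normal(0, jit, n)
    z = rng.normal(0, jit, n)
    ring = pd.DataFrame(
        {
            "x_lr": x,
            "y_rc": y,
            "z": z,
            "is_ring": True,
            "true_alpha": alpha,
            "distractor_kind": "none",
        }
    )
    if nd > 0:
        rd = rng.uniform(1.5 * r, 3.0 * r, nd)
        th = rng.uniform(-np.pi, np.pi, nd)
        n_motor = int(round(nd * params.motor_distractor_fraction))
        kinds = np.array(["noise"] * nd, dtype=object)
        sides = rng.choice(["left", "right"], size=n_motor)
        kinds[:n_motor] = ["motor_" + s for s in sides]
        rng.shuffle(kinds)
        dist = pd.DataFrame(
            {
                "x_lr": rd * np.sin(th),
                "y_rc": -rd * np.cos(th),
                "z": rng.normal(0, 3 * jit, nd),
                "is_ring": False,
                "true_alpha": np.nan,
                "distractor_kind": kinds,
            }
        )
        rois = pd.concat([ring, dist], ignore_index=True)
    else:
        rois = ring
    rois = rois.sample(frac=1.0, random_state=rng.integers(2**31)).reset_index(
        drop=True
    )
    rois.insert(0, "roi_id", np.arange(len(rois)))
    return rois


def _tuning(theta: np.ndarray, params: SessionParams) -> np.ndarray:
    if params.tuning_shape == "raised_cosine":
        return 0.5 * (1.0 + np.cos(theta))
    return np.exp(params.kappa * (np.cos(theta) - 1.0))


def _calcium_filter(x: np.ndarray, tau_s: float, rate_hz: float) -> np.ndarray:
    """Causal single-exponential indicator kernel, DC gain 1."""
    if tau_s <= 0:
        return x
    a = np.exp(-1.0 / (tau_s * rate_hz))
    return lfilter([1.0 - a], [1.0, -a], x, axis=-1)


def _event_regressor(
    events: list, classes, n: int, rate: float, tau_s: float
) -> np.ndarray:
    ind = np.zeros(n)
    for ev in events:
        if ev.swim_class in classes:
            i = int(round(ev.onset_s * rate))
            if 0 <= i < n:
                ind[i] = 1.0
    if tau_s <= 0:
        return ind
    a = np.exp(-1.0 / (tau_s * rate))
    return lfilter([1.0], [1.0, -a], ind)


def render_calcium(
    truth: GroundTruth,
    rois: pd.DataFrame,
    params: SessionParams,
    rng=None,
) -> TraceMatrix:
    """Render ROI activity from the true phase.

    Ring drive is ``amplitude * g(true_phase - alpha_i)`` with ``g`` the
    configured tuning curve, convolved with the causal indicator kernel, plus
    i.i.d. Gaussian noise.  Noise distractors carry noise only; motor
    distractors follow a calcium-filtered left- or right-swim event train.
    """
    if rng is None:
        rng = np.random.default_rng(params.seed + 4)
    n_frames = truth.true_phase.size
    values = np.zeros((len(rois), n_frames))
    ring_rows = np.flatnonzero(rois["is_ring"].to_numpy())
    alpha = rois["true_alpha"].to_numpy()[ring_rows]
    drive = params.amplitude * _tuning(
        truth.true_phase[None, :] - alpha[:, None], params
    )
    values[ring_rows] = _calcium_filter(
        drive, params.calcium_tau_s, params.imaging_rate_hz
    )
    for side in ("left", "right"):
        rows = np.flatnonzero(
            (rois["distractor_kind"] == f"motor_{side}").to_numpy()
        )
        if rows.size:
            reg = _event_regressor(
                truth.swim_events,
                {side},
                n_frames,
                params.imaging_rate_hz,
                params.calcium_tau_s,
            )
            values[rows] = params.amplitude * reg[None, :]
    if params.noise_sd > 0:
        values += rng.normal(0.0, params.noise_sd, values.shape)
    return TraceMatrix(
        values=values, rate=params.imaging_rate_hz, roi_ids=rois["roi_id"].to_numpy()
    )


def _true_phase(
    events: list, gaze: GazeTrace | None, params: SessionParams
) -> np.ndarray:
    """Unwrapped ground-truth phase on the imaging clock.

    Each swim moves the set point by ``phase_gain * laterality``; the phase
    relaxes to the set point with time constant ``phase_ramp_tau_s`` (0 for
    instantaneous steps).  An optional gaze term adds
    ``gaze_coupling * gaze(t)``.
    """
    n = params.n_frames
    t = np.arange(n) / params.imaging_rate_hz
    setpoint = np.zeros(n)
    for ev in events:
        setpoint[t >= ev.onset_s] += params.phase_gain * ev.laterality
    if params.phase_ramp_tau_s > 0:
        phase = _calcium_filter(setpoint, params.phase_ramp_tau_s, params.imaging_rate_hz)
    else:
        phase = setpoint
    if gaze is not None and params.gaze_coupling != 0.0:
        step = max(1, int(round(params.behavior_rate_hz / params.imaging_rate_hz)))
        g = gaze.angle[::step][:n]
        g = np.pad(g, (0, n - g.size), mode="edge")
        phase = phase + params.gaze_coupling * g
    return phase


def integrate_true_heading(events: list, params: SessionParams) -> np.ndarray:
    heading = np.zeros(params.n_behavior_frames)
    t = np.arange(params.n_behavior_frames) / params.behavior_rate_hz
    for ev in events:
        heading[t >= ev.onset_s] += ev.laterality
    return heading


def simulate_session(params: SessionParams) -> SyntheticSession:
    """Compose a full synthetic session; deterministic given ``params.seed``."""
    params.validate()
    rng = np.random.default_rng(params.seed)
    events = simulate_swim_sequence(params, rng)
    tail = synthesize_tail_trace(events, params, np.random.default_rng(params.seed + 1))
    gaze = (
        simulate_gaze_trace(params, np.random.default_rng(params.seed + 2))
        if params.include_gaze
        else None
    )
    rois = place_ring_rois(params, np.random.default_rng(params.seed + 3))
    phase = _true_phase(events, gaze, params)
    heading = integrate_true_heading(events, params)
    ring_alpha = rois.loc[rois["is_ring"], "true_alpha"].to_numpy()
    truth = GroundTruth(
        true_phase=phase,
        true_heading=heading,
        true_alpha=ring_alpha,
        swim_events=events,
    )
    traces = render_calcium(truth, rois, params, np.random.default_rng(params.seed + 4))
    fluo = params.baseline_fluorescence * (1.0 + traces.values)
    if params.bleach_tau_s:
        fluo = fluo * np.exp(-traces.times[None, :] / params.bleach_tau_s)
    raw = RawFluorescence(values=fluo, rate=params.imaging_rate_hz, roi_ids=traces.roi_ids)
    return SyntheticSession(
        traces=traces, raw=raw, rois=rois, tail=tail, gaze=gaze, truth=truth,
        params=params,
    )


# ---------------------------------------------------------------------------
# synthetic anatomy: mirrored skeletons and a mirrored two-photon plane
# ---------------------------------------------------------------------------


def make_mirrored_skeletons(
    n_neurons: int = 19,
    midline_x: float = 0.0,
    span_um: float = 30.0,
    n_branch: int = 5,
    jitter_um: float = 0.0,
    seed: int = 0,
):
    """Synthetic IPN-projecting neurons with antiphase-partner projections.

    A neuron whose dendrite sits at distance ``d`` from the midline sends
    its axon across the midline to the mirror position of its antiphase
    partner's dendrite: ``axon_x = dendrite_x - (span + d_min)``.  Midline
    distances of dendrite and axon are therefore perfectly anticorrelated (a
    lateral dendrite pairs with a medial axon and vice versa), the
    dendrite-axon separation along the frontal axis is a constant
    ``span + d_min`` for every neuron, and the soma's antero-posterior
    position increases with the dendrite's laterality.  Returns a list of
    :class:`ipnmap.Skeleton`.
    """
    from .ipnmap import Skeleton

    rng = np.random.default_rng(seed)
    skels = []
    d_min = 2.0
    d_vals = np.linspace(d_min, span_um, n_neurons)
    pitch = span_um + d_min  # constant dendrite-axon separation
    for i, d in enumerate(d_vals):
        dend_x = midline_x + d
        axon_x = dend_x - pitch  # contralateral, medial when d is lateral
        rows = []
        soma_y = 10.0 + d  # AP position tied to dendrite laterality
        rows.append((1, 1, midline_x, soma_y, 40.0, 1.0, -1))  # soma
        rows.append((2, 3, dend_x, 0.0, 0.0, 0.5, 1))  # dendrite root
        rows.append((3, 2, axon_x, 0.0, 0.0, 0.5, 1))  # axon root
        nid = 4
        for (root, comp, cx) in ((2, 3, dend_x), (3, 2, axon_x)):
            for b in range(n_branch):
                bx = cx + rng.normal(0, jitter_um)
                by = rng.uniform(-3.0, 3.0) if jitter_um else (b - n_branch / 2)
                # branch node with two children -> a true branching point
                rows.append((nid, comp, bx, by, 0.0, 0.3, root))
                rows.append((nid + 1, comp, bx + 0.5, by + 0.5, 0.0, 0.2, nid))
                rows.append((nid + 2, comp, bx - 0.5, by - 0.5, 0.0, 0.2, nid))
                nid += 3
        nodes = pd.DataFrame(
            rows, columns=["id", "type", "x", "y", "z", "radius", "parent"]
        )
        skels.append(
            Skeleton(nodes=nodes, midline_x=midline_x, neuron_id=f"syn{i:02d}")
        )
    return skels


def simulate_mirrored_plane(
    mirror_offset_um: float = 14.0,
    pixel_size_um: float = 1.0,
    extent_um: tuple = (56.0, 28.0),
    n_frames: int = 400,
    bump_sd_um: float = 3.0,
    noise_sd: float = 0.05,
    seed: int = 0,
):
    """Synthetic neuropil plane: a traveling Gaussian bump plus a copy shifted
    by ``mirror_offset_um`` along the frontal (x) axis.

    Pixels separated by the mirror offset share their signal, so the 2-D
    autocorrelation of the movie develops side lobes at that frontal distance.
    Returns ``(frames, mask, pixel_size_um)`` with frames shaped (T, H, W).
    """
    rng = np.random.default_rng(seed)
    w = int(round(extent_um[0] / pixel_size_um))
    h = int(round(extent_um[1] / pixel_size_um))
    xs = (np.arange(w) + 0.5) * pixel_size_um
    ys = (np.arange(h) + 0.5) * pixel_size_um
    # bump center random-walks along the frontal axis within the left half
    span = extent_um[0] - mirror_offset_um
    c = np.abs(
        np.cumsum(rng.normal(0, span / 12, n_frames)) % (2 * span) - span
    )
    frames = np.empty((n_frames, h, w))
    for t in range(n_frames):
        prof = np.exp(-0.5 * ((xs - c[t]) / bump_sd_um) ** 2) + np.exp(
            -0.5 * ((xs - c[t] - mirror_offset_um) / bump_sd_um) ** 2
        )
        frames[t] = prof[None, :] * np.ones((h, 1))
    frames += rng.normal(0, noise_sd, frames.shape)
    mask = np.ones((h, w), dtype=bool)
    return frames, mask, pixel_size_um
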