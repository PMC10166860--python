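"""Heading integration and phase-heading coupling statistics.

The estimated heading of a head-restrained fish is the running sum of swim
laterality indices (instantaneous angular velocity proxy).  Coupling with the
decoded network phase is quantified by rolling-window correlations against a
non-overlapping-epoch shuffle, swim-triggered phase averages, post-swim
delta-regressions (slope of phase change on heading change), motor/gaze
exponential regressors (tau = 3 s) and cross-validated multilinear
regression of the phase derivative.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from pingouin.circular import circ_rayleigh
from scipy.signal import lfilter, medfilt
from scipy.stats import chi2, linregress, mannwhitneyu, rankdata, wilcoxon

from .core import HeadingTrace, PhaseTrace, SwimEvent

__all__ = [
    "TriggeredAverage",
    "CouplingResult",
    "RegressorSet",
    "integrate_heading",
    "resample_zero_order_hold",
    "phase_heading_coupling",
    "triggered_average",
    "phase_occupancy_at_swims",
    "window_delta_regression",
    "compare_conditions",
    "build_regressors",
    "classify_motor_rois",
    "crossval_phase_regression",
]


@dataclass
class TriggeredAverage:
    lags: np.ndarray
    mean: np.ndarray
    n_events: int
    baseline_subtracted: bool = True


@dataclass
class CouplingResult:
    window_correlations: np.ndarray
    shuffle_correlations: np.ndarray
    p_value: float
    slope: float = None
    condition: str = None


@dataclass
class RegressorSet:
    tau_s: float
    rate: float
    regressors: dict = field(default_factory=dict)
    correlation_threshold: float = 0.7


def integrate_heading(
    events: list, rate: float, duration_s: float
) -> HeadingTrace:
    """Cumulative laterality: one step per swim onset, constant between."""
    n = int(round(rate * duration_s))
    heading = np.zeros(n)
    for ev in events:
        i = int(round(ev.onset_s * rate))
        if 0 <= i < n:
            heading[i:] += ev.laterality
    return HeadingTrace(heading=heading, rate=rate)


def resample_zero_order_hold(x: np.ndarray, rate_in: float, rate_out: float, n_out: int):
    """Sample-and-hold resampling onto ``n_out`` frames at ``rate_out``."""
    t_out = np.arange(n_out) / rate_out
    idx = np.minimum((t_out * rate_in).astype(int), x.size - 1)
    return x[idx]


def _pearson(a: np.ndarray, b: np.ndarray) -> float:
    return float(np.corrcoef(a, b)[0, 1])


def phase_heading_coupling(
    phase: PhaseTrace,
    heading: HeadingTrace,
    window_s: float = 300.0,
    window_step_s: float = 30.0,
    shuffle_epoch_s: float = 300.0,
    rng=None,
) -> CouplingResult:
    """Rolling-window phase-heading correlation against an epoch shuffle.

    Pearson correlation of unwrapped phase and heading in ``window_s``
    windows stepped by ``window_step_s`` (window/10 by default); the shuffle
    correlates each phase window with a randomly placed, non-overlapping
    heading epoch of the same length.  The two correlation populations are
    compared with a two-sided rank-sum test.
    """
    if rng is None:
        rng = np.random.default_rng(0)
    h = resample_zero_order_hold(
        heading.heading, heading.rate, phase.rate, phase.unwrapped.size
    )
    w = int(round(window_s * phase.rate))
    if w > phase.unwrapped.size:
        raise ValueError("session shorter than one correlation window")
    step = max(1, int(round(window_step_s * phase.rate)))
    epoch = int(round(shuffle_epoch_s * phase.rate))
    starts = np.arange(0, phase.unwrapped.size - w + 1, step)
    data_r, shuf_r = [], []
    for s in starts:
        pw = phase.unwrapped[s : s + w]
        if np.std(pw) == 0 or np.std(h[s : s + w]) == 0:
            continue
        data_r.append(_pearson(pw, h[s : s + w]))
        candidates = [
            c
            for c in range(0, h.size - epoch + 1, step)
            if c + epoch <= s or c >= s + w
        ]
        if candidates:
            c = candidates[rng.integers(len(candidates))]
            hw = h[c : c + epoch][:w]
            if hw.size == w and np.std(hw) > 0:
                shuf_r.append(_pearson(pw, hw))
    data_r, shuf_r = np.asarray(data_r), np.asarray(shuf_r)
    if data_r.size and shuf_r.size:
        p = float(mannwhitneyu(data_r, shuf_r, alternative="two-sided").pvalue)
    else:
        p = np.nan
    return CouplingResult(
        window_correlations=data_r, shuffle_correlations=shuf_r, p_value=p
    )


def triggered_average(
    phase: PhaseTrace,
    events: list,
    pre_s: float = 10.0,
    post_s: float = 25.0,
    min_events: int = 3,
) -> dict:
    """Event-locked averages of the unwrapped phase, one per swim class.

    Each crop has the mean of its 10 s pre-event interval subtracted; classes
    with fewer than ``min_events`` usable crops are omitted with a warning.
    """
    n_pre = int(round(pre_s * phase.rate))
    n_post = int(round(post_s * phase.rate))
    lags = np.arange(-n_pre, n_post + 1) / phase.rate
    by_class = {}
    for ev in events:
        i = int(round(ev.onset_s * phase.rate))
        if i - n_pre < 0 or i + n_post >= phase.unwrapped.size:
            continue
        crop = phase.unwrapped[i - n_pre : i + n_post + 1].copy()
        crop -= crop[:n_pre].mean()
        by_class.setdefault(ev.swim_class, []).append(crop)
    out = {}
    for cls, crops in by_class.items():
        if len(crops) < min_events:
            warnings.warn(f"class {cls!r}: only {len(crops)} events; omitted")
            continue
        out[cls] = TriggeredAverage(
            lags=lags, mean=np.mean(crops, axis=0), n_events=len(crops)
        )
    return out


def mardia_watson_wheeler(groups: list) -> tuple:
    """Uniform-scores test for a common circular distribution across groups.

    Returns (W, p) with W ~ chi2(2(k-1)) under the null.
    """
    pooled = np.concatenate(groups)
    ranks = rankdata(pooled)
    beta = 2 * np.pi * ranks / pooled.size
    w_stat, start = 0.0, 0
    for g in groups:
        b = beta[start : start + len(g)]
        start += len(g)
        w_stat += (np.sum(np.cos(b)) ** 2 + np.sum(np.sin(b)) ** 2) / len(g)
    w_stat *= 2.0
    p = float(chi2.sf(w_stat, df=2 * (len(groups) - 1)))
    return float(w_stat), p


def phase_occupancy_at_swims(phase: PhaseTrace, events: list) -> dict:
    """Wrapped phase at swim onsets, per class, with uniformity statistics.

    Returns per-class angles and Rayleigh (z, p), plus a cross-class
    Mardia-Watson-Wheeler uniform-scores comparison.
    """
    by_class = {}
    for ev in events:
        i = int(round(ev.onset_s * phase.rate))
        if 0 <= i < phase.wrapped.size:
            by_class.setdefault(ev.swim_class, []).append(phase.wrapped[i])
    result = {"per_class": {}}
    for cls, angles in by_class.items():
        angles = np.asarray(angles)
        if angles.size < 10:
            warnings.warn(f"class {cls!r}: fewer than 10 events")
        z, p = circ_rayleigh(angles)
        result["per_class"][cls] = {
            "angles": angles,
            "rayleigh_z": float(z),
            "rayleigh_p": float(p),
        }
    if len(by_class) >= 2:
        w, p = mardia_watson_wheeler([np.asarray(v) for v in by_class.values()])
        result["cross_class"] = {"W": w, "p": p}
    return result


def window_delta_regression(
    phase: PhaseTrace,
    heading: HeadingTrace,
    events: list,
    window_s: tuple = (15.0, 20.0),
    min_events: int = 5,
) -> dict:
    """Regression of post-swim phase change on heading change.

    For each swim, the change of each signal from its value at onset to its
    mean over the 15-20 s post-onset window; ordinary least squares of
    delta-phase on delta-heading over swims.  Events whose window exceeds the
    recording are dropped.
    """
    h = resample_zero_order_hold(
        heading.heading, heading.rate, phase.rate, phase.unwrapped.size
    )
    i0w = int(round(window_s[0] * phase.rate))
    i1w = int(round(window_s[1] * phase.rate))
    d_phase, d_heading = [], []
    for ev in events:
        i = int(round(ev.onset_s * phase.rate))
        if i < 0 or i + i1w >= phase.unwrapped.size:
            continue
        base_p = phase.unwrapped[max(i - 1, 0)]
        base_h = h[max(i - 1, 0)]
        d_phase.append(phase.unwrapped[i + i0w : i + i1w].mean() - base_p)
        d_heading.append(h[i + i0w : i + i1w].mean() - base_h)
    if len(d_phase) < min_events:
        raise ValueError(f"only {len(d_phase)} usable events (need {min_events})")
    d_phase, d_heading = np.asarray(d_phase), np.asarray(d_heading)
    if np.std(d_heading) == 0:
        raise ValueError("degenerate regressor: heading changes are all equal")
    fit = linregress(d_heading, d_phase)
    return {
        "slope": float(fit.slope),
        "intercept": float(fit.intercept),
        "r": float(fit.rvalue),
        "points": np.column_stack([d_heading, d_phase]),
        "n_events": int(d_phase.size),
    }


def compare_conditions(
    slopes_a, slopes_b, paired: bool = True
) -> dict:
    """Nonparametric comparison of per-session slopes between conditions.

    Wilcoxon signed-rank for paired samples (exact where scipy supports it),
    Mann-Whitney U otherwise.  All-zero paired differences give p = 1 by
    convention, flagged.
    """
    a, b = np.asarray(slopes_a, float), np.asarray(slopes_b, float)
    if paired:
        if a.size != b.size:
            raise ValueError("paired comparison needs equal-length samples")
        if a.size < 5:
            warnings.warn("fewer than 5 pairs; paired test has little power")
        if np.allclose(a, b):
            return {"test": "wilcoxon", "statistic": 0.0, "p_value": 1.0,
                    "degenerate": True}
        res = wilcoxon(a, b, alternative="two-sided")
        return {"test": "wilcoxon", "statistic": float(res.statistic),
                "p_value": float(res.pvalue), "degenerate": False}
    res = mannwhitneyu(a, b, alternative="two-sided", method="auto")
    return {"test": "mannwhitneyu", "statistic": float(res.statistic),
            "p_value": float(res.pvalue), "degenerate": False}


def _exp_kernel_filter(x: np.ndarray, tau_s: float, rate: float) -> np.ndarray:
    """Causal convolution with exp(-t/tau), kernel peak 1 at lag 0."""
    a = np.exp(-1.0 / (tau_s * rate))
    return lfilter([1.0], [1.0, -a], x)


def build_regressors(
    events: list,
    rate: float,
    n_frames: int,
    gaze=None,
    tau_s: float = 3.0,
) -> RegressorSet:
    """Exponentially convolved motor and gaze regressors (tau = 3 s).

    Regressors: ``left_swims`` / ``right_swims`` (event indicators),
    ``angular_velocity`` (laterality impulses), and, when a gaze trace is
    given, ``gaze_direction`` and ``gaze_velocity``.
    """
    left = np.zeros(n_frames)
    right = np.zeros(n_frames)
    angvel = np.zeros(n_frames)
    for ev in events:
        i = int(round(ev.onset_s * rate))
        if 0 <= i < n_frames:
            angvel[i] += ev.laterality
            if ev.swim_class == "left":
                left[i] = 1.0
            elif ev.swim_class == "right":
                right[i] = 1.0
    regs = {
        "left_swims": _exp_kernel_filter(left, tau_s, rate),
        "right_swims": _exp_kernel_filter(right, tau_s, rate),
        "angular_velocity": _exp_kernel_filter(angvel, tau_s, rate),
    }
    if gaze is not None:
        g = resample_zero_order_hold(gaze.angle, gaze.rate, rate, n_frames)
        regs["gaze_direction"] = _exp_kernel_filter(g, tau_s, rate)
        gv = np.concatenate([[0.0], np.diff(g)]) * rate
        regs["gaze_velocity"] = _exp_kernel_filter(gv, tau_s, rate)
    return RegressorSet(tau_s=tau_s, rate=rate, regressors=regs)


def classify_motor_rois(
    traces, regressors: RegressorSet, threshold: float = 0.7
) -> np.ndarray:
    """Dual-threshold motor classification per ROI.

    A ROI is 'left' if its correlation with the left-swim regressor exceeds
    the threshold while the right-swim correlation stays below it (and vice
    versa); anything else is 'none'.
    """
    left = regressors.regressors["left_swims"]
    right = regressors.regressors["right_swims"]
    out = np.full(traces.n_rois, "none", dtype=object)
    for i in range(traces.n_rois):
        x = traces.values[i]
        if np.std(x) == 0:
            continue
        rl, rr = _pearson(x, left), _pearson(x, right)
        if rl > threshold and rr < threshold:
            out[i] = "left"
        elif rr > threshold and rl < threshold:
            out[i] = "right"
    return out


def phase_derivative(phase: PhaseTrace, median_frames: int = 3) -> np.ndarray:
    """Central-difference derivative of the lightly median-filtered
    unwrapped phase, in rad/s."""
    smoothed = medfilt(phase.unwrapped, kernel_size=median_frames)
    return np.gradient(smoothed) * phase.rate


MODEL_PREDICTORS = {
    "gaze": ("gaze_velocity",),
    "motor": ("angular_velocity",),
    "both": ("gaze_velocity", "angular_velocity"),
}


def crossval_phase_regression(
    phase: PhaseTrace,
    regressors: RegressorSet,
    models: dict = None,
    n_draws: int = 500,
    epoch_s: float = 300.0,
    rng=None,
) -> dict:
    """Cross-validated multilinear regression of the phase derivative.

    For each model (named tuple of regressor keys), a linear fit on a random
    5 min train epoch is evaluated by the Pearson correlation between
    prediction and observed derivative on a disjoint test epoch; repeated
    ``n_draws`` times.  Returns model -> array of test correlations.
    """
    if rng is None:
        rng = np.random.default_rng(0)
    if models is None:
        models = MODEL_PREDICTORS
    y = phase_derivative(phase)
    n = y.size
    w = int(round(epoch_s * phase.rate))
    if n < 2 * w:
        raise ValueError("recording too short for two disjoint 5-min epochs")
    out = {name: np.empty(n_draws) for name in models}
    for d in range(n_draws):
        # draw a train start, then a test start uniformly from the
        # positions whose epoch does not overlap the train epoch
        while True:
            s_train = int(rng.integers(0, n - w + 1))
            n_left = max(0, s_train - w + 1)
            n_right = max(0, (n - w) - (s_train + w) + 1)
            if n_left + n_right > 0:
                break
        k = int(rng.integers(n_left + n_right))
        s_test = k if k < n_left else s_train + w + (k - n_left)
        tr = slice(s_train, s_train + w)
        te = slice(s_test, s_test + w)
        for name, keys in models.items():
            x = np.column_stack([regressors.regressors[k] for k in keys])
            design = np.column_stack([x[tr], np.ones(w)])
            coef, *_ = np.linalg.lstsq(design, y[tr], rcond=None)
            pred = np.column_stack([x[te], np.ones(w)]) @ coef
            out[name][d] = (
                _pearson(pred, y[te]) if np.std(pred) > 0 else 0.0
            )
    return out
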