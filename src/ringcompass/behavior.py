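"""Swim, laterality and gaze extraction from tail and eye time series.

Swims are episodes in which the tail "vigor" (rolling 50 ms standard
deviation of the tail angle) exceeds a threshold of 0.1; the laterality index
of a swim is the mean tail angle over its first 70 ms, a good proxy for the
angle turned by a free-swimming fish.  Lateralities pool into a trimodal
distribution (forward + symmetric left/right lobes); the crossing point of
the fitted central and side Gaussians separates forward from directional
swims.  The packaged fallback threshold is the reference operating point
+-0.239 rad.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

from .core import GazeTrace, SwimEvent, TailTrace

__all__ = [
    "DEFAULT_CLASS_THRESHOLD",
    "TrimodalFit",
    "compute_tail_angle",
    "compute_vigor",
    "detect_swims",
    "fit_trimodal",
    "classify_swims",
    "compute_gaze",
]

#: reference forward/directional laterality cut, in rad
DEFAULT_CLASS_THRESHOLD = 0.239

VIGOR_WINDOW_MS = 50.0
SWIM_VIGOR_THRESHOLD = 0.1
LATERALITY_WINDOW_MS = 70.0


def compute_tail_angle(segment_angles: np.ndarray) -> np.ndarray:
    """Tail angle from per-segment angles (segments x frames): difference
    between the mean of the first two and the last two segments."""
    segment_angles = np.asarray(segment_angles, dtype=float)
    if segment_angles.shape[0] < 4:
        raise ValueError("need at least 4 tail segments")
    return segment_angles[-2:].mean(axis=0) - segment_angles[:2].mean(axis=0)


def compute_vigor(tail: TailTrace, window_ms: float = VIGOR_WINDOW_MS) -> np.ndarray:
    """Rolling standard deviation of the tail angle (right-aligned window),
    same length as the input; the start is padded with the first sample so a
    resting offset does not register as vigor."""
    window = int(round(window_ms / 1000.0 * tail.rate))
    if window < 2:
        raise ValueError("vigor window must span at least 2 samples")
    padded = np.concatenate(
        [np.full(window - 1, tail.angle[0] if tail.angle.size else 0.0),
         tail.angle]
    )
    vigor = (
        pd.Series(padded).rolling(window=window).std(ddof=1).to_numpy()[window - 1 :]
    )
    return np.nan_to_num(vigor)


def detect_swims(
    tail: TailTrace,
    threshold: float = SWIM_VIGOR_THRESHOLD,
    min_gap_ms: float = 100.0,
    vigor_window_ms: float = VIGOR_WINDOW_MS,
) -> list:
    """Maximal supra-threshold vigor episodes, merged across gaps shorter
    than ``min_gap_ms``; laterality filled as the mean tail angle over the
    first 70 ms of each episode."""
    vigor = compute_vigor(tail, vigor_window_ms)
    above = vigor > threshold
    if not np.any(above):
        return []
    edges = np.diff(above.astype(int))
    starts = list(np.flatnonzero(edges == 1) + 1)
    ends = list(np.flatnonzero(edges == -1) + 1)
    if above[0]:
        starts.insert(0, 0)
    if above[-1]:
        ends.append(above.size)
    min_gap = int(round(min_gap_ms / 1000.0 * tail.rate))
    merged = [[starts[0], ends[0]]]
    for s, e in zip(starts[1:], ends[1:]):
        if s - merged[-1][1] < min_gap:
            merged[-1][1] = e
        else:
            merged.append([s, e])
    n_lat = max(1, int(round(LATERALITY_WINDOW_MS / 1000.0 * tail.rate)))
    events = []
    for s, e in merged:
        lat = float(tail.angle[s : min(s + n_lat, tail.angle.size)].mean())
        events.append(
            SwimEvent(
                onset_s=s / tail.rate,
                offset_s=e / tail.rate,
                laterality=lat,
            )
        )
    return events


@dataclass
class TrimodalFit:
    """Symmetric three-Gaussian fit of the laterality histogram."""

    central_sd: float
    side_mean: float
    side_sd: float
    weights: tuple  # (central, side) mixture proportions; sides share one
    threshold: float  # positive crossing of central and side densities

    def __post_init__(self):
        if not 0 < self.threshold < self.side_mean:
            raise ValueError("threshold must lie strictly between 0 and side_mean")


def _gauss(x, mu, sd):
    return np.exp(-0.5 * ((x - mu) / sd) ** 2) / (sd * np.sqrt(2 * np.pi))


def trimodal_density(x, w_c, sd_c, w_s, mu_s, sd_s):
    """Density of w_c N(0, sd_c) + w_s N(+mu, sd_s) + w_s N(-mu, sd_s)."""
    return (
        w_c * _gauss(x, 0.0, sd_c)
        + w_s * _gauss(x, mu_s, sd_s)
        + w_s * _gauss(x, -mu_s, sd_s)
    )


def density_intersection(
    w_c, sd_c, w_s, mu_s, sd_s, n_grid: int = 20001
) -> float:
    """Positive abscissa in (0, mu) where the central and side component
    densities cross, by dense-grid sign change (None if none exists)."""
    x = np.linspace(1e-9, mu_s, n_grid)
    diff = w_c * _gauss(x, 0.0, sd_c) - w_s * _gauss(x, mu_s, sd_s)
    sign = np.signbit(diff)
    flips = np.flatnonzero(sign[1:] != sign[:-1])
    if flips.size == 0:
        return None
    k = flips[0]
    # linear interpolation of the zero crossing
    x0, x1, d0, d1 = x[k], x[k + 1], diff[k], diff[k + 1]
    return float(x0 - d0 * (x1 - x0) / (d1 - d0))


def fit_trimodal(lateralities, n_bins: int = 61) -> TrimodalFit:
    """Least-squares fit of the symmetric trimodal density to the binned
    laterality distribution.

    The classification threshold is the positive crossing of the central and
    side component densities.  Raises (suggesting the packaged fallback
    ``DEFAULT_CLASS_THRESHOLD``) if the fit fails or no crossing exists.
    """
    lat = np.asarray(lateralities, dtype=float)
    if lat.size < 30:
        warnings.warn(f"only {lat.size} lateralities; trimodal fit may be unstable")
    span = max(1e-3, np.max(np.abs(lat)))
    counts, edges = np.histogram(lat, bins=n_bins, range=(-span, span), density=True)
    centers = 0.5 * (edges[:-1] + edges[1:])
    directional = np.abs(lat) > 0.3
    frac_dir = max(0.05, min(0.9, directional.mean()))
    p0 = (
        1.0 - frac_dir,
        max(0.03, np.std(lat[~directional]) if np.any(~directional) else 0.1),
        frac_dir / 2,
        max(0.35, np.mean(np.abs(lat[directional])) if np.any(directional) else 0.6),
        0.2,
    )
    bounds = ([0.0, 1e-3, 0.0, 0.05, 1e-3], [2.0, span, 2.0, span, span])
    try:
        popt, _ = curve_fit(
            trimodal_density, centers, counts, p0=p0, bounds=bounds, maxfev=20000
        )
    except RuntimeError as exc:
        raise RuntimeError(
            "trimodal fit did not converge; consider the fixed fallback "
            f"threshold DEFAULT_CLASS_THRESHOLD = {DEFAULT_CLASS_THRESHOLD}"
        ) from exc
    w_c, sd_c, w_s, mu_s, sd_s = popt
    threshold = density_intersection(w_c, sd_c, w_s, mu_s, sd_s)
    if threshold is None:
        raise RuntimeError(
            "central and side densities do not cross in (0, side_mean); "
            "consider the fixed fallback threshold "
            f"DEFAULT_CLASS_THRESHOLD = {DEFAULT_CLASS_THRESHOLD}"
        )
    return TrimodalFit(
        central_sd=float(sd_c),
        side_mean=float(mu_s),
        side_sd=float(sd_s),
        weights=(float(w_c), float(w_s)),
        threshold=threshold,
    )


def classify_swims(events: list, fit: TrimodalFit | float = None) -> list:
    """Assign left/right/forward classes from the laterality index.

    Positive laterality beyond the threshold is a rightward swim, negative a
    leftward one.  ``fit`` may be a :class:`TrimodalFit`, a plain threshold,
    or None for the packaged fallback threshold.
    """
    if fit is None:
        threshold = DEFAULT_CLASS_THRESHOLD
    elif isinstance(fit, TrimodalFit):
        threshold = fit.threshold
    else:
        threshold = float(fit)
    for ev in events:
        if ev.laterality > threshold:
            ev.swim_class = "right"
        elif ev.laterality < -threshold:
            ev.swim_class = "left"
        else:
            ev.swim_class = "forward"
    return events


def compute_gaze(
    left_eye: np.ndarray,
    right_eye: np.ndarray,
    rate: float,
    saccade_velocity_threshold: float = 3.0,
    merge_ms: float = 100.0,
) -> GazeTrace:
    """Gaze = mean of the two eye angles; saccades are episodes where the
    absolute gaze velocity exceeds the threshold (rad/s), merged within
    100 ms."""
    left_eye = np.asarray(left_eye, dtype=float)
    right_eye = np.asarray(right_eye, dtype=float)
    if left_eye.shape != right_eye.shape:
        raise ValueError("left and right eye traces differ in length")
    gaze = 0.5 * (left_eye + right_eye)
    velocity = np.abs(np.diff(gaze)) * rate
    fast = np.flatnonzero(velocity > saccade_velocity_threshold)
    times = []
    merge = merge_ms / 1000.0 * rate
    for i in fast:
        if not times or i - times[-1] > merge:
            times.append(i)
    return GazeTrace(
        angle=gaze, rate=rate, saccade_times=np.asarray(times, float) / rate
    )
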