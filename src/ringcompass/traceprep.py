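"""Raw fluorescence -> smoothed, z-scored dF/F traces.

The baseline is a centered rolling mean (default 900 s window, truncated at
the edges), which removes the slow bleaching trends seen in long recordings;
dF/F is then median-filtered (default 3 frames) and z-scored per ROI.  The
whole chain is invariant to per-ROI multiplicative gain, so absolute
fluorescence units never matter downstream.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy.signal import medfilt

from .core import RawFluorescence, TraceMatrix

__all__ = ["compute_dff", "denoise_zscore", "preprocess", "preprocess_dff"]


def compute_dff(
    raw: RawFluorescence,
    baseline_window_s: float = 900.0,
    baseline_statistic: str = "mean",
    percentile: float = 20.0,
) -> np.ndarray:
    """dF/F with a centered rolling baseline.

    ``baseline_statistic`` is "mean" (default) or "percentile" (rolling
    percentile of the given rank), both with truncated edge windows.  Raises
    if the baseline is non-positive anywhere, naming the offending ROI.
    """
    window = int(round(baseline_window_s * raw.rate))
    if window < 2:
        raise ValueError("baseline window must span at least 2 frames")
    n = raw.n_frames
    window = min(window, n)
    if baseline_statistic == "mean":
        # centered window of constant length, clamped inside the recording
        # (a shrinking edge window would high-pass the slow bump signal
        # unevenly; for traces shorter than the window this reduces to the
        # global mean)
        starts = np.clip(np.arange(n) - window // 2, 0, n - window)
        csum = np.cumsum(
            np.concatenate([np.zeros((raw.n_rois, 1)), raw.values], axis=1),
            axis=1,
        )
        baseline = (csum[:, starts + window] - csum[:, starts]) / window
    elif baseline_statistic == "percentile":
        frame = pd.DataFrame(raw.values.T)
        roll = frame.rolling(window=window, center=True, min_periods=1)
        baseline = roll.quantile(percentile / 100.0).to_numpy().T
    else:
        raise ValueError(f"unknown baseline statistic {baseline_statistic!r}")
    bad = np.flatnonzero(np.min(baseline, axis=1) <= 0)
    if bad.size:
        raise ValueError(
            "non-positive fluorescence baseline for ROI(s) "
            f"{list(np.asarray(raw.roi_ids)[bad[:5]])}; dF/F undefined"
        )
    return (raw.values - baseline) / baseline


def denoise_zscore(
    dff: np.ndarray,
    rate: float,
    roi_ids,
    median_kernel_frames: int = 3,
) -> TraceMatrix:
    """Median-filter then z-score each trace.

    Zero-variance ROIs are dropped with a warning; an all-constant matrix is
    an error because nothing downstream could be computed from it.
    """
    if median_kernel_frames < 1 or median_kernel_frames % 2 == 0:
        raise ValueError("median kernel must be odd and >= 1")
    dff = np.asarray(dff, dtype=float)
    smoothed = (
        medfilt(dff, kernel_size=(1, median_kernel_frames))
        if median_kernel_frames > 1
        else dff
    )
    sd = smoothed.std(axis=1)
    keep = sd > 0
    if not np.any(keep):
        raise ValueError("all traces are constant; nothing to analyze")
    roi_ids = np.asarray(roi_ids)
    if not np.all(keep):
        warnings.warn(
            f"dropping {np.sum(~keep)} zero-variance ROI(s): "
            f"{list(roi_ids[~keep][:5])}"
        )
    smoothed = smoothed[keep]
    values = (smoothed - smoothed.mean(axis=1, keepdims=True)) / smoothed.std(
        axis=1, keepdims=True
    )
    return TraceMatrix(values=values, rate=rate, roi_ids=roi_ids[keep])


def preprocess(
    raw: RawFluorescence,
    baseline_window_s: float = 900.0,
    median_kernel_frames: int = 3,
    baseline_statistic: str = "mean",
) -> TraceMatrix:
    """Full preprocessing chain: rolling dF/F, median filter, z-score."""
    dff = compute_dff(raw, baseline_window_s, baseline_statistic)
    return denoise_zscore(dff, raw.rate, raw.roi_ids, median_kernel_frames)


def preprocess_dff(
    raw: RawFluorescence,
    baseline_window_s: float = 900.0,
    median_kernel_frames: int = 3,
    baseline_statistic: str = "mean",
) -> TraceMatrix:
    """Median-filtered dF/F without z-scoring.

    The population-vector phase weighs ROIs by their dF/F; z-scoring would
    subtract each ROI's temporal mean, which correlates with ring position
    whenever phase occupancy is uneven and would bias the decoded angle
    toward the most-visited phase.  Phase decoding therefore consumes this
    variant while PCA and selection stages use the z-scored traces.
    """
    dff = compute_dff(raw, baseline_window_s, baseline_statistic)
    if median_kernel_frames > 1:
        dff = medfilt(dff, kernel_size=(1, median_kernel_frames))
    return TraceMatrix(values=dff, rate=raw.rate, roi_ids=np.asarray(raw.roi_ids))
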