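"""Network phase decoding and bump characterization.

The instantaneous network phase phi(t) is the angle of the population
vector v(t) = (1/n) sum_i f_i(t) rPC_i, where each trace is first clipped to
its 2nd/98th percentiles (per ROI, over the whole recording) and the
across-ROI mean is subtracted at every frame so that sum_i f_i(t) = 0.  The
phase-zeroed average of the interpolated trace matrix gives the bump profile,
whose full width at half maximum is around pi for sinusoidal tuning.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .core import PhaseTrace, TraceMatrix, wrap_angle
from .rpcspace import RpcEmbedding

__all__ = [
    "BumpProfile",
    "TuningCurve",
    "compute_phase",
    "unwrap_phase",
    "phase_zeroed_profile",
    "estimate_fwhm",
    "tuning_curves",
]


@dataclass
class BumpProfile:
    """Phase-zeroed population activity profile over 100 ring bins."""

    bins: np.ndarray  # bin-center angles, (-pi, pi]
    mean: np.ndarray
    sd: np.ndarray
    fwhm: float
    raw_mean: np.ndarray = None  # non-interpolated consistency variant
    raw_bins: np.ndarray = None

    def __post_init__(self):
        if not 0 < self.fwhm < 2 * np.pi:
            raise ValueError("fwhm must lie in (0, 2*pi)")


@dataclass
class TuningCurve:
    roi_id: object
    phase_bins: np.ndarray
    mean_activity: np.ndarray
    fwhm: float  # nan when the curve is flat or the peak is uncovered


def compute_phase(
    traces: TraceMatrix,
    embedding: RpcEmbedding,
    clip_percentiles: tuple = (2.0, 98.0),
    clip_mode: str = "per_roi",
    subtract_trough: bool = False,
    norm_tol: float = 1e-12,
) -> PhaseTrace:
    """Population-vector phase decoding.

    ``clip_mode`` selects whether the percentile clipping is computed per ROI
    over the recording (default; stable for ~10^2 ROIs) or across ROIs at
    each frame.  With ``subtract_trough`` each clipped trace has its lower
    clip bound subtracted, so every ROI's activation is measured from its
    tuning trough; this removes per-ROI additive offsets (for example from
    baseline estimation) but relies on every ROI's anti-preferred phase
    being visited, so it is off by default.  ROIs with a degenerate clipped
    range are left untouched.
    """
    index = {rid: k for k, rid in enumerate(embedding.roi_ids)}
    try:
        rows = [index[rid] for rid in traces.roi_ids]
    except KeyError as exc:
        raise ValueError(f"embedding does not cover ROI {exc.args[0]}") from exc
    coords = embedding.coords[rows]
    f = traces.values.copy()
    lo, hi = clip_percentiles
    if clip_mode == "per_roi":
        bounds = np.percentile(f, [lo, hi], axis=1)
        f = np.clip(f, bounds[0][:, None], bounds[1][:, None])
    elif clip_mode == "per_frame":
        bounds = np.percentile(f, [lo, hi], axis=0)
        f = np.clip(f, bounds[0][None, :], bounds[1][None, :])
        bounds = np.percentile(f, [lo, hi], axis=1)
    else:
        raise ValueError(f"unknown clip_mode {clip_mode!r}")
    if subtract_trough:
        span = bounds[1] - bounds[0]
        ok = span > norm_tol
        f[ok] = f[ok] - bounds[0][ok, None]
    f = f - f.mean(axis=0, keepdims=True)  # enforce sum_i f_i(t) = 0
    v = f.T @ coords / traces.n_rois  # (frames, 2)
    norm = np.hypot(v[:, 0], v[:, 1])
    if np.mean(norm < norm_tol) > 0.5:
        warnings.warn(
            "population vector is near zero for most frames; phase ill-defined"
        )
    wrapped = wrap_angle(np.arctan2(v[:, 1], v[:, 0]))
    return PhaseTrace(
        wrapped=wrapped,
        unwrapped=unwrap_phase(wrapped),
        vector_norm=norm,
        rate=traces.rate,
    )


def unwrap_phase(wrapped: np.ndarray) -> np.ndarray:
    """Remove the 2*pi discontinuities at +-pi; the first sample is kept."""
    return np.unwrap(np.asarray(wrapped, dtype=float))


def phase_zeroed_profile(
    traces: TraceMatrix,
    embedding: RpcEmbedding,
    phase: PhaseTrace,
    n_bins: int = 100,
) -> BumpProfile:
    """Average bump profile after centering the phase at every frame.

    Traces are interpolated over alpha onto ``n_bins`` ring bins and each
    frame's profile is circularly shifted by -phi(t), so the bump peak sits
    at the center; the mean and s.d. across frames follow.  A non-
    interpolated variant (alpha-sorted ROIs, nearest-bin shift) is computed
    alongside as a consistency check on the resampling.
    """
    if traces.n_rois < 8:
        raise ValueError("need at least 8 ROIs for a stable profile")
    index = {rid: k for k, rid in enumerate(embedding.roi_ids)}
    rows = np.array([index[rid] for rid in traces.roi_ids])
    alpha = embedding.alpha[rows]
    order = np.argsort(alpha)
    alpha_sorted = alpha[order]
    values_sorted = traces.values[order]
    centers = -np.pi + (np.arange(n_bins) + 0.5) * 2 * np.pi / n_bins
    # interpolated matrix (bins x frames), then per-frame circular shift:
    # the value plotted at ring angle b after zeroing is the activity at
    # angle b + phi(t), so the peak (at phi) moves to b = 0.
    shifted = np.empty((n_bins, phase.wrapped.size))
    a = np.concatenate(
        [alpha_sorted - 2 * np.pi, alpha_sorted, alpha_sorted + 2 * np.pi]
    )
    v3 = np.vstack([values_sorted] * 3)
    for t in range(phase.wrapped.size):
        targets = wrap_angle(centers + phase.wrapped[t])
        shifted[:, t] = np.interp(targets, a, v3[:, t])
    mean, sd = shifted.mean(axis=1), shifted.std(axis=1)
    # raw-sorted variant: shift whole ROIs by the nearest integer bin
    n = traces.n_rois
    raw_shifted = np.empty_like(values_sorted)
    for t in range(phase.wrapped.size):
        k = int(round(phase.wrapped[t] / (2 * np.pi / n)))
        raw_shifted[:, t] = np.roll(values_sorted[:, t], -k)
    raw_mean = raw_shifted.mean(axis=1)
    return BumpProfile(
        bins=centers,
        mean=mean,
        sd=sd,
        fwhm=estimate_fwhm(mean, centers),
        raw_mean=raw_mean,
        raw_bins=alpha_sorted,
    )


def estimate_fwhm(profile: np.ndarray, bins: np.ndarray = None, tol: float = 1e-9) -> float:
    """Full width at half maximum of a circular activity profile.

    The baseline is the profile minimum; the half level is halfway between
    baseline and peak.  Crossings flanking the peak are located by linear
    interpolation walking circularly away from the peak bin.
    """
    profile = np.asarray(profile, dtype=float)
    n = profile.size
    if bins is None:
        bins = -np.pi + (np.arange(n) + 0.5) * 2 * np.pi / n
    lo, hi = profile.min(), profile.max()
    if hi - lo < tol:
        raise ValueError("flat profile: no bump")
    half = lo + 0.5 * (hi - lo)
    peak = int(np.argmax(profile))
    widths = []
    for step in (1, -1):
        prev, k = peak, (peak + step) % n
        travelled = 0.0
        while profile[k] > half and k != peak:
            travelled += abs(wrap_angle(bins[k] - bins[prev]))
            prev, k = k, (k + step) % n
        seg = abs(wrap_angle(bins[k] - bins[prev]))
        frac = (profile[prev] - half) / (profile[prev] - profile[k])
        widths.append(travelled + frac * seg)
    return float(widths[0] + widths[1])


def tuning_curves(
    traces: TraceMatrix, phase: PhaseTrace, n_bins: int = 36
) -> list:
    """Per-ROI mean activity binned by the wrapped network phase.

    Warns if the recording covers less than one full phase revolution.  Empty
    bins are NaN; the FWHM of a curve whose peak region is uncovered or flat
    is NaN.
    """
    span = phase.unwrapped.max() - phase.unwrapped.min()
    if span < 2 * np.pi:
        warnings.warn(
            "phase covers less than one revolution; tuning curves incomplete"
        )
    edges = np.linspace(-np.pi, np.pi, n_bins + 1)
    centers = 0.5 * (edges[:-1] + edges[1:])
    which = np.clip(np.digitize(phase.wrapped, edges) - 1, 0, n_bins - 1)
    curves = []
    for i in range(traces.n_rois):
        mean_act = np.full(n_bins, np.nan)
        for b in range(n_bins):
            sel = which == b
            if np.any(sel):
                mean_act[b] = traces.values[i, sel].mean()
        covered = ~np.isnan(mean_act)
        fwhm = np.nan
        if covered.sum() >= 3:
            filled = mean_act.copy()
            if not covered.all():
                filled[~covered] = np.interp(
                    centers[~covered], centers[covered], mean_act[covered],
                    period=2 * np.pi,
                )
            try:
                fwhm = estimate_fwhm(filled, centers)
            except ValueError:
                fwhm = np.nan
        curves.append(
            TuningCurve(
                roi_id=traces.roi_ids[i],
                phase_bins=centers,
                mean_activity=mean_act,
                fwhm=fwhm,
            )
        )
    return curves
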