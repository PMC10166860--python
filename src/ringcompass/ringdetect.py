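"""Selection of ring (r1pi-like) ROIs by anticorrelation structure.

Ring neurons come in anticorrelated pairs (a partner at angle pi on the
ring), so a ROI belongs to the provisional selection iff its minimum
correlation with any other ROI falls below a negative threshold (between
-0.75 and -0.5 in practice; default -0.6, optionally chosen by scanning for
the roundest embedding).  A second pass drops ROIs whose row of the
alpha-sorted correlation matrix deviates from the ideal cos(alpha_i -
alpha_j) template - a reproducible surrogate for the manual
discontinuity-based curation the selection replaces.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .core import TraceMatrix

__all__ = ["RingSelection", "select_anticorrelated", "exclude_by_sorted_matrix",
           "ring_quality"]


@dataclass
class RingSelection:
    selected_ids: np.ndarray
    threshold_used: float
    quality: float = np.nan
    excluded_ids: dict = field(default_factory=dict)  # roi_id -> reason

    def __post_init__(self):
        overlap = set(np.asarray(self.selected_ids).tolist()) & set(
            self.excluded_ids
        )
        if overlap:
            raise ValueError(f"ROI(s) both selected and excluded: {overlap}")


def ring_quality(traces: TraceMatrix, roi_ids) -> float:
    """1 - coefficient of variation of the embedding projection radii
    (1 for a perfect circle, lower for scattered selections)."""
    from .rpcspace import fit_circle, pca_neuron_embedding

    sub = traces.subset(roi_ids)
    coords, _ = pca_neuron_embedding(sub)
    circle = fit_circle(coords)
    radii = np.hypot(*(coords - circle.center).T)
    return float(1.0 - radii.std() / radii.mean())


def select_anticorrelated(
    traces: TraceMatrix,
    threshold: float = -0.6,
    scan: bool = False,
    scan_range: tuple = (-0.75, -0.5),
    scan_steps: int = 6,
) -> RingSelection:
    """Keep ROIs whose minimum pairwise correlation is at or below the
    threshold.

    With ``scan=True`` the threshold is chosen from a grid over
    ``scan_range`` to maximize the ring-quality score of the selection,
    replacing per-fish manual tuning with a reproducible rule.
    """
    if traces.n_rois < 8:
        raise ValueError("need at least 8 ROIs")
    corr = np.corrcoef(traces.values)
    np.fill_diagonal(corr, np.nan)
    min_corr = np.nanmin(corr, axis=1)

    def _select(thr):
        return traces.roi_ids[min_corr <= thr]

    quality = np.nan
    if scan:
        best = None
        for thr in np.linspace(*scan_range, scan_steps):
            ids = _select(thr)
            if ids.size < 8:
                continue
            q = ring_quality(traces, ids)
            if best is None or q > best[0]:
                best = (q, thr, ids)
        if best is None:
            warnings.warn("threshold scan found no viable selection")
            return RingSelection(
                selected_ids=np.array([]), threshold_used=threshold
            )
        quality, threshold, selected = best
    else:
        selected = _select(threshold)
        if selected.size >= 8:
            quality = ring_quality(traces, selected)
    if selected.size == 0:
        warnings.warn(
            f"no ROI has a partner correlation <= {threshold}; empty selection"
        )
    return RingSelection(
        selected_ids=np.asarray(selected),
        threshold_used=float(threshold),
        quality=quality,
    )


def exclude_by_sorted_matrix(
    traces: TraceMatrix,
    provisional: RingSelection,
    alpha_order: np.ndarray,
    template_min_corr: float = 0.5,
) -> RingSelection:
    """Drop ROIs that break the continuity of the alpha-sorted correlation
    matrix.

    With ROIs sorted by their ring angle, the correlation matrix of an ideal
    sinusoidally tuned ring is cos(alpha_i - alpha_j).  A ROI is excluded
    iff the Pearson correlation between its row of the sorted matrix and the
    template row falls below ``template_min_corr`` (set -1 to disable).
    ``alpha_order`` gives each provisional ROI's angle, aligned with
    ``provisional.selected_ids``.
    """
    ids = np.asarray(provisional.selected_ids)
    if ids.size == 0:
        raise ValueError("provisional selection is empty")
    alpha_order = np.asarray(alpha_order, dtype=float)
    sub = traces.subset(ids)
    order = np.argsort(alpha_order)
    alpha_sorted = alpha_order[order]
    corr = np.corrcoef(sub.values[order])
    template = np.cos(alpha_sorted[:, None] - alpha_sorted[None, :])
    off = ~np.eye(ids.size, dtype=bool)
    keep = np.ones(ids.size, dtype=bool)
    row_scores = np.empty(ids.size)
    for k in range(ids.size):
        c, t = corr[k, off[k]], template[k, off[k]]
        row_scores[k] = np.corrcoef(c, t)[0, 1]
        if row_scores[k] < template_min_corr:
            keep[k] = False
    excluded = dict(provisional.excluded_ids)
    sorted_ids = ids[order]
    for k in np.flatnonzero(~keep):
        excluded[sorted_ids[k]] = (
            f"template correlation {row_scores[k]:.3f} < {template_min_corr}"
        )
    kept_ids = sorted_ids[keep]
    quality = (
        ring_quality(traces, kept_ids) if kept_ids.size >= 8 else np.nan
    )
    return RingSelection(
        selected_ids=kept_ids,
        threshold_used=provisional.threshold_used,
        quality=quality,
        excluded_ids=excluded,
    )
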