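"""Skeleton morphometry and dIPN functional-correlation geometry.

Reconstructed hindbrain neurons project into the dorsal interpeduncular
nucleus (dIPN) with a mirrored layout: a neuron whose dendrite sits at
lateral distance d from the midline extends its axon to distance d on the
other side.  This module quantifies that geometry from SWC skeletons
(compartment centroids over branching points, midline distances, pairwise
branch-point offset histograms) and from two-photon pixel data (2-D spatial
autocorrelation in 3.5 um bins), whose side lobes reflect the mirror offset.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import pearsonr

__all__ = [
    "Skeleton",
    "MorphometryRow",
    "AutocorrMap",
    "load_skeleton",
    "save_skeleton",
    "branch_points",
    "compartment_centroids",
    "morphometry_correlations",
    "branchpoint_distance_profile",
    "dipn_autocorrelation",
]

SWC_COLUMNS = ["id", "type", "x", "y", "z", "radius", "parent"]
#: SWC structure identifiers -> compartment labels
SWC_TYPE_LABELS = {1: "soma", 2: "axon", 3: "dendrite"}


@dataclass
class Skeleton:
    """SWC-style node tree with compartment labels.

    ``nodes`` has the canonical SWC columns; coordinates are micrometres in
    a frame whose coronal midline sits at ``midline_x``.  Validated to be a
    single connected tree.
    """

    nodes: pd.DataFrame
    midline_x: float = 0.0
    neuron_id: str = ""

    def __post_init__(self):
        nd = self.nodes
        if list(nd.columns) != SWC_COLUMNS:
            raise ValueError(f"skeleton table must have columns {SWC_COLUMNS}")
        ids = nd["id"].to_numpy()
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate node ids")
        parents = nd["parent"].to_numpy()
        roots = np.flatnonzero(parents == -1)
        if roots.size != 1:
            raise ValueError(f"expected exactly one root, found {roots.size}")
        known = set(ids)
        dangling = [p for p in parents if p != -1 and p not in known]
        if dangling:
            raise ValueError(f"dangling parent reference(s): {dangling[:5]}")
        # cycle check: every node must reach the root
        parent_of = dict(zip(ids, parents))
        for start in ids:
            seen, node = set(), start
            while node != -1:
                if node in seen:
                    raise ValueError(f"cycle detected at node {node}")
                seen.add(node)
                node = parent_of[node]

    @property
    def compartments(self) -> pd.Series:
        return self.nodes["type"].map(SWC_TYPE_LABELS).fillna("unlabeled")


def load_skeleton(
    path, label_source=None, midline_x: float = 0.0, neuron_id: str = ""
) -> Skeleton:
    """Read an SWC file (optionally with a sidecar compartment table).

    ``label_source`` maps node id -> SWC type code (dict or two-column CSV
    path) and overrides the file's own type column.
    """
    nodes = pd.read_csv(
        path, sep=r"\s+", comment="#", header=None, names=SWC_COLUMNS
    )
    nodes = nodes.astype(
        {"id": int, "type": int, "x": float, "y": float, "z": float,
         "radius": float, "parent": int}
    )
    if label_source is not None:
        if not isinstance(label_source, dict):
            table = pd.read_csv(label_source)
            label_source = dict(zip(table.iloc[:, 0], table.iloc[:, 1]))
        nodes["type"] = nodes["id"].map(label_source).fillna(nodes["type"]).astype(int)
    return Skeleton(nodes=nodes, midline_x=midline_x, neuron_id=neuron_id)


def save_skeleton(skel: Skeleton, path) -> None:
    """Write the node table in plain SWC (whitespace-separated)."""
    skel.nodes.to_csv(path, sep=" ", header=False, index=False)


def branch_points(skel: Skeleton) -> pd.DataFrame:
    """Nodes with at least two children (terminal and pass-through nodes are
    not branching points)."""
    counts = skel.nodes["parent"].value_counts()
    branch_ids = counts[counts >= 2].index
    return skel.nodes[skel.nodes["id"].isin(branch_ids)]


@dataclass
class MorphometryRow:
    neuron_id: str
    dendrite_centroid: np.ndarray
    axon_centroid: np.ndarray
    dendrite_midline_dist: float
    axon_midline_dist: float
    soma_ap: float


def compartment_centroids(
    skel: Skeleton, fallback_all_nodes: bool = False
) -> MorphometryRow:
    """Centroids of dendritic and axonal branching points and their midline
    distances; the soma's antero-posterior position comes from the soma node.

    A compartment with no branching point yields a NaN centroid (flagged)
    unless ``fallback_all_nodes`` uses the all-node centroid instead.
    """
    comp = skel.compartments
    bp = branch_points(skel)
    bp_comp = comp.loc[bp.index]
    out = {}
    for name in ("dendrite", "axon"):
        sel = bp[ (bp_comp == name).to_numpy() ]
        if len(sel) == 0 and fallback_all_nodes:
            sel = skel.nodes[(comp == name).to_numpy()]
        if len(sel) == 0:
            out[name] = np.full(3, np.nan)
        else:
            out[name] = sel[["x", "y", "z"]].mean().to_numpy()
    soma = skel.nodes[(comp == "soma").to_numpy()]
    soma_ap = float(soma["y"].mean()) if len(soma) else np.nan
    return MorphometryRow(
        neuron_id=skel.neuron_id,
        dendrite_centroid=out["dendrite"],
        axon_centroid=out["axon"],
        dendrite_midline_dist=float(abs(out["dendrite"][0] - skel.midline_x)),
        axon_midline_dist=float(abs(out["axon"][0] - skel.midline_x)),
        soma_ap=soma_ap,
    )


def morphometry_correlations(rows: list) -> dict:
    """Pearson correlations of the mirrored-projection geometry.

    dendrite vs axon midline distance (strongly negative for mirrored
    arbors) and soma antero-posterior position vs dendrite midline distance.
    """
    if len(rows) < 3:
        raise ValueError("need at least 3 neurons")
    dd = np.array([r.dendrite_midline_dist for r in rows])
    ad = np.array([r.axon_midline_dist for r in rows])
    ap = np.array([r.soma_ap for r in rows])
    for name, col in (("dendrite", dd), ("axon", ad), ("soma_ap", ap)):
        if np.std(col) == 0:
            raise ValueError(f"zero-variance column: {name}")
    r_da = pearsonr(dd, ad)
    r_ap = pearsonr(ap, dd)
    return {
        "dendrite_axon_r": float(r_da.statistic),
        "dendrite_axon_p": float(r_da.pvalue),
        "soma_ap_dendrite_r": float(r_ap.statistic),
        "soma_ap_dendrite_p": float(r_ap.pvalue),
        "n": len(rows),
    }


def branchpoint_distance_profile(
    skels: list, bin_um: float = 3.5, max_dist_um: float = None
):
    """2-D histogram of signed offsets between all ordered branch-point
    pairs, axons and dendrites pooled.

    Offsets are (delta frontal, delta sagittal) = (delta x, delta y).
    Returns (counts, x_edges, y_edges); the total count is N(N-1) for N
    branch points when no cutoff is applied.
    """
    pts = []
    for skel in skels:
        bp = branch_points(skel)
        pts.append(bp[["x", "y"]].to_numpy())
    pts = np.vstack(pts)
    if pts.shape[0] < 2:
        raise ValueError("need at least 2 branch points")
    dx = (pts[:, 0][None, :] - pts[:, 0][:, None]).ravel()
    dy = (pts[:, 1][None, :] - pts[:, 1][:, None]).ravel()
    # drop self-pairs only (identical coordinates across pairs are kept)
    self_idx = np.arange(pts.shape[0]) * pts.shape[0] + np.arange(pts.shape[0])
    mask = np.ones(dx.size, dtype=bool)
    mask[self_idx] = False
    dx, dy = dx[mask], dy[mask]
    if max_dist_um is None:
        max_dist_um = max(np.abs(dx).max(), np.abs(dy).max()) + bin_um
    n_bins = int(np.ceil(max_dist_um / bin_um))
    edges = np.arange(-n_bins, n_bins + 1) * bin_um
    counts, xe, ye = np.histogram2d(dx, dy, bins=[edges, edges])
    return counts, xe, ye


@dataclass
class AutocorrMap:
    """Average correlation as a function of 2-D bin offset.

    ``mean_correlation[i, j]`` is the average Pearson correlation between
    focal bins and bins offset by ``(dx_um[i], dy_um[j])``; ``n_pairs``
    counts the ordered bin pairs entering each offset.
    """

    dx_um: np.ndarray
    dy_um: np.ndarray
    mean_correlation: np.ndarray
    n_pairs: np.ndarray
    bin_um: float

    def at_offset(self, dx: float, dy: float) -> float:
        i = int(np.argmin(np.abs(self.dx_um - dx)))
        j = int(np.argmin(np.abs(self.dy_um - dy)))
        return float(self.mean_correlation[i, j])


def dipn_autocorrelation(
    frames: np.ndarray,
    mask: np.ndarray,
    pixel_size_um: float,
    bin_um: float = 3.5,
) -> AutocorrMap:
    """2-D autocorrelation of neuropil activity in square spatial bins.

    The masked area is divided into ``bin_um`` x ``bin_um`` bins; each bin's
    average trace is z-scored; correlations between all bin pairs are sorted
    by their signed per-axis offsets and averaged per offset.  Zero-variance
    bins are excluded (tracked via ``n_pairs``).
    """
    frames = np.asarray(frames, dtype=float)
    mask = np.asarray(mask, dtype=bool)
    if frames.ndim != 3 or frames.shape[1:] != mask.shape:
        raise ValueError("frames must be (T, H, W) matching the mask")
    if not mask.any():
        raise ValueError("empty mask")
    h, w = mask.shape
    px_per_bin = bin_um / pixel_size_um
    rows, cols = np.nonzero(mask)
    bx = np.floor(cols / px_per_bin).astype(int)
    by = np.floor(rows / px_per_bin).astype(int)
    keys = np.unique(np.column_stack([bx, by]), axis=0)
    traces, coords = [], []
    for kx, ky in keys:
        sel = (bx == kx) & (by == ky)
        tr = frames[:, rows[sel], cols[sel]].mean(axis=1)
        if np.std(tr) == 0:
            continue
        traces.append((tr - tr.mean()) / tr.std())
        coords.append((kx, ky))
    if len(traces) < 2:
        raise ValueError("fewer than two usable bins")
    traces = np.asarray(traces)
    coords = np.asarray(coords)
    corr = np.corrcoef(traces)
    dx = coords[:, 0][None, :] - coords[:, 0][:, None]
    dy = coords[:, 1][None, :] - coords[:, 1][:, None]
    max_dx, max_dy = np.abs(dx).max(), np.abs(dy).max()
    acc = np.zeros((2 * max_dx + 1, 2 * max_dy + 1))
    cnt = np.zeros_like(acc, dtype=int)
    ix, iy = dx + max_dx, dy + max_dy
    np.add.at(acc, (ix.ravel(), iy.ravel()), corr.ravel())
    np.add.at(cnt, (ix.ravel(), iy.ravel()), 1)
    with np.errstate(invalid="ignore"):
        mean_corr = np.where(cnt > 0, acc / np.maximum(cnt, 1), np.nan)
    return AutocorrMap(
        dx_um=np.arange(-max_dx, max_dx + 1) * bin_um,
        dy_um=np.arange(-max_dy, max_dy + 1) * bin_um,
        mean_correlation=mean_corr,
        n_pairs=cnt,
        bin_um=bin_um,
    )
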