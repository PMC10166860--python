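"""Rotated-PC circular embedding of ring neurons and its anatomical anchoring.

Two complementary PCA views are used: the *state-space* projection (time
points as observations) in which the population trajectory lives on a circle,
and the *neuron embedding* (ROIs as observations over the time axis) in which
the neurons themselves form a circle.  The neuron embedding is normalized to
a unit circle (hyper least-squares circle fit), then rotated/reflected so
that an anatomically weighted rostral anchor points to pi and a rightward
anchor to -pi/2; the resulting per-ROI angle alpha follows the caudal-zero,
clockwise-positive convention.  The Fisher-Lee T-linear circular correlation
quantifies how well alpha matches the anatomical angle.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA

from .core import TraceMatrix, anatomical_angle, wrap_angle

__all__ = [
    "CircleFit",
    "RpcEmbedding",
    "AnatomyStats",
    "pca_state_space",
    "pca_neuron_embedding",
    "fit_circle",
    "align_embedding",
    "fisher_lee_correlation",
    "anatomy_stats",
]


@dataclass
class CircleFit:
    center: np.ndarray
    radius: float

    def __post_init__(self):
        self.center = np.asarray(self.center, dtype=float)
        if self.radius <= 0:
            raise ValueError("radius must be positive")


@dataclass
class RpcEmbedding:
    """Per-ROI coordinates on the registered unit circle.

    ``coords`` are the rotated-PC coordinates (circle centered on the origin,
    radius ~1), ``alpha`` the per-ROI angles in (-pi, pi], ``transform``
    records the normalization and alignment applied, ``anchor_angles`` the
    residual misfits (theta1, theta2) of the rostral and rightward anchors.
    """

    coords: np.ndarray
    alpha: np.ndarray
    roi_ids: np.ndarray
    transform: dict
    anchor_angles: tuple


@dataclass
class AnatomyStats:
    rho_t: float
    sinusoid_fit_residuals: dict  # per-axis residual sum of squares
    shuffle_residuals: dict  # per-axis arrays over shuffles

    def __post_init__(self):
        if not -1.0 - 1e-9 <= self.rho_t <= 1.0 + 1e-9:
            raise ValueError("rho_t out of [-1, 1]")


def pca_state_space(traces: TraceMatrix, k: int = 2):
    """PCA of the population state (time points as observations in ROI
    space).  Returns (scores (frames x k), explained-variance ratios)."""
    if traces.n_rois < k:
        raise ValueError(f"need at least {k} ROIs")
    if np.linalg.matrix_rank(traces.values - traces.values.mean(1, keepdims=True)) < k:
        raise ValueError(f"trace matrix has rank below {k}")
    pca = PCA(n_components=k, svd_solver="full")  # deterministic
    scores = pca.fit_transform(traces.values.T)
    return scores, pca.explained_variance_ratio_


def pca_neuron_embedding(traces: TraceMatrix):
    """PCA over the time axis (ROIs as observations); each ROI is mapped to
    its first-two-component scores.  Returns (coords (n x 2), evr)."""
    if traces.n_rois < 3:
        raise ValueError("need at least 3 ROIs")
    centered = traces.values - traces.values.mean(axis=0, keepdims=True)
    if np.linalg.matrix_rank(centered) < 2:
        raise ValueError("degenerate covariance: neuron embedding undefined")
    pca = PCA(n_components=2, svd_solver="full")  # deterministic
    coords = pca.fit_transform(traces.values)
    return coords, pca.explained_variance_ratio_


def fit_circle(points: np.ndarray) -> CircleFit:
    """Algebraic 'hyper' least-squares circle fit (Al-Sharadqah & Chernov).

    Solves the generalized eigenproblem M A = eta H A for the algebraic
    circle parameters; unbiased to leading order and exact on noiseless
    circles.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2 or pts.shape[0] < 3:
        raise ValueError("need >= 3 two-dimensional points")
    x, y = pts[:, 0], pts[:, 1]
    if np.linalg.matrix_rank(pts - pts.mean(0)) < 2:
        raise ValueError("points are collinear; no circle fit")
    z = x * x + y * y
    design = np.column_stack([z, x, y, np.ones_like(x)])
    m = design.T @ design / pts.shape[0]
    zm, xm, ym = z.mean(), x.mean(), y.mean()
    h = np.array(
        [
            [8 * zm, 4 * xm, 4 * ym, 2],
            [4 * xm, 1, 0, 0],
            [4 * ym, 0, 1, 0],
            [2, 0, 0, 0],
        ]
    )
    evals, evecs = np.linalg.eig(np.linalg.solve(h, m))
    evals, evecs = np.real(evals), np.real(evecs)
    # smallest non-negative eigenvalue (up to rounding) gives the hyper fit
    order = np.argsort(np.where(evals < -1e-12 * np.abs(evals).max(), np.inf, evals))
    a = evecs[:, order[0]]
    if abs(a[0]) < 1e-12:
        raise ValueError("degenerate circle fit (infinite radius)")
    center = -a[1:3] / (2 * a[0])
    r2 = (a[1] ** 2 + a[2] ** 2 - 4 * a[0] * a[3]) / (4 * a[0] ** 2)
    return CircleFit(center=center, radius=float(np.sqrt(r2)))


def _anchor_vector(coords: np.ndarray, weights: np.ndarray) -> np.ndarray:
    w = weights - weights.mean()
    return (w[:, None] * coords).sum(axis=0)


def align_embedding(
    coords: np.ndarray,
    rois: pd.DataFrame,
    grid_deg: float = 0.1,
    anchor_tol: float = 1e-8,
) -> RpcEmbedding:
    """Normalize a neuron embedding to the unit circle and anchor it
    anatomically.

    The rostral anchor is the embedding-coordinate average weighted by the
    mean-centered rostro-caudal position (rostral positive); its target
    direction is pi (since caudal ROIs have alpha = 0).  The rightward anchor
    is weighted by the centered rightward position and targets -pi/2.  An
    exhaustive search over rotations (0.1 degree grid) x {identity,
    reflection} minimizes |theta1| + |theta2|, tie-breaking toward the
    smaller rotation; the winning transform defines alpha.
    """
    coords = np.asarray(coords, dtype=float)
    circle = fit_circle(coords)
    unit = (coords - circle.center) / circle.radius
    w_rostral = rois["y_rc"].to_numpy(dtype=float)
    w_rightward = -rois["x_lr"].to_numpy(dtype=float)  # x_lr is left-positive
    a_rost = _anchor_vector(unit, w_rostral)
    a_right = _anchor_vector(unit, w_rightward)
    scale = np.abs(unit).max() * len(unit)
    if np.hypot(*a_rost) < anchor_tol * scale or np.hypot(*a_right) < anchor_tol * scale:
        raise ValueError(
            "anchor vector vanishes: ROI set is anatomically unpolarized"
        )
    ang_rost, ang_right = np.arctan2(a_rost[1], a_rost[0]), np.arctan2(
        a_right[1], a_right[0]
    )
    thetas = np.deg2rad(np.arange(-180.0, 180.0, grid_deg))
    best = None
    for reflect in (False, True):
        s = -1.0 if reflect else 1.0
        t1 = np.abs(wrap_angle(s * ang_rost + thetas - np.pi))
        t2 = np.abs(wrap_angle(s * ang_right + thetas + np.pi / 2))
        cost = t1 + t2
        k = int(np.lexsort((np.abs(thetas), cost))[0])
        if best is None or cost[k] < best[0] - 1e-15:
            best = (cost[k], thetas[k], reflect, t1[k], t2[k])
    _, theta, reflect, th1, th2 = best
    transformed = unit.copy()
    if reflect:
        transformed[:, 1] *= -1
    rot = np.array(
        [[np.cos(theta), -np.sin(theta)], [np.sin(theta), np.cos(theta)]]
    )
    transformed = transformed @ rot.T
    alpha = wrap_angle(np.arctan2(transformed[:, 1], transformed[:, 0]))
    return RpcEmbedding(
        coords=transformed,
        alpha=alpha,
        roi_ids=rois["roi_id"].to_numpy() if "roi_id" in rois else np.arange(len(rois)),
        transform={
            "center": circle.center.tolist(),
            "radius": circle.radius,
            "rotation_rad": float(theta),
            "reflected": bool(reflect),
        },
        anchor_angles=(float(th1), float(th2)),
    )


def fisher_lee_correlation(theta, phi) -> float:
    """Fisher-Lee T-linear circular-circular association coefficient.

    rho_T = sum_{i<j} sin(ti - tj) sin(pi - pj) /
            sqrt(sum_{i<j} sin^2(ti - tj) * sum_{i<j} sin^2(pi - pj))
    """
    theta = np.asarray(theta, dtype=float)
    phi = np.asarray(phi, dtype=float)
    if theta.shape != phi.shape or theta.ndim != 1:
        raise ValueError("theta and phi must be equal-length 1-D arrays")
    st = np.sin(theta[:, None] - theta[None, :])
    sp = np.sin(phi[:, None] - phi[None, :])
    num = np.sum(np.triu(st * sp, k=1))
    den = np.sqrt(
        np.sum(np.triu(st * st, k=1)) * np.sum(np.triu(sp * sp, k=1))
    )
    if den == 0:
        raise ValueError("degenerate angle set (all angles equal)")
    return float(num / den)


def _sinusoid_residual(alpha: np.ndarray, coord: np.ndarray) -> float:
    """Residual SS of the least-squares fit coord ~ a sin(alpha) + b
    cos(alpha) + c."""
    design = np.column_stack([np.sin(alpha), np.cos(alpha), np.ones_like(alpha)])
    _, res, *_ = np.linalg.lstsq(design, coord, rcond=None)
    if res.size:
        return float(res[0])
    fitted = design @ np.linalg.lstsq(design, coord, rcond=None)[0]
    return float(np.sum((coord - fitted) ** 2))


def anatomy_stats(
    embedding: RpcEmbedding,
    rois: pd.DataFrame,
    n_shuffles: int = 1000,
    rng=None,
) -> AnatomyStats:
    """Quantify the anatomical organization of the embedding.

    Fisher-Lee correlation between alpha and the anatomical angle, plus
    per-axis sinusoid fits of the anatomical coordinates over alpha compared
    with fits after randomly reassigning coordinates to ROIs.
    """
    if len(rois) < 8:
        raise ValueError("need at least 8 ROIs")
    if rng is None:
        rng = np.random.default_rng(0)
    anat = anatomical_angle(rois["x_lr"].to_numpy(), rois["y_rc"].to_numpy())
    rho = fisher_lee_correlation(embedding.alpha, anat)
    residuals, shuffles = {}, {}
    for axis in ("x_lr", "y_rc"):
        coord = rois[axis].to_numpy(dtype=float)
        residuals[axis] = _sinusoid_residual(embedding.alpha, coord)
        draws = np.empty(n_shuffles)
        for k in range(n_shuffles):
            draws[k] = _sinusoid_residual(embedding.alpha, rng.permutation(coord))
        shuffles[axis] = draws
    return AnatomyStats(
        rho_t=rho, sinusoid_fit_residuals=residuals, shuffle_residuals=shuffles
    )
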