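"""Convex-hull analysis of pre-movement neural state space.

All hull comparisons for one session are carried out in a single shared
low-dimensional embedding (top principal components of the session's state
vectors) because hull volumes are basis-dependent. A k-nearest-neighbor
triage removes the most isolated points before any hull is evaluated.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import ConvexHull, Delaunay, QhullError, cKDTree
from sklearn.decomposition import PCA

from .exceptions import DegenerateDataError, InsufficientDataError, ParameterError
from .preprocess import TrialSet

__all__ = [
    "HullMetrics", "HullOverlap", "knn_triage", "hull_volume", "session_embedding",
    "hull_ratio_curve", "auc_ratio", "hull_overlap",
]


@dataclass
class HullMetrics:
    """Hull summary for one session: ratio curve over offsets and its AUC."""

    dim: int
    session_volume: float
    offsets_s: np.ndarray
    ratio_curve: np.ndarray            # in [0, 1], NaN where undefined
    auc: float | None = None           # normalized by the random-trigger curve
    overlap: dict = field(default_factory=dict)


@dataclass
class HullOverlap:
    """Monte-Carlo hull intersection fractions, both directions."""

    a_in_b: float
    b_in_a: float

    @property
    def mean(self) -> float:
        return 0.5 * (self.a_in_b + self.b_in_a)


def knn_triage(points: np.ndarray, frac: float = 0.10, k: int = 10) -> np.ndarray:
    """Drop the ``frac`` fraction of points with the largest mean distance to
    their k nearest neighbors; keeps ceil((1 - frac) * n) points."""
    points = np.asarray(points, dtype=float)
    n = points.shape[0]
    if frac == 0:
        return points
    if n < k + 2:
        raise InsufficientDataError(f"need at least k + 2 = {k + 2} points")
    tree = cKDTree(points)
    dist, _ = tree.query(points, k=k + 1)      # first neighbor is the point itself
    score = dist[:, 1:].mean(axis=1)
    n_keep = int(np.ceil((1.0 - frac) * n))
    keep = np.argsort(score, kind="stable")[:n_keep]
    return points[np.sort(keep)]


def session_embedding(points: np.ndarray, dim: int = 3) -> PCA:
    """Shared PCA basis (top ``dim`` components) for all hull computations of
    one session."""
    points = np.asarray(points, dtype=float)
    if points.shape[1] < dim:
        raise ParameterError(f"points have {points.shape[1]} dims; need >= {dim}")
    pca = PCA(n_components=dim, svd_solver="full")
    pca.fit(points)
    return pca


def hull_volume(points: np.ndarray, embed_dim: int = 3,
                basis: PCA | None = None) -> float:
    """Convex-hull hypervolume of the points in the (shared) embedding.

    Points already at the embedding dimension are used as-is; otherwise they
    are projected with ``basis`` (required for cross-set comparability). A
    degenerate (affinely dependent) set yields volume 0 with a warning.
    """
    X = np.asarray(points, dtype=float)
    if X.ndim != 2:
        raise ParameterError("points must be a 2-D array")
    if X.shape[1] != embed_dim:
        if basis is None:
            raise ParameterError("points above the embedding dimension need a shared basis")
        X = basis.transform(X)
    if X.shape[0] < embed_dim + 1:
        warnings.warn("too few points for a full-dimensional hull; volume 0")
        return 0.0
    try:
        return float(ConvexHull(X).volume)
    except QhullError:
        warnings.warn("degenerate point set (coplanar); volume 0")
        return 0.0


def hull_ratio_curve(session_points: np.ndarray, trials: TrialSet,
                     offsets_s=None, seg_len_s: float = 1.0, embed_dim: int = 3,
                     triage_frac: float = 0.10, k: int = 10,
                     min_points: int = 20) -> HullMetrics:
    """Per-offset hull ratio: hull(trial vectors in the 1-s segment ending at
    the offset) / hull(all session vectors), both after triage, in one shared
    embedding. Contraction of the ratio toward t = 0 indicates pre-movement
    stereotypy.
    """
    if offsets_s is None:
        offsets_s = np.arange(-10.0, 0.5, 1.0)
    offsets_s = np.asarray(offsets_s, dtype=float)

    basis = session_embedding(session_points, dim=embed_dim)
    all_emb = basis.transform(np.asarray(session_points, dtype=float))
    denom = hull_volume(knn_triage(all_emb, frac=triage_frac, k=k), embed_dim)
    if denom == 0:
        raise DegenerateDataError("session hull is degenerate")

    ratios = np.full(offsets_s.size, np.nan)
    for i, off in enumerate(offsets_s):
        sel = (trials.times_s > off - seg_len_s - 1e-9) & (trials.times_s <= off + 1e-9)
        seg = trials.data[:, :, sel]               # (trials, features, seg frames)
        pts = np.transpose(seg, (0, 2, 1)).reshape(-1, trials.n_features)
        if pts.shape[0] < max(min_points, k + 2):
            continue
        emb = basis.transform(pts)
        vol = hull_volume(knn_triage(emb, frac=triage_frac, k=k), embed_dim)
        ratios[i] = min(vol / denom, 1.0)
    return HullMetrics(dim=embed_dim, session_volume=denom,
                       offsets_s=offsets_s, ratio_curve=ratios)


def auc_ratio(ratio_pull, ratio_random, offsets_s=None) -> float:
    """Trapezoidal AUC of the pull ratio curve divided by the AUC of the
    random-trigger ratio curve (same offsets)."""
    a = np.asarray(ratio_pull, dtype=float)
    b = np.asarray(ratio_random, dtype=float)
    if a.shape != b.shape:
        raise ParameterError("curves must share offsets")
    ok = ~(np.isnan(a) | np.isnan(b))
    if ok.sum() < 2:
        raise InsufficientDataError("need >= 2 defined offsets")
    x = np.asarray(offsets_s, dtype=float)[ok] if offsets_s is not None else np.flatnonzero(ok).astype(float)
    denom = np.trapezoid(b[ok], x)
    if denom == 0:
        raise DegenerateDataError("random-trigger AUC is zero")
    return float(np.trapezoid(a[ok], x) / denom)


def _sample_in_hull(points: np.ndarray, n: int, rng) -> np.ndarray:
    """Uniform samples inside the convex hull via its Delaunay simplices."""
    tri = Delaunay(points)
    simplices = points[tri.simplices]              # (n_simplex, d+1, d)
    d = points.shape[1]
    vecs = simplices[:, 1:, :] - simplices[:, :1, :]
    vols = np.abs(np.linalg.det(vecs))  # proportional to simplex volume (common 1/d!)
    total = vols.sum()
    if total == 0:
        raise DegenerateDataError("degenerate hull: cannot sample")
    choice = rng.choice(len(vols), size=n, p=vols / total)
    # uniform barycentric coordinates on each simplex
    w = rng.dirichlet(np.ones(d + 1), size=n)
    return np.einsum("nk,nkd->nd", w, simplices[choice])


def hull_overlap(points_a: np.ndarray, points_b: np.ndarray, n_mc: int = 100_000,
                 seed: int | None = None) -> HullOverlap:
    """Monte-Carlo hull intersection: fraction of uniform samples inside
    hull(A) that fall inside hull(B), and vice versa."""
    A = np.asarray(points_a, dtype=float)
    B = np.asarray(points_b, dtype=float)
    rng = np.random.default_rng(seed)
    try:
        tri_a, tri_b = Delaunay(A), Delaunay(B)
    except QhullError as e:
        raise DegenerateDataError(f"degenerate hull: {e}") from None
    sa = _sample_in_hull(A, n_mc, rng)
    sb = _sample_in_hull(B, n_mc, rng)
    a_in_b = float(np.mean(tri_b.find_simplex(sa) >= 0))
    b_in_a = float(np.mean(tri_a.find_simplex(sb) >= 0))
    return HullOverlap(a_in_b=a_in_b, b_in_a=b_in_a)
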