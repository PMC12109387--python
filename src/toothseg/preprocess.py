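"""Point-cloud sampling, grouping and relative-coordinate encoding.

The pipeline reduces a raw cloud (10^4-10^5 points) to ``m`` representative
center points with farthest point sampling, gathers each center's ``k``
Euclidean nearest neighbors, and describes every neighbor by its offset
``r_ij = p_j - p_i`` from the center and distance ``d_ij = |r_ij|`` — a
translation-invariant description of local geometry that is the model's core
input.

All routines are exactly deterministic: ties are broken everywhere by lowest
point index, and k-NN is chunked brute force (stable sort), so results are
identical across platforms and match the O(N^2) oracle by construction.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

logger = logging.getLogger(__name__)

__all__ = [
    "SamplingResult",
    "GroupedEncoding",
    "ENCODING_LAYOUTS",
    "farthest_point_sampling",
    "knn_group",
    "relative_encoding",
    "preprocess_cloud",
]

#: per-neighbor feature layouts -> feature width F
ENCODING_LAYOUTS = {"rel_dist_abs": 7, "rel_dist": 4, "abs_only": 3}


@dataclass(frozen=True)
class SamplingResult:
    """Indices of the ``m`` FPS-selected centers (distinct, in pick order)."""

    center_indices: np.ndarray

    @property
    def m(self) -> int:
        return len(self.center_indices)


@dataclass(frozen=True)
class GroupedEncoding:
    """Per-center neighborhoods with relative geometry.

    Attributes
    ----------
    neighbor_indices : (m, k) int
        The k nearest points of each center (center itself included).
    rel_pos : (m, k, 3)
        Offsets r_ij = p_j - p_i.
    dist : (m, k)
        Euclidean distances d_ij = |r_ij|.
    features : (m, k, F)
        Stacked per-neighbor features in the configured layout.
    layout : str
        One of :data:`ENCODING_LAYOUTS`.
    """

    neighbor_indices: np.ndarray
    rel_pos: np.ndarray
    dist: np.ndarray
    features: np.ndarray
    layout: str


def farthest_point_sampling(
    points: np.ndarray,
    m: int,
    start_index: int | None = 0,
    seed: int | None = None,
) -> SamplingResult:
    """Greedy max-min subsampling of ``m`` distinct points.

    Each successive pick maximizes its minimum Euclidean distance to the
    already-selected set; ties break to the lowest index.  The start point is
    ``start_index`` (default 0) or, when ``start_index`` is None, drawn from
    ``seed`` — either way the result is fully deterministic.
    """
    points = np.asarray(points)
    if points.dtype != np.float32:  # keep float32 pipelines cheap
        points = points.astype(np.float64)
    points = points.reshape(-1, 3)
    n = len(points)
    if not 1 <= m <= n:
        raise ValueError(f"m={m} must be in [1, {n}]")
    if start_index is None:
        start_index = int(np.random.default_rng(seed).integers(n))
    if not 0 <= start_index < n:
        raise ValueError(f"start_index {start_index} out of range [0, {n})")
    selected = np.empty(m, dtype=np.int64)
    selected[0] = start_index
    # min distance from every point to the selected set so far
    min_d2 = np.sum((points - points[start_index]) ** 2, axis=1)
    for i in range(1, m):
        nxt = int(np.argmax(min_d2))  # first occurrence = lowest index on ties
        selected[i] = nxt
        np.minimum(min_d2, np.sum((points - points[nxt]) ** 2, axis=1), out=min_d2)
    return SamplingResult(center_indices=selected)


def knn_group(
    points: np.ndarray,
    center_indices: np.ndarray,
    k: int,
    chunk: int = 512,
) -> np.ndarray:
    """For each center, the ``k`` nearest points (center included, d = 0).

    Brute-force distances with a stable argsort give oracle-exact results and
    lowest-index tie-breaks; centers are processed in chunks to bound memory.
    Returns an (m, k) integer index array ordered by increasing distance.
    """
    points = np.asarray(points)
    if points.dtype != np.float32:  # keep float32 pipelines cheap
        points = points.astype(np.float64)
    points = points.reshape(-1, 3)
    center_indices = np.asarray(center_indices, dtype=np.int64).reshape(-1)
    n = len(points)
    if not 1 <= k <= n:
        raise ValueError(f"k={k} must be in [1, {n}]")
    out = np.empty((len(center_indices), k), dtype=np.int64)
    sq = np.einsum("ij,ij->i", points, points)
    for lo in range(0, len(center_indices), chunk):
        centers = points[center_indices[lo : lo + chunk]]
        # ||c - p||^2 = ||c||^2 + ||p||^2 - 2 c.p  (BLAS-backed)
        d2 = sq[center_indices[lo : lo + chunk], None] + sq[None, :] - 2.0 * (
            centers @ points.T
        )
        np.maximum(d2, 0.0, out=d2)  # guard tiny negative round-off
        out[lo : lo + chunk] = _smallest_k(d2, k)
    return out


def _smallest_k(d2: np.ndarray, k: int) -> np.ndarray:
    """Indices of the k smallest values per row, ties to the lowest index.

    argpartition + a within-candidate stable sort; rows with ties at the
    k-th value boundary (where the k-set itself is ambiguous) fall back to a
    full stable argsort.  Equivalent to ``argsort(kind="stable")[:, :k]``
    but O(n + k log k) per row instead of O(n log n).
    """
    n = d2.shape[1]
    if k >= n:
        return np.argsort(d2, axis=1, kind="stable")[:, :k]
    part = np.argpartition(d2, k - 1, axis=1)[:, :k]
    vals = np.take_along_axis(d2, part, axis=1)
    thresh = vals.max(axis=1)
    # candidate set is unique iff no k-th-value ties fall outside it
    ambiguous = (d2 <= thresh[:, None]).sum(axis=1) > k
    # sort candidate columns by index first so a stable value-sort breaks
    # remaining ties toward the lowest index
    by_index = np.argsort(part, axis=1)
    part = np.take_along_axis(part, by_index, axis=1)
    vals = np.take_along_axis(vals, by_index, axis=1)
    order = np.argsort(vals, axis=1, kind="stable")
    result = np.take_along_axis(part, order, axis=1)
    for row in np.flatnonzero(ambiguous):
        result[row] = np.argsort(d2[row], kind="stable")[:k]
    return result


def relative_encoding(
    points: np.ndarray,
    center_indices: np.ndarray,
    neighbor_indices: np.ndarray,
    layout: str = "rel_dist_abs",
) -> GroupedEncoding:
    """Relative offsets/distances and the stacked per-neighbor feature tensor.

    Layouts: ``rel_dist_abs`` = [r_ij, d_ij, p_j] (F=7, default);
    ``rel_dist`` = [r_ij, d_ij] (F=4); ``abs_only`` = [p_j] (F=3, the
    absolute-coordinate ablation).
    """
    if layout not in ENCODING_LAYOUTS:
        raise ValueError(f"unknown layout {layout!r}; options: {list(ENCODING_LAYOUTS)}")
    points = np.asarray(points, dtype=np.float64).reshape(-1, 3)
    center_indices = np.asarray(center_indices, dtype=np.int64).reshape(-1)
    neighbor_indices = np.asarray(neighbor_indices, dtype=np.int64)
    centers = points[center_indices]  # (m, 3)
    neighbors = points[neighbor_indices]  # (m, k, 3)
    rel = neighbors - centers[:, None, :]
    dist = np.linalg.norm(rel, axis=2)
    if layout == "rel_dist_abs":
        feats = np.concatenate([rel, dist[..., None], neighbors], axis=2)
    elif layout == "rel_dist":
        feats = np.concatenate([rel, dist[..., None]], axis=2)
    else:
        feats = neighbors.copy()
    return GroupedEncoding(
        neighbor_indices=neighbor_indices,
        rel_pos=rel,
        dist=dist,
        features=feats,
        layout=layout,
    )


def preprocess_cloud(
    points: np.ndarray,
    num_centers: int = 2048,
    k: int = 64,
    layout: str = "rel_dist_abs",
    start_index: int | None = 0,
    seed: int | None = None,
) -> tuple[SamplingResult, GroupedEncoding]:
    """FPS + k-NN grouping + relative encoding in one call.

    When the cloud has fewer than ``num_centers`` points, m is clamped to N
    with a warning (small synthetic clouds).
    """
    points = np.asarray(points, dtype=np.float64).reshape(-1, 3)
    n = len(points)
    m = num_centers
    if m > n:
        logger.warning("num_centers=%d exceeds cloud size %d; clamping", m, n)
        m = n
    kk = min(k, n)
    sampling = farthest_point_sampling(points, m, start_index=start_index, seed=seed)
    neighbors = knn_group(points, sampling.center_indices, kk)
    return sampling, relative_encoding(points, sampling.center_indices, neighbors, layout)
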