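"""Directed pairwise overlap scores between bin-groups.

The overlap score from bin-group U to bin-group V is the fraction of the
k-nearest neighbours of the points of U that belong to V, where neighbours
are searched *only* inside ``U ∪ V − {u}`` — never in the whole cloud. A
radius-r variant replaces the k-neighbourhood by all points within distance
r. Computing the score for every ordered pair of bin-groups yields an
adjacency matrix with zero diagonal, interpretable as a weighted directed
graph over the bin-groups.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.sparse.csgraph import shortest_path
from scipy.spatial.distance import cdist
from sklearn.neighbors import kneighbors_graph

from .binning import BinPartition

__all__ = [
    "NeighborSpec",
    "OverlapMatrix",
    "overlap_score_knn",
    "overlap_score_radius",
    "overlap_matrix",
    "geodesic_distance_matrix",
]


@dataclass(frozen=True)
class NeighborSpec:
    """How point neighbourhoods are formed.

    mode ``"knn"`` uses the ``k`` nearest neighbours of each point; mode
    ``"radius"`` uses every point within distance ``r``. ``metric`` is any
    metric name accepted by :func:`scipy.spatial.distance.cdist`, or
    ``"geodesic"`` (shortest-path distance on the symmetrised kNN graph of
    the full cloud, with ``graph_k`` neighbours), or ``"precomputed"`` (a
    full N-by-N distance matrix is supplied instead of coordinates).
    """

    mode: str = "knn"
    k: int | None = 3
    r: float | None = None
    metric: str = "euclidean"
    graph_k: int = 15

    def __post_init__(self) -> None:
        if self.mode not in ("knn", "radius"):
            raise ValueError(f"mode must be 'knn' or 'radius', got {self.mode!r}")
        if self.mode == "knn":
            if self.k is None or self.k < 1:
                raise ValueError("knn mode requires k >= 1")
            if self.r is not None:
                raise ValueError("knn mode does not take a radius")
        else:
            if self.r is None or self.r <= 0:
                raise ValueError("radius mode requires r > 0")
            if self.k is not None:
                object.__setattr__(self, "k", None)


@dataclass(frozen=True)
class OverlapMatrix:
    """n-by-n matrix of directed overlap scores between bin-groups.

    ``m[i, j]`` is the overlap score from group i to group j; the diagonal
    is identically zero and all entries lie in [0, 1].
    """

    m: np.ndarray
    node_labels: tuple[str, ...]
    node_sizes: np.ndarray
    spec: NeighborSpec

    def __post_init__(self) -> None:
        m = np.asarray(self.m, dtype=float)
        if m.ndim != 2 or m.shape[0] != m.shape[1]:
            raise ValueError("overlap matrix must be square")
        if np.any(np.diag(m) != 0):
            raise ValueError("overlap matrix diagonal must be zero")
        if m.min() < 0 or m.max() > 1:
            raise ValueError("overlap scores must lie in [0, 1]")
        object.__setattr__(self, "m", m)
        object.__setattr__(self, "node_sizes", np.asarray(self.node_sizes, dtype=np.intp))

    @property
    def n_groups(self) -> int:
        return int(self.m.shape[0])

    def mean_out_degree(self) -> float:
        """Mean weighted out-degree of the bin-group graph."""
        return float(self.m.sum() / self.n_groups)


def _validate_cloud(coords) -> np.ndarray:
    x = np.asarray(coords, dtype=float)
    if x.ndim == 1:
        x = x[:, None]
    if x.ndim != 2:
        raise ValueError("point cloud must be an N x D matrix")
    if x.shape[0] < 2 or x.shape[1] < 1:
        raise ValueError("point cloud needs N >= 2 points and D >= 1 dimensions")
    if not np.all(np.isfinite(x)):
        raise ValueError("point cloud coordinates must be finite")
    return x


def _knn_counts(d: np.ndarray, in_v: np.ndarray, k: int) -> np.ndarray:
    """Per-row count of V-members among the k nearest columns of ``d``.

    ``d`` holds distances from each u in U (rows) to every point of
    U ∪ V − {u} (columns); ``in_v`` flags the columns belonging to V.
    Ties at the k-th distance are broken by ascending column index (stable
    sort), so results are deterministic on lattices.
    """
    order = np.argsort(d, axis=1, kind="stable")
    return in_v[order[:, :k]].sum(axis=1)


def overlap_score_knn(points_u, points_v, k: int, metric: str = "euclidean",
                      *, pair: tuple | None = None) -> float:
    """Directed overlap score from U to V with k-nearest neighbours.

    Returns ``(1 / (|U| k)) * sum_u |kNN(u; U ∪ V − {u}) ∩ V|``. The
    neighbour search is restricted to the two groups; the rest of the cloud
    is invisible to it.
    """
    u = _validate_cloud(points_u)
    v = _validate_cloud(points_v)
    su, sv = _pair_distance_blocks(u, v, metric)
    return _score_knn_from_blocks(su, sv, k, pair=pair)


def _pair_distance_blocks(u: np.ndarray, v: np.ndarray, metric: str):
    """Distance blocks (U->U, U->V) under a cdist metric."""
    return cdist(u, u, metric=metric), cdist(u, v, metric=metric)


def _score_knn_from_blocks(
    d_uu: np.ndarray, d_uv: np.ndarray, k: int, *, pair: tuple | None = None
) -> float:
    nu, nv = d_uv.shape
    if nu + nv <= k:
        label = f" between bin-groups {pair[0]} and {pair[1]}" if pair else ""
        raise ValueError(
            f"cannot take k={k} neighbours from a pair of {nu}+{nv} points"
            f"{label}; decrease k or increase min_points"
        )
    # columns: first the other members of U, then all of V; exclude self by
    # setting the diagonal of the U-U block to +inf
    d = np.concatenate([d_uu, d_uv], axis=1)
    np.fill_diagonal(d[:, :nu], np.inf)
    in_v = np.zeros(nu + nv, dtype=bool)
    in_v[nu:] = True
    counts = _knn_counts(d, in_v, k)
    return float(counts.sum() / (nu * k))


def overlap_score_radius(points_u, points_v, r: float, metric: str = "euclidean",
                         *, pair: tuple | None = None) -> float:
    """Directed overlap score from U to V with radius-r neighbourhoods.

    Each point u of U contributes the fraction of V-members among all points
    of ``U ∪ V − {u}`` within distance r of u. Points with an empty
    neighbourhood are excluded from the average (their fraction is
    undefined) with a warning; if every neighbourhood is empty the score is
    reported as 0 with a prominent warning.
    """
    if r <= 0:
        raise ValueError("radius must be positive")
    u = _validate_cloud(points_u)
    v = _validate_cloud(points_v)
    su, sv = _pair_distance_blocks(u, v, metric)
    return _score_radius_from_blocks(su, sv, r, pair=pair)


def _score_radius_from_blocks(
    d_uu: np.ndarray, d_uv: np.ndarray, r: float, *, pair: tuple | None = None
) -> float:
    nu, nv = d_uv.shape
    d = np.concatenate([d_uu, d_uv], axis=1)
    np.fill_diagonal(d[:, :nu], np.inf)
    within = d <= r
    n_ball = within.sum(axis=1)
    n_ball_v = within[:, nu:].sum(axis=1)
    nonempty = n_ball > 0
    label = f" (bin-groups {pair[0]} -> {pair[1]})" if pair else ""
    if not nonempty.any():
        warnings.warn(
            f"radius r={r:g} leaves every point without neighbours{label}; "
            "overlap score undefined, reporting 0",
            UserWarning,
            stacklevel=3,
        )
        return 0.0
    n_excluded = int((~nonempty).sum())
    if n_excluded:
        warnings.warn(
            f"excluded {n_excluded} point(s) with empty radius-{r:g} "
            f"neighbourhoods from the overlap score{label}",
            UserWarning,
            stacklevel=3,
        )
    frac = n_ball_v[nonempty] / n_ball[nonempty]
    return float(frac.mean())


def geodesic_distance_matrix(coords, graph_k: int = 15) -> np.ndarray:
    """Shortest-path distances on the symmetrised kNN graph of the cloud.

    Edge weights are Euclidean lengths; the directed kNN graph is
    symmetrised by taking each edge in both directions. Disconnected pairs
    come out infinite, which downstream neighbour searches treat as
    "farther than everything".
    """
    x = _validate_cloud(coords)
    n = x.shape[0]
    g = kneighbors_graph(
        x, n_neighbors=min(graph_k, n - 1), mode="distance", include_self=False
    )
    g = g.maximum(g.T)
    d = shortest_path(g, method="D", directed=False)
    if np.isinf(d).any():
        warnings.warn(
            "kNN graph is disconnected; geodesic distances across components "
            "are infinite — consider a larger graph_k",
            UserWarning,
            stacklevel=2,
        )
    return d


def _full_distance_matrix(coords, spec: NeighborSpec,
                          precomputed=None) -> np.ndarray | None:
    """Full N x N distances when the metric requires them, else None."""
    if precomputed is not None or spec.metric == "precomputed":
        if precomputed is None:
            raise ValueError("metric 'precomputed' requires a distance matrix")
        d = np.asarray(precomputed, dtype=float)
        if d.ndim != 2 or d.shape[0] != d.shape[1]:
            raise ValueError("precomputed distance matrix must be square")
        return d
    if spec.metric == "geodesic":
        return geodesic_distance_matrix(coords, graph_k=spec.graph_k)
    return None


def overlap_matrix(
    coords,
    partition: BinPartition,
    spec: NeighborSpec,
    *,
    precomputed_distances=None,
) -> OverlapMatrix:
    """Overlap scores for every ordered pair of bin-groups.

    Each pair's neighbour search is restricted to that pair's points; the
    two directed scores of a pair share one distance computation. Entry
    order of evaluation does not affect the result.
    """
    if partition.n_groups < 2:
        raise ValueError("need at least 2 bin-groups")
    full_d = _full_distance_matrix(coords, spec, precomputed_distances)
    if full_d is None:
        x = _validate_cloud(coords)
        if x.shape[0] != partition.n_points:
            raise ValueError(
                f"cloud has {x.shape[0]} points but partition describes "
                f"{partition.n_points}"
            )
    else:
        if full_d.shape[0] != partition.n_points:
            raise ValueError(
                f"distance matrix is {full_d.shape[0]} x {full_d.shape[0]} but "
                f"partition describes {partition.n_points} points"
            )
        x = None

    n = partition.n_groups
    groups = [partition.group_indices(g) for g in range(n)]
    m = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            gi, gj = groups[i], groups[j]
            if full_d is None:
                d_ii = cdist(x[gi], x[gi], metric=spec.metric)
                d_ij = cdist(x[gi], x[gj], metric=spec.metric)
                d_jj = cdist(x[gj], x[gj], metric=spec.metric)
                d_ji = d_ij.T
            else:
                d_ii = full_d[np.ix_(gi, gi)]
                d_ij = full_d[np.ix_(gi, gj)]
                d_jj = full_d[np.ix_(gj, gj)]
                d_ji = d_ij.T
            li = partition.group_labels[i] if partition.group_labels else str(i)
            lj = partition.group_labels[j] if partition.group_labels else str(j)
            if spec.mode == "knn":
                m[i, j] = _score_knn_from_blocks(d_ii, d_ij, spec.k, pair=(li, lj))
                m[j, i] = _score_knn_from_blocks(d_jj, d_ji, spec.k, pair=(lj, li))
            else:
                m[i, j] = _score_radius_from_blocks(d_ii, d_ij, spec.r, pair=(li, lj))
                m[j, i] = _score_radius_from_blocks(d_jj, d_ji, spec.r, pair=(lj, li))
    labels = partition.group_labels or tuple(str(g) for g in range(n))
    return OverlapMatrix(m, labels, partition.group_sizes, spec)
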