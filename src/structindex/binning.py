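"""Partition a point cloud into bin-groups according to feature values.

A *bin-group* is the subset of points whose feature values fall into one bin.
The bin-groups form a disjoint finite covering of the (assigned) point cloud:
for a scalar feature the bins are half-open intervals ``[t_i, t_{i+1})`` with
the last bin closed so the feature maximum is assigned; for a categorical
feature there is one group per distinct label; for an m-dimensional vector
feature the groups are the non-empty cells of the Cartesian product of
per-dimension scalar binnings.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "UNASSIGNED",
    "BinPartition",
    "uniform_bin_edges",
    "assign_bins",
    "filter_small_groups",
]

#: Sentinel label for points that belong to no bin-group (e.g. dropped by
#: :func:`filter_small_groups`).
UNASSIGNED = -1


@dataclass(frozen=True)
class BinPartition:
    """Assignment of every point to exactly one bin-group.

    Attributes
    ----------
    labels : ndarray of int, shape (n_points,)
        Dense bin-group index in ``0..n_groups-1`` per point, or
        :data:`UNASSIGNED` for discarded points.
    edges : tuple of ndarray, or None
        Per-feature-dimension ascending bin limits (length ``n_bins+1``
        each). ``None`` for categorical features.
    n_groups : int
        Number of non-empty bin-groups.
    group_sizes : ndarray of int, shape (n_groups,)
        Point count per group.
    group_labels : tuple of str
        Human-readable descriptor per group: an interval ``"[lo, hi)"`` for
        continuous bins (product of intervals for vector features) or the
        category name.
    """

    labels: np.ndarray
    edges: tuple[np.ndarray, ...] | None
    n_groups: int
    group_sizes: np.ndarray
    group_labels: tuple[str, ...] = field(default=())

    def __post_init__(self) -> None:
        labels = np.asarray(self.labels, dtype=np.intp)
        object.__setattr__(self, "labels", labels)
        object.__setattr__(
            self, "group_sizes", np.asarray(self.group_sizes, dtype=np.intp)
        )
        if self.n_groups != len(self.group_sizes):
            raise ValueError("n_groups inconsistent with group_sizes")
        assigned = labels[labels != UNASSIGNED]
        if assigned.size and (assigned.min() < 0 or assigned.max() >= self.n_groups):
            raise ValueError("labels outside 0..n_groups-1")

    @property
    def n_points(self) -> int:
        return int(self.labels.shape[0])

    @property
    def n_assigned(self) -> int:
        return int(np.count_nonzero(self.labels != UNASSIGNED))

    def group_indices(self, g: int) -> np.ndarray:
        """Indices of the points in bin-group ``g``."""
        return np.flatnonzero(self.labels == g)


def uniform_bin_edges(
    feature_min: float, feature_max: float, n_bins: int
) -> np.ndarray:
    """Equally spaced bin limits ``t_i = (i-1)(max-min)/n + min``.

    Parameters
    ----------
    feature_min, feature_max : float
        Range of the feature; ``feature_max`` must exceed ``feature_min``.
    n_bins : int
        Number of bins (>= 2).

    Returns
    -------
    ndarray, shape (n_bins + 1,)
        Strictly increasing edges, first equal to ``feature_min`` and last
        to ``feature_max``.
    """
    if n_bins < 2:
        raise ValueError(f"n_bins must be >= 2, got {n_bins}")
    if not (np.isfinite(feature_min) and np.isfinite(feature_max)):
        raise ValueError("feature range must be finite")
    if feature_max <= feature_min:
        raise ValueError(
            "constant feature has no structure to bin "
            f"(min == max == {feature_min!r})"
            if feature_max == feature_min
            else "feature_max must exceed feature_min"
        )
    return np.linspace(feature_min, feature_max, n_bins + 1)


def _format_interval(lo: float, hi: float, closed: bool) -> str:
    return f"[{lo:g}, {hi:g}{']' if closed else ')'}"


def _assign_scalar(values: np.ndarray, edges: np.ndarray) -> np.ndarray:
    """Digitize with half-open bins, last bin closed at the top edge."""
    # np.digitize(right=False): index i such that edges[i-1] <= v < edges[i]
    raw = np.digitize(values, edges, right=False) - 1
    n_bins = len(edges) - 1
    raw[values == edges[-1]] = n_bins - 1  # close the last bin
    out = np.where((raw >= 0) & (raw < n_bins), raw, UNASSIGNED)
    return out.astype(np.intp)


def _scalar_edges(values: np.ndarray, n_bins, custom: np.ndarray | None) -> np.ndarray:
    if custom is not None:
        edges = np.asarray(custom, dtype=float)
        if edges.ndim != 1 or edges.size < 3:
            raise ValueError("custom edges must be a 1-D sequence of >= 3 limits")
        if not np.all(np.diff(edges) > 0):
            raise ValueError("custom edges must be strictly increasing")
        return edges
    return uniform_bin_edges(float(values.min()), float(values.max()), int(n_bins))


def _densify(
    labels: np.ndarray,
    descriptors: list[str],
) -> tuple[np.ndarray, np.ndarray, list[str]]:
    """Re-index labels densely over non-empty groups, keeping order."""
    kept = np.unique(labels[labels != UNASSIGNED])
    remap = np.full(int(kept.max()) + 1 if kept.size else 0, UNASSIGNED, dtype=np.intp)
    remap[kept] = np.arange(kept.size)
    out = np.where(labels != UNASSIGNED, remap[np.clip(labels, 0, None)], UNASSIGNED)
    sizes = np.bincount(out[out != UNASSIGNED], minlength=kept.size)
    return out.astype(np.intp), sizes, [descriptors[g] for g in kept]


def assign_bins(
    values,
    n_bins: int | list[int] | tuple[int, ...] = 10,
    *,
    categorical: bool = False,
    custom_edges=None,
) -> BinPartition:
    """Partition points into bin-groups by feature value.

    Parameters
    ----------
    values : array-like
        Length-N scalars, length-N category labels, or (N, m) numeric matrix
        for a vector feature.
    n_bins : int or per-dimension sequence of int
        Number of equal-width bins (ignored for categorical features, and
        for dimensions given ``custom_edges``).
    categorical : bool
        Treat ``values`` as nominal labels; one group per distinct label in
        order of first appearance.
    custom_edges : array-like or sequence of array-like, optional
        Explicit ascending bin limits; for vector features, one sequence per
        feature dimension.

    Returns
    -------
    BinPartition
        Non-empty groups only; for vector features the empty cells of the
        per-dimension product are dropped and labels re-indexed densely.
    """
    if categorical:
        arr = np.asarray(values)
        if arr.ndim != 1:
            raise ValueError("categorical feature must be 1-D")
        if arr.size == 0:
            raise ValueError("empty feature")
        cats, inverse = np.unique(arr, return_inverse=True)
        # reorder to first-appearance order
        first_pos = np.array([np.flatnonzero(inverse == c)[0] for c in range(len(cats))])
        order = np.argsort(first_pos, kind="stable")
        rank = np.empty_like(order)
        rank[order] = np.arange(len(order))
        labels = rank[inverse].astype(np.intp)
        n_groups = len(cats)
        if n_groups < 2:
            raise ValueError(
                f"need at least 2 bin-groups, found {n_groups} distinct label(s)"
            )
        sizes = np.bincount(labels, minlength=n_groups)
        names = tuple(str(cats[g]) for g in order)
        return BinPartition(labels, None, n_groups, sizes, names)

    arr = np.asarray(values, dtype=float)
    if arr.size == 0:
        raise ValueError("empty feature")
    if not np.all(np.isfinite(arr)):
        raise ValueError("continuous feature values must be finite")
    if arr.ndim == 1:
        arr = arr[:, None]
    if arr.ndim != 2:
        raise ValueError("feature must be 1-D (scalar) or 2-D (vector)")
    n_dim = arr.shape[1]

    if custom_edges is not None:
        if n_dim == 1 and np.isscalar(custom_edges[0]):
            per_dim_edges = [custom_edges]
        else:
            per_dim_edges = list(custom_edges)
        if len(per_dim_edges) != n_dim:
            raise ValueError(
                f"got edge sequences for {len(per_dim_edges)} dimension(s), "
                f"feature has {n_dim}"
            )
    else:
        per_dim_edges = [None] * n_dim

    if np.isscalar(n_bins):
        n_bins_per_dim = [n_bins] * n_dim
    else:
        n_bins_per_dim = list(n_bins)
        if len(n_bins_per_dim) != n_dim:
            raise ValueError(
                f"got n_bins for {len(n_bins_per_dim)} dimension(s), feature has {n_dim}"
            )

    edges: list[np.ndarray] = []
    dim_labels: list[np.ndarray] = []
    for d in range(n_dim):
        e = _scalar_edges(arr[:, d], n_bins_per_dim[d], per_dim_edges[d])
        edges.append(e)
        dim_labels.append(_assign_scalar(arr[:, d], e))

    # product cell index; any UNASSIGNED dimension marks the point unassigned
    cell = np.zeros(arr.shape[0], dtype=np.intp)
    unassigned = np.zeros(arr.shape[0], dtype=bool)
    for d in range(n_dim):
        nb = len(edges[d]) - 1
        cell = cell * nb + np.clip(dim_labels[d], 0, None)
        unassigned |= dim_labels[d] == UNASSIGNED
    cell[unassigned] = UNASSIGNED

    descriptors = _product_descriptors(edges)
    labels, sizes, names = _densify(cell, descriptors)
    n_groups = len(sizes)
    if n_groups < 2:
        raise ValueError(
            f"need at least 2 non-empty bin-groups, got {n_groups}; "
            "use more bins or a less degenerate feature"
        )
    return BinPartition(labels, tuple(edges), n_groups, sizes, tuple(names))


def _product_descriptors(edges: list[np.ndarray]) -> list[str]:
    """Descriptor for every cell of the per-dimension bin product."""
    per_dim: list[list[str]] = []
    for e in edges:
        nb = len(e) - 1
        per_dim.append(
            [_format_interval(e[i], e[i + 1], closed=(i == nb - 1)) for i in range(nb)]
        )
    out = [""]
    for names in per_dim:
        out = [f"{a} x {b}" if a else b for a in out for b in names]
    return out


def filter_small_groups(partition: BinPartition, min_points: int = 3) -> BinPartition:
    """Drop bin-groups smaller than ``min_points``; their points become unassigned.

    Every point of a directed overlap pair must have k neighbours inside the
    pair, so tiny groups are unusable downstream. Surviving groups are
    re-indexed densely; a warning names the dropped groups.
    """
    if min_points < 1:
        raise ValueError("min_points must be >= 1")
    small = np.flatnonzero(partition.group_sizes < min_points)
    if small.size == 0:
        return partition
    dropped = [partition.group_labels[g] if partition.group_labels else str(g)
               for g in small]
    warnings.warn(
        f"dropping {small.size} bin-group(s) with fewer than {min_points} "
        f"points: {dropped}",
        UserWarning,
        stacklevel=2,
    )
    labels = partition.labels.copy()
    labels[np.isin(labels, small)] = UNASSIGNED
    if partition.n_groups - small.size < 2:
        raise ValueError(
            f"fewer than 2 bin-groups have >= {min_points} points; "
            "reduce n_bins or min_points"
        )
    descriptors = list(
        partition.group_labels
        if partition.group_labels
        else map(str, range(partition.n_groups))
    )
    new_labels, sizes, names = _densify(labels, descriptors)
    return BinPartition(new_labels, partition.edges, len(sizes), sizes, tuple(names))
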