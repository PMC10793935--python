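"""The Structure Index: scaled mean out-degree of the overlap graph.

For an n-group overlap matrix M with zero diagonal,

    SI = 1 - (2 / (n^2 - n)) * sum_ij M[i, j]

so a random feature distribution (every pairwise overlap near 0.5) scores 0
and a perfectly separated one (all overlaps 0) scores 1. Small samples and
small k can push the raw value slightly negative; the reported SI is clipped
at 0 while the raw value is retained for diagnostics. Significance is
assessed against a permutation null: feature values are shuffled over the
points and the SI recomputed, and the observed value is compared with the
null's 99th percentile.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from .binning import BinPartition, assign_bins, filter_small_groups
from .overlap import NeighborSpec, OverlapMatrix, overlap_matrix

__all__ = [
    "SIResult",
    "SweepProfile",
    "structure_index",
    "compute_si",
    "shuffle_null",
    "sweep",
]


@dataclass
class SIResult:
    """Everything one run of the Structure Index produces."""

    si: float
    si_raw: float
    overlap: OverlapMatrix
    partition: BinPartition
    params: dict
    null_values: np.ndarray = field(default_factory=lambda: np.empty(0))
    null_percentile_99: float | None = None

    @property
    def significant(self) -> bool | None:
        """Whether the observed SI exceeds the null 99th percentile."""
        if self.null_percentile_99 is None:
            return None
        return self.si > self.null_percentile_99

    def to_dict(self) -> dict:
        out = {
            "schema_version": 1,
            "si": self.si,
            "si_raw": self.si_raw,
            "n_groups": self.overlap.n_groups,
            "group_sizes": self.partition.group_sizes.tolist(),
            "group_labels": list(self.overlap.node_labels),
            "params": self.params,
            "overlap_matrix": self.overlap.m.tolist(),
            "null": {
                "n_shuffles": int(self.null_values.size),
                "values": self.null_values.tolist(),
                "percentile_99": self.null_percentile_99,
            },
        }
        return out

    def to_json(self, **kwargs) -> str:
        return json.dumps(self.to_dict(), **kwargs)


@dataclass(frozen=True)
class SweepProfile:
    """SI as a function of neighbourhood size (k or r)."""

    grid: np.ndarray
    si_values: np.ndarray
    null_99: np.ndarray | None = None

    def __post_init__(self) -> None:
        grid = np.asarray(self.grid)
        if grid.size == 0 or np.any(np.diff(grid.astype(float)) <= 0):
            raise ValueError("grid must be non-empty and strictly increasing")
        object.__setattr__(self, "grid", grid)
        object.__setattr__(self, "si_values", np.asarray(self.si_values, dtype=float))
        if len(self.si_values) != len(grid):
            raise ValueError("si_values length must match grid")
        if self.null_99 is not None:
            object.__setattr__(self, "null_99", np.asarray(self.null_99, dtype=float))


def structure_index(m: OverlapMatrix | np.ndarray) -> tuple[float, float]:
    """SI of an overlap matrix: ``1 - 2/(n^2-n) * sum(M)``.

    Returns ``(si, si_raw)`` where ``si = max(si_raw, 0)``. For n = 2 the
    scaling factor is exactly 1.
    """
    a = m.m if isinstance(m, OverlapMatrix) else np.asarray(m, dtype=float)
    if a.ndim != 2 or a.shape[0] != a.shape[1]:
        raise ValueError("overlap matrix must be square")
    n = a.shape[0]
    if n < 2:
        raise ValueError("SI needs at least 2 bin-groups")
    si_raw = float(1.0 - (2.0 / (n * n - n)) * a.sum())
    return max(si_raw, 0.0), si_raw


def _partition(feature, n_bins, categorical, custom_edges, min_points):
    part = assign_bins(
        feature, n_bins, categorical=categorical, custom_edges=custom_edges
    )
    if min_points and min_points > 1:
        part = filter_small_groups(part, min_points)
    return part


def compute_si(
    coords,
    feature,
    *,
    n_bins: int | list[int] = 10,
    categorical: bool = False,
    custom_edges=None,
    spec: NeighborSpec | None = None,
    min_points: int = 3,
    n_shuffles: int = 0,
    seed: int | None = None,
    precomputed_distances=None,
) -> SIResult:
    """Full Structure Index pipeline on one cloud/feature pair.

    Binning -> small-group filtering -> pairwise overlap matrix -> SI, plus
    a permutation null when ``n_shuffles > 0``. Reproducible from ``seed``.
    """
    spec = spec or NeighborSpec()
    part = _partition(feature, n_bins, categorical, custom_edges, min_points)
    m = overlap_matrix(coords, part, spec, precomputed_distances=precomputed_distances)
    si, si_raw = structure_index(m)
    params = {
        "n_bins": n_bins if np.isscalar(n_bins) else list(n_bins),
        "categorical": categorical,
        "mode": spec.mode,
        "k": spec.k,
        "r": spec.r,
        "metric": spec.metric,
        "min_points": min_points,
        "n_shuffles": n_shuffles,
        "seed": seed,
    }
    null = np.empty(0)
    p99 = None
    if n_shuffles > 0:
        null = shuffle_null(
            coords,
            feature,
            n_bins=n_bins,
            categorical=categorical,
            custom_edges=custom_edges,
            spec=spec,
            min_points=min_points,
            n_shuffles=n_shuffles,
            seed=seed,
            precomputed_distances=precomputed_distances,
        )
        p99 = float(np.percentile(null, 99))
    return SIResult(si, si_raw, m, part, params, null, p99)


def shuffle_null(
    coords,
    feature,
    *,
    n_bins: int | list[int] = 10,
    categorical: bool = False,
    custom_edges=None,
    spec: NeighborSpec | None = None,
    min_points: int = 3,
    n_shuffles: int = 100,
    seed: int | None = None,
    precomputed_distances=None,
) -> np.ndarray:
    """SI values under random permutation of the feature over the points.

    Each shuffle permutes the feature values (the cloud is untouched) and
    recomputes the SI with identical parameters. Because a permutation
    preserves the value multiset, the bin edges and group sizes are
    identical across shuffles; only the point-to-group assignment changes.
    """
    if n_shuffles < 1:
        raise ValueError("n_shuffles must be >= 1")
    spec = spec or NeighborSpec()
    feat = np.asarray(feature)
    rng = np.random.default_rng(seed)
    out = np.empty(n_shuffles)
    for s in range(n_shuffles):
        perm = rng.permutation(feat.shape[0])
        part = _partition(feat[perm], n_bins, categorical, custom_edges, min_points)
        m = overlap_matrix(
            coords, part, spec, precomputed_distances=precomputed_distances
        )
        out[s], _ = structure_index(m)
    return out


def sweep(
    coords,
    feature,
    grid,
    *,
    mode: str = "knn",
    n_bins: int | list[int] = 10,
    categorical: bool = False,
    custom_edges=None,
    metric: str = "euclidean",
    graph_k: int = 15,
    min_points: int = 3,
    n_shuffles: int = 0,
    seed: int | None = None,
    precomputed_distances=None,
) -> SweepProfile:
    """SI profile over a grid of k (or r) values, with shared binning.

    Small k probes local structure, large k global structure: a feature
    organised only locally loses its SI quickly as k grows, while a global
    gradient decays smoothly. Shuffle nulls, when requested, are computed
    at every grid value with per-value derived seeds.
    """
    grid = np.asarray(grid)
    if grid.size == 0:
        raise ValueError("grid must be non-empty")
    part = _partition(feature, n_bins, categorical, custom_edges, min_points)
    feat = np.asarray(feature)
    ss = np.random.SeedSequence(seed)
    child_seeds = [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(grid.size)]
    si_values = np.empty(grid.size)
    null_99 = np.empty(grid.size) if n_shuffles > 0 else None
    for idx, g in enumerate(grid):
        if mode == "knn":
            spec = NeighborSpec(mode="knn", k=int(g), metric=metric, graph_k=graph_k)
        else:
            spec = NeighborSpec(mode="radius", k=None, r=float(g), metric=metric,
                                graph_k=graph_k)
        m = overlap_matrix(
            coords, part, spec, precomputed_distances=precomputed_distances
        )
        si_values[idx], _ = structure_index(m)
        if n_shuffles > 0:
            null = shuffle_null(
                coords,
                feat,
                n_bins=n_bins,
                categorical=categorical,
                custom_edges=custom_edges,
                spec=spec,
                min_points=min_points,
                n_shuffles=n_shuffles,
                seed=child_seeds[idx],
                precomputed_distances=precomputed_distances,
            )
            null_99[idx] = np.percentile(null, 99)
    return SweepProfile(grid, si_values, null_99)
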