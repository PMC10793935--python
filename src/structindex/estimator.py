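"""Scikit-learn style estimator front end for the Structure Index."""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator

from .graph_export import to_graph
from .overlap import NeighborSpec
from .si_core import compute_si

__all__ = ["StructureIndex"]


class StructureIndex(BaseEstimator):
    """Quantify how a feature is structured over a point cloud.

    ``fit(X, y)`` bins the points by the per-point feature ``y``, computes
    the directed k-nearest-neighbour (or radius) overlap between every pair
    of bin-groups, and summarises the overlap graph as a single index:
    0 for a randomly distributed feature, 1 for a maximally separated one.
    An optional permutation null gives a significance threshold.

    Parameters
    ----------
    n_bins : int or sequence of int, default=10
        Equal-width bins for continuous features (per dimension for vector
        features). Ignored when ``categorical=True`` or ``custom_edges`` is
        given.
    categorical : bool, default=False
        Treat ``y`` as nominal labels, one bin-group per distinct label.
    custom_edges : array-like or sequence of array-like, optional
        Explicit ascending bin limits, one sequence per feature dimension.
    n_neighbors : int, default=3
        k of the kNN neighbourhoods. Small k probes local structure, large
        k global structure. Mutually exclusive with ``radius``.
    radius : float, optional
        Use radius-r neighbourhoods instead of kNN (useful for clouds of
        very uneven density).
    metric : str, default="euclidean"
        Any ``scipy.spatial.distance.cdist`` metric, ``"geodesic"``
        (shortest paths on the symmetrised kNN graph of the full cloud) or
        ``"precomputed"`` (pass the N x N distance matrix as ``X``).
    graph_k : int, default=15
        Neighbours of the graph underlying the geodesic metric.
    min_points : int, default=3
        Bin-groups smaller than this are dropped with a warning.
    n_shuffles : int, default=0
        Size of the permutation null; 0 disables it.
    random_state : int, optional
        Seed for the permutation null.

    Attributes
    ----------
    si_ : float
        The Structure Index, clipped to [0, 1].
    si_raw_ : float
        Unclipped value (can be slightly negative for small samples/k).
    overlap_ : OverlapMatrix
        Directed pairwise overlap scores between bin-groups.
    labels_ : ndarray of shape (n_samples,)
        Bin-group index per point (-1 for points dropped by the
        small-group filter).
    n_groups_ : int
    group_sizes_ : ndarray
    null_values_ : ndarray
        SI of each feature shuffle (empty if ``n_shuffles=0``).
    null_percentile_99_ : float or None
        Significance threshold from the permutation null.

    Examples
    --------
    >>> from structindex import StructureIndex
    >>> from structindex.synthetic import gradient_ellipsoid
    >>> X, y = gradient_ellipsoid(2000, seed=0)
    >>> si = StructureIndex(n_neighbors=3).fit(X, y)
    >>> si.si_ > 0.9
    True
    """

    def __init__(
        self,
        n_bins=10,
        *,
        categorical: bool = False,
        custom_edges=None,
        n_neighbors: int = 3,
        radius: float | None = None,
        metric: str = "euclidean",
        graph_k: int = 15,
        min_points: int = 3,
        n_shuffles: int = 0,
        random_state: int | None = None,
    ):
        self.n_bins = n_bins
        self.categorical = categorical
        self.custom_edges = custom_edges
        self.n_neighbors = n_neighbors
        self.radius = radius
        self.metric = metric
        self.graph_k = graph_k
        self.min_points = min_points
        self.n_shuffles = n_shuffles
        self.random_state = random_state

    def _neighbor_spec(self) -> NeighborSpec:
        metric = "euclidean" if self.metric == "precomputed" else self.metric
        if self.radius is not None:
            return NeighborSpec(mode="radius", k=None, r=self.radius,
                                metric=metric, graph_k=self.graph_k)
        return NeighborSpec(mode="knn", k=self.n_neighbors, metric=metric,
                            graph_k=self.graph_k)

    def fit(self, X, y):
        """Compute the Structure Index of feature ``y`` over cloud ``X``.

        ``X`` is the (n_samples, n_dimensions) point cloud — or the
        (n_samples, n_samples) distance matrix when ``metric='precomputed'``
        — and ``y`` the per-point feature: scalars, category labels, or an
        (n_samples, m) matrix for a vector feature.
        """
        y_arr = np.asarray(y)
        if self.metric == "precomputed":
            result = compute_si(
                np.zeros((np.asarray(X).shape[0], 1)),
                y_arr,
                n_bins=self.n_bins,
                categorical=self.categorical,
                custom_edges=self.custom_edges,
                spec=self._neighbor_spec(),
                min_points=self.min_points,
                n_shuffles=self.n_shuffles,
                seed=self.random_state,
                precomputed_distances=np.asarray(X, dtype=float),
            )
        else:
            result = compute_si(
                X,
                y_arr,
                n_bins=self.n_bins,
                categorical=self.categorical,
                custom_edges=self.custom_edges,
                spec=self._neighbor_spec(),
                min_points=self.min_points,
                n_shuffles=self.n_shuffles,
                seed=self.random_state,
            )
        self.result_ = result
        self.si_ = result.si
        self.si_raw_ = result.si_raw
        self.overlap_ = result.overlap
        self.partition_ = result.partition
        self.labels_ = result.partition.labels
        self.n_groups_ = result.overlap.n_groups
        self.group_sizes_ = result.partition.group_sizes
        self.null_values_ = result.null_values
        self.null_percentile_99_ = result.null_percentile_99
        return self

    def score(self, X=None, y=None) -> float:
        """The fitted Structure Index (arguments accepted for API symmetry)."""
        if not hasattr(self, "si_"):
            raise AttributeError("StructureIndex must be fitted before scoring")
        return self.si_

    def to_graph(self, weight_threshold: float = 0.0):
        """Fitted overlap matrix as a weighted :class:`networkx.DiGraph`."""
        if not hasattr(self, "overlap_"):
            raise AttributeError("StructureIndex must be fitted first")
        return to_graph(self.overlap_, weight_threshold)
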