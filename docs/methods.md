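# Methods

## The model

The Structure Index treats "feature structure" operationally: a feature is
structured over a point cloud exactly to the extent that points with similar
feature values are each other's neighbours. The pipeline is

1. **Binning.** Points are partitioned into bin-groups by feature value.
   Continuous features get `n` equal-width bins `[t_i, t_{i+1})` over
   `[min f, max f]`, with the last bin closed so the maximum is assigned;
   this makes the groups pairwise disjoint while covering every point.
   Categorical features get one group per distinct label (first-appearance
   order, which only affects node labelling — the SI is invariant to group
   order because it sums all matrix entries). Vector features are binned per
   dimension and the groups are the non-empty cells of the Cartesian
   product; empty cells are dropped silently so the graph has no hollow
   nodes. Custom edges (e.g. logarithmic for heavy-tailed features) can be
   supplied per dimension; automatic quantile/log binning is deliberately
   out of scope.
2. **Pairwise overlap.** For each ordered pair of groups (U, V), the score
   is the fraction of the k nearest neighbours of U's points that belong to
   V, with the search restricted to `U ∪ V − {u}`. The restriction is load-
   bearing: searching the whole cloud would dilute every pair by the other
   groups and change the 0.5 random baseline that anchors the index. The
   radius variant averages `|β_u(r) ∩ V| / |β_u(r)|` over the points of U
   with non-empty `β_u(r)`.
3. **Index.** `SI = 1 − (2/(n²−n)) Σ M_ij`, i.e. one minus the scaled mean
   weighted out-degree of the overlap digraph. Reported SI is clipped at 0;
   the raw value is retained (`si_raw_`) because a persistent, strongly
   negative raw value usually signals k too large for the group sizes.
4. **Null.** Feature values are permuted over points and the SI recomputed.
   Permutation preserves the value multiset, so bin edges and group sizes
   are identical across shuffles and only the assignment of points to groups
   randomises; whether one re-bins per shuffle or permutes labels directly
   is therefore observationally equivalent (we re-bin). The threshold is the
   99th percentile by linear interpolation of order statistics.

Assumptions worth stating: the metric sees only the distance structure of
the cloud, so it inherits whatever pathologies the chosen metric has in the
ambient space; bins are treated as exchangeable nodes, so ordinal adjacency
of bins carries no weight (a gradient and a patchy layout with equal
overlaps score identically — by design); and each pair must satisfy
`|U ∪ V| > k`, which is why tiny bin-groups are filtered.

## Parameters

| parameter | default | notes |
|---|---|---|
| `n_bins` | 10 | heuristic for continuous features; the index is stable over roughly 5–20 bins on the toy models, and the choice should keep a reasonable count per bin. Vector features take one value per dimension — keep the product of bins small enough that cells hold several points each. |
| `n_neighbors` (k) | 3 | small k probes local structure; sweeping k (e.g. 3–200) profiles local vs global. Units: points. |
| `radius` (r) | off | alternative to k for clouds with very uneven density; same units as the coordinates. Points with empty balls are excluded from the average with a warning. |
| `metric` | euclidean | any `cdist` metric; `geodesic` approximates intrinsic distance by shortest paths on the symmetrised `graph_k`-NN graph (default 15) of the **full** cloud, computed once and sliced per pair; `precomputed` accepts an N×N matrix for arbitrary metrics. |
| `min_points` | 3 | bin-groups smaller than this are dropped with a warning; with k = 3 a pair of 3-point groups is still feasible. |
| `n_shuffles` | 100 (CLI) / 0 (estimator) | permutation-null size; 100 gives a usable 99th percentile. |

## Numerical choices

- **kNN ties** are broken by ascending candidate index (stable argsort),
  with U's points ordered before V's. Continuous data makes ties
  measure-zero, but synthetic lattices hit them; the convention makes
  results independent of evaluation order and bitwise reproducible.
- Per-pair distance blocks are computed independently (or sliced from the
  full matrix for geodesic/precomputed metrics), so the matrix is identical
  regardless of pair evaluation order.
- Degenerate inputs error early with named offenders: constant features
  (nothing to bin), fewer than two surviving groups, pairs with
  `|U ∪ V| ≤ k` (the k-th neighbour does not exist; we refuse rather than
  silently truncate k).
- All randomness flows from `numpy.random.default_rng(seed)`; sweeps and
  multi-run protocols derive child seeds via `SeedSequence.spawn`.

## Synthetic generators

The generators produce clouds whose feature structure is known by
construction: a uniform 2:1 ellipse with a major-axis gradient (optionally
skew-transformed by the monotone power map `u ↦ u^exp(s)` — any monotone
family tests the same invariance, since the SI depends on feature values
only through the binning); a 3D ball sampled uniformly in angles and radius
(feature = radius, so noise-free bins are concentric shells); unit
D-spheres from uniform hyperspherical angles with per-coordinate Gaussian
noise; one 2D strip carrying both a locally repeating and a global ramp
feature on identical coordinates; a two-latent cloud at `(x, y) = (b, α·a)`
plus noise, a minimal realisation of "b's influence fixed, a's scaled by α"
(the published construction is not fully specified; this reconstruction
reproduces the stated behaviour); dimensional embedding by zero-padding,
isotropic noise, and a Haar-random rotation (an exact isometry at zero
noise); SNR-controlled noise with noise variance = mean per-coordinate
signal variance / SNR (one of several SNR conventions — substitute your own
via `add_noise_snr`'s definition if needed); and a stack of disjoint discs
standing in for discontinuous multi-part objects.

What they do *not* emulate: anisotropic or heteroscedastic noise, outliers,
non-uniform sampling density along the feature (except the radial ball's
parametric sampling), temporal autocorrelation of real trajectories on
neural manifolds, and measurement noise on the feature itself. Passing
tests on these toys shows the metric's geometry is implemented correctly
and behaves as designed; it does not certify performance on any particular
experimental dataset.

## Test and acceptance problem sizes

The validation protocols run at desk scale, chosen so the full suite
completes in minutes while keeping every qualitative contrast far from its
decision boundary: random-baseline checks use 5,000-point clouds averaged
over 5–10 seeds; the local/global k-sweep uses 3,000 points with k up to
200 and a 20-shuffle null; robustness sweeps use 1,000–10,000 points,
embedding dimensions 2–20, and 5–20 bins; sphere protocols use 4,000 points
with 10 bins per angle for scalar/3-sphere features and 3 bins per angle
dimension for higher-dimensional vector features (keeping tens of points
per product cell). Oracle agreement is checked exactly (zero tolerance)
against a brute-force full-sort reference on 50 random configurations of up
to 300 points.

## Limitations

- Cost is dominated by the `n(n−1)/2` pairwise kNN searches; with many
  product cells from vector features this grows quadratically in cell
  count. Exact brute-force search is used throughout (no approximate
  indices), which is the right trade below ~10⁵ points per pair.
- The SI says *whether* and *where* (via the graph) a feature is
  structured, not *how*; two very different layouts can share an SI value.
- The permutation null tests exchangeability of feature values over points;
  autocorrelated features on trajectory data violate it and make the
  threshold optimistic.
- Radius mode's exclusion of empty neighbourhoods biases the average toward
  dense regions when r is small relative to the cloud's spacing.
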