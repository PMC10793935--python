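# structindex

Quantify how a per-point feature is distributed over a point cloud in a
space of any dimension — the **Structure Index (SI)**.

Point clouds with per-point features are everywhere: population activity of
N neurons over time (a neural manifold with behavioural variables such as
head direction or speed projected onto it), event waveforms in a
timestamp space, images in pixel space, cells in gene-expression space. A
recurring question is whether a feature is *structured* over the cloud —
organised in any non-random way — and whether that organisation is local
(holding only in small neighbourhoods) or global. Cluster-cohesion indices
(silhouette and relatives) need discrete, well-separated groups; linear
correlation misses convoluted geometries. The SI handles continuous,
categorical, and vector features on arbitrary clouds, without embedding or
visualisation.

## The metric

Given a cloud `P ⊂ ℝ^D` and feature values `f_p`, the points are divided
into `n` disjoint **bin-groups** `B_i = {p : t_i ≤ f_p < t_{i+1}}` (equal-width
bins by default; one group per label for categorical features; products of
per-dimension bins for vector features). For each ordered pair of groups the
**overlap score** is the fraction of k-nearest neighbours of the points of
`U` that fall in `V`, with neighbours searched only inside `U ∪ V − {u}`:

    OS_{U→V}(k) = (1 / |U|·k) · Σ_{u∈U} |kNN(u; U ∪ V − {u}) ∩ V|

(a radius-r neighbourhood may replace the k nearest for clouds of uneven
density). The scores form an `n×n` adjacency matrix `M` with zero diagonal —
a weighted directed graph over the bin-groups — and the Structure Index is
one minus its scaled mean weighted out-degree:

    SI(M) = 1 − (2 / (n² − n)) · Σ_i Σ_j M_ij

A randomly distributed feature overlaps every pair at ≈ 0.5, giving SI = 0;
perfectly separated bin-groups give SI = 1. Small samples with small k can
produce slightly negative raw values, which are clipped to 0 (the raw value
is kept for diagnostics). Significance is assessed against the 99th
percentile of a permutation null (feature values shuffled over the points).
Sweeping k (or r) profiles local versus global organisation: locally
repeating features lose SI sharply as k grows, global gradients decay
smoothly. The directed graph itself is a diagnostic — distributions with
equal SI can have different topology, and edge asymmetry shows which group
infiltrates which.

## Worked example

```python
import numpy as np
from structindex import StructureIndex
from structindex.synthetic import gradient_ellipsoid

# 2D ellipse with a feature gradient along its major axis
X, y = gradient_ellipsoid(n_points=3000, seed=42)

si = StructureIndex(n_bins=10, n_neighbors=3,
                    n_shuffles=100, random_state=0).fit(X, y)
print(f"SI = {si.si_:.3f} (raw {si.si_raw_:.3f})")
print(f"null 99th percentile = {si.null_percentile_99_:.3f}")

rng = np.random.default_rng(0)
si0 = StructureIndex(n_bins=10, n_neighbors=3).fit(X, rng.permutation(y))
print(f"shuffled-feature SI = {si0.si_:.3f} (raw {si0.si_raw_:.3f})")
```

prints

```
SI = 0.989 (raw 0.989)
null 99th percentile = 0.015
shuffled-feature SI = 0.000 (raw -0.021)
```

The gradient is almost maximally structured (SI ≈ 0.99, far above the
shuffle threshold of 0.015), while the same values randomly reassigned to
points carry no structure (SI clipped to 0 from a slightly negative raw
value). `si.overlap_` holds the directed overlap matrix,
`si.to_graph()` the weighted digraph (exportable with
`structindex.write_graph` as GraphML or TSV edge list), and
`structindex.sweep` profiles SI over a k-grid.

The estimator follows scikit-learn conventions (`get_params`/`set_params`,
`clone`, fitted attributes with trailing underscores); the equivalent
functional interface is `structindex.compute_si(X, y, ...)`.

## Command line

```
structindex generate --kind gradient_ellipsoid --n 3000 --seed 42 --out-dir toy
structindex compute --data toy/points.csv --feature toy/feature.csv \
    --k 3 --n-shuffles 100 --seed 0 --out-dir run
structindex sweep --data toy/points.csv --feature toy/feature.csv \
    --grid 3,10,30,100 --out-dir run
```

`compute` writes `result.json`, `overlap_matrix.csv`, a graph file, and the
null distribution; `generate` writes any synthetic toy cloud (gradient
ellipse, radial ball, D-spheres, local/global tilings, two-latent clouds,
discontinuous multipart stacks) with a provenance record.

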