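import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("derandomized", deadline=None, derandomize=True)
settings.load_profile("derandomized")


def brute_force_overlap_knn(u, v, k):
    """Independent reference for the directed kNN overlap score.

    Builds the full pairwise distance table for U ∪ V explicitly and sorts
    it per point; ties broken by within-pair column order (U first, then V)
    to mirror the deterministic convention.
    """
    u = np.atleast_2d(np.asarray(u, dtype=float))
    v = np.atleast_2d(np.asarray(v, dtype=float))
    both = np.vstack([u, v])
    n_u = len(u)
    total = 0
    for i in range(n_u):
        d = np.sqrt(((both - both[i]) ** 2).sum(axis=1))
        d[i] = np.inf  # exclude self
        order = np.argsort(d, kind="stable")[:k]
        total += int(np.sum(order >= n_u))
    return total / (n_u * k)


def brute_force_overlap_matrix(cloud, labels, k):
    """Reference overlap matrix: one brute-force score per ordered pair."""
    cloud = np.asarray(cloud, dtype=float)
    groups = sorted(set(labels[labels >= 0]))
    n = len(groups)
    m = np.zeros((n, n))
    for a, ga in enumerate(groups):
        for b, gb in enumerate(groups):
            if a == b:
                continue
            m[a, b] = brute_force_overlap_knn(
                cloud[labels == ga], cloud[labels == gb], k
            )
    return m


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def separated_groups():
    """Four 100-point 2D discs with centres 100 apart; feature = group id."""
    rng = np.random.default_rng(7)
    centers = np.array([[0.0, 0.0], [100.0, 0.0], [0.0, 100.0], [100.0, 100.0]])
    pts, feat = [], []
    for g, c in enumerate(centers):
        r = np.sqrt(rng.uniform(size=100))
        a = rng.uniform(0, 2 * np.pi, size=100)
        pts.append(c + np.column_stack([r * np.cos(a), r * np.sin(a)]))
        feat.append(np.full(100, g))
    return np.concatenate(pts), np.concatenate(feat)
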