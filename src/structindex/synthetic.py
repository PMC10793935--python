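"""Seedable toy point clouds with known feature structure.

These generators produce the validation surface for the Structure Index:
clouds where the ground-truth relation between geometry and feature is
known by construction — a linear gradient over an ellipse, concentric
shells of a solid ball, hyperspheres parameterised by their angles, local
versus global tilings of the same cloud, and a two-latent-feature cloud
whose geometry weights one latent by a gain α. Every generator is a pure
function of its parameters and seed.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "gradient_ellipsoid",
    "random_cloud",
    "radial_ball",
    "ndim_sphere",
    "local_and_global_patterns",
    "two_feature_cloud",
    "embed_and_rotate",
    "add_noise_snr",
    "discontinuous_multipart",
    "GENERATORS",
]


def _rng(seed):
    return np.random.default_rng(seed)


def gradient_ellipsoid(
    n_points: int = 40000,
    skewness: float = 0.0,
    noise_sd: float = 0.0,
    seed: int | None = None,
):
    """Uniform 2:1 ellipse with a feature gradient along the major axis.

    The feature is the major-axis coordinate passed through the monotone
    power transform ``u -> u**exp(skewness)`` on the unit interval, so
    ``skewness=0`` is the identity and any value preserves rank order —
    only the skewness of the feature's marginal changes, which the SI
    should shrug off.
    """
    if n_points < 10:
        raise ValueError("n_points must be >= 10")
    rng = _rng(seed)
    # uniform in the unit disc, then stretch x by 2
    radius = np.sqrt(rng.uniform(size=n_points))
    angle = rng.uniform(0, 2 * np.pi, size=n_points)
    pts = np.column_stack([2.0 * radius * np.cos(angle), radius * np.sin(angle)])
    u = (pts[:, 0] + 2.0) / 4.0  # major axis mapped to [0, 1]
    feature = u ** np.exp(skewness)
    if noise_sd > 0:
        pts = pts + rng.normal(scale=noise_sd, size=pts.shape)
    return pts, feature


def random_cloud(
    n_points: int = 5000, dim: int = 2, seed: int | None = None
):
    """Uniform cloud on the unit hypercube with an independent random feature.

    The feature is a random permutation of ``n_points`` uniformly spaced
    values in [0, 1]: its marginal is flat and its relation to position is
    pure chance, the canonical SI = 0 condition.
    """
    rng = _rng(seed)
    pts = rng.uniform(size=(n_points, dim))
    feature = rng.permutation(np.linspace(0.0, 1.0, n_points))
    return pts, feature


def radial_ball(
    n_points: int = 40000, noise_sd: float = 0.0, seed: int | None = None
):
    """3D ball sampled by uniform angles and radius; feature = radius.

    Azimuth uniform on [0, 2π), polar angle uniform on [0, π], radius
    uniform on [0, 1] (so density concentrates toward the centre and the
    poles — the sampling is uniform in the parameters, not in volume).
    Gaussian noise is added to the Euclidean coordinates; the feature is
    the radius before noise, so noise-free binning gives concentric shells.
    """
    if n_points < 10:
        raise ValueError("n_points must be >= 10")
    rng = _rng(seed)
    r = rng.uniform(size=n_points)
    theta = rng.uniform(0, np.pi, size=n_points)
    phi = rng.uniform(0, 2 * np.pi, size=n_points)
    pts = np.column_stack(
        [
            r * np.sin(theta) * np.cos(phi),
            r * np.sin(theta) * np.sin(phi),
            r * np.cos(theta),
        ]
    )
    if noise_sd > 0:
        pts = pts + rng.normal(scale=noise_sd, size=pts.shape)
    return pts, r


def _hypersphere_coords(angles: np.ndarray) -> np.ndarray:
    """Unit-radius hyperspherical-to-Cartesian recursion.

    With angles (t1, ..., t_{d-1}):
    x1 = cos t1, x2 = sin t1 cos t2, ..., x_d = sin t1 ... sin t_{d-1}.
    """
    n, n_ang = angles.shape
    dim = n_ang + 1
    pts = np.empty((n, dim))
    sin_prod = np.ones(n)
    for a in range(n_ang):
        pts[:, a] = sin_prod * np.cos(angles[:, a])
        sin_prod = sin_prod * np.sin(angles[:, a])
    pts[:, dim - 1] = sin_prod
    return pts


def ndim_sphere(
    dim: int = 3,
    n_points: int = 40000,
    noise_sd: float = 0.0,
    seed: int | None = None,
):
    """Unit D-sphere from uniform angles; feature = the angle vector.

    Angles θ_1..θ_{dim-2} are uniform on [0, π] and the final angle
    θ_{dim-1} uniform on [0, 2π). The first angle fully determines the
    first coordinate, so single-angle structure decreases along the angle
    list, and the azimuthal θ_{dim-1} carries the least as `dim` grows.
    Returns the (N, dim) noisy cloud and the (N, dim-1) angle matrix;
    individual angles are its columns.
    """
    if dim < 2:
        raise ValueError("dim must be >= 2")
    if n_points < 10:
        raise ValueError("n_points must be >= 10")
    rng = _rng(seed)
    angles = np.empty((n_points, dim - 1))
    for a in range(dim - 2):
        angles[:, a] = rng.uniform(0, np.pi, size=n_points)
    angles[:, dim - 2] = rng.uniform(0, 2 * np.pi, size=n_points)
    pts = _hypersphere_coords(angles)
    if noise_sd > 0:
        pts = pts + rng.normal(scale=noise_sd, size=pts.shape)
    return pts, angles


def local_and_global_patterns(
    n_points: int = 9000, n_tiles: int = 4, seed: int | None = None
):
    """One 2D cloud, two feature layouts: locally repeating vs one global ramp.

    The cloud is uniform on an ``n_tiles x 1`` strip split into unit tiles
    along x. The *local* feature ramps 0 -> 1 inside every tile
    independently, so the same bin-groups recur in each tile; the *global*
    feature ramps 0 -> 1 once across the whole strip. Both outputs share
    identical coordinates, isolating the feature layout as the only
    difference.
    """
    if n_tiles < 2:
        raise ValueError("n_tiles must be >= 2")
    rng = _rng(seed)
    x = rng.uniform(0, n_tiles, size=n_points)
    y = rng.uniform(0, 1, size=n_points)
    pts = np.column_stack([x, y])
    local_feature = np.mod(x, 1.0)
    global_feature = x / n_tiles
    return (pts, local_feature), (pts, global_feature)


def two_feature_cloud(
    n_points: int = 20000,
    alpha: float = 1.0,
    noise_sd: float = 0.0,
    seed: int | None = None,
):
    """2D cloud positioned by two latents a, b with a's gain set by α.

    Latents a, b ~ Uniform[0, 1]; coordinates (x, y) = (b, α·a) plus
    Gaussian noise. At α = 0 position is entirely determined by b; as α
    grows, a gains equal footing and the joint vector feature (a, b)
    becomes fully separable. Returns the cloud and the (N, 2) feature
    matrix with columns (a, b).
    """
    if alpha < 0:
        raise ValueError("alpha must be >= 0")
    rng = _rng(seed)
    a = rng.uniform(size=n_points)
    b = rng.uniform(size=n_points)
    pts = np.column_stack([b, alpha * a])
    if noise_sd > 0:
        pts = pts + rng.normal(scale=noise_sd, size=pts.shape)
    return pts, np.column_stack([a, b])


def embed_and_rotate(
    coords,
    target_dim: int,
    noise_sd: float = 0.0,
    seed: int | None = None,
) -> np.ndarray:
    """Embed a cloud in a higher dimension: pad, add noise, rotate randomly.

    Zero-pads to ``target_dim``, adds isotropic Gaussian noise on every
    coordinate, then applies a uniformly random rotation (QR-orthonormalised
    Gaussian matrix, Haar measure). The intrinsic geometry is untouched —
    at zero noise the map is an isometry — but the information spreads over
    all target dimensions.
    """
    x = np.asarray(coords, dtype=float)
    n, d = x.shape
    if target_dim < d:
        raise ValueError(f"target_dim {target_dim} below original dimension {d}")
    rng = _rng(seed)
    padded = np.zeros((n, target_dim))
    padded[:, :d] = x
    if noise_sd > 0:
        padded = padded + rng.normal(scale=noise_sd, size=padded.shape)
    q, r = np.linalg.qr(rng.normal(size=(target_dim, target_dim)))
    q = q * np.sign(np.diag(r))  # fix column signs -> Haar-distributed
    return padded @ q.T


def add_noise_snr(coords, snr: float, seed: int | None = None) -> np.ndarray:
    """Add isotropic Gaussian noise at a given signal-to-noise ratio.

    SNR is defined as a per-coordinate variance ratio: the noise variance
    on every coordinate equals (mean per-coordinate signal variance) / snr.
    Other SNR conventions exist; with this one, ``snr=1`` adds noise whose
    variance matches the average coordinate variance of the signal.
    """
    if snr <= 0:
        raise ValueError("snr must be positive")
    x = np.asarray(coords, dtype=float)
    rng = _rng(seed)
    noise_var = x.var(axis=0).mean() / snr
    return x + rng.normal(scale=np.sqrt(noise_var), size=x.shape)


def discontinuous_multipart(
    n_points: int = 32000, n_parts: int = 4, seed: int | None = None
):
    """Stack of spatially disjoint 3D discs with one feature ramping across.

    Part i is a thin solid cylinder (radius 1, height 0.2) centred on the
    z-axis at z = 2i, so consecutive parts are separated by a clear gap.
    The feature is the z coordinate, continuous and monotone along the
    stacking axis yet discontinuous in the cloud — structure the SI should
    still see at small k.
    """
    if n_parts < 2:
        raise ValueError("n_parts must be >= 2")
    if n_points < 10:
        raise ValueError("n_points must be >= 10")
    rng = _rng(seed)
    sizes = np.full(n_parts, n_points // n_parts)
    sizes[: n_points % n_parts] += 1
    pts = []
    for i in range(n_parts):
        m = sizes[i]
        radius = np.sqrt(rng.uniform(size=m))
        angle = rng.uniform(0, 2 * np.pi, size=m)
        z = 2.0 * i + rng.uniform(-0.1, 0.1, size=m)
        pts.append(
            np.column_stack([radius * np.cos(angle), radius * np.sin(angle), z])
        )
    cloud = np.concatenate(pts)
    return cloud, cloud[:, 2].copy()


#: Name -> generator registry used by the fixture CLI.
GENERATORS = {
    "gradient_ellipsoid": gradient_ellipsoid,
    "random_cloud": random_cloud,
    "radial_ball": radial_ball,
    "ndim_sphere": ndim_sphere,
    "local_pattern": local_and_global_patterns,
    "global_pattern": local_and_global_patterns,
    "two_feature": two_feature_cloud,
    "discontinuous_multipart": discontinuous_multipart,
}
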