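"""Uniform point clouds on the three constant-curvature model manifolds and
their geodesic distance matrices.

The three models are the unit hypercube ``[0,1]^dim`` (sectional curvature 0),
the unit sphere ``S^{dim-1}`` embedded in ``R^dim`` (curvature +1), and the
Poincaré ball model of hyperbolic space ``H^dim`` (curvature -1).  For the
sphere, ``dim`` is the AMBIENT dimension, so a correlation matrix of length-T
series corresponds to ``dim = T``; this convention is recorded in the cloud
metadata.

Hyperbolic sampling follows a two-stage construction: a point is drawn
uniformly in the Euclidean ball of radius R, its norm r is read as the
hyperbolic radial coordinate, and the point is radially rescaled into the
unit Poincaré ball so its new norm is ``(cosh r - 1) / (2 + cosh r)``.  The
parameter R therefore controls how deep into hyperbolic space the cloud
reaches: for R << 1 the cloud is metrically indistinguishable from a flat
Euclidean ball, while large R pushes points toward the ideal boundary.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import pdist, squareform

from .matrices import SymmetricMatrix

__all__ = [
    "PointCloud",
    "sample_euclidean",
    "sample_sphere",
    "sample_hyperbolic",
    "distance_matrix",
]

_STREAM_EUCLIDEAN = 1
_STREAM_SPHERE = 2
_STREAM_HYPERBOLIC = 3


def _rng(seed: int, stream: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(stream,)))


@dataclass
class PointCloud:
    """Sampled points on a model manifold plus geometry metadata.

    ``points`` has shape ``(n_points, ambient_dim)``.  ``radius`` is the
    hyperbolic sampling radius R and is ``None`` for the other geometries.
    """

    points: np.ndarray
    geometry: str
    seed: int
    radius: float | None = None

    def __post_init__(self) -> None:
        p = np.asarray(self.points, dtype=float)
        if p.ndim != 2:
            raise ValueError("points must be a 2-D array (n_points, dim)")
        if self.geometry not in ("euclidean", "sphere", "hyperbolic"):
            raise ValueError(f"unknown geometry {self.geometry!r}")
        self.points = p

    @property
    def n_points(self) -> int:
        return self.points.shape[0]

    @property
    def ambient_dim(self) -> int:
        return self.points.shape[1]


def sample_euclidean(n_points: int, dim: int, seed: int) -> PointCloud:
    """``n_points`` i.i.d. uniform samples from the unit hypercube [0,1]^dim."""
    if n_points < 1 or dim < 1:
        raise ValueError("n_points and dim must be positive")
    rng = _rng(seed, _STREAM_EUCLIDEAN)
    pts = rng.uniform(size=(n_points, dim))
    return PointCloud(pts, "euclidean", seed)


def sample_sphere(n_points: int, dim: int, seed: int) -> PointCloud:
    """``n_points`` uniform samples on the unit sphere S^{dim-1} in R^dim.

    Implemented as normalized isotropic Gaussian vectors; ``dim`` is the
    ambient dimension and must be at least 2.
    """
    if n_points < 1:
        raise ValueError("n_points must be positive")
    if dim < 2:
        raise ValueError("sphere sampling requires ambient dim >= 2")
    rng = _rng(seed, _STREAM_SPHERE)
    g = rng.standard_normal((n_points, dim))
    norms = np.linalg.norm(g, axis=1, keepdims=True)
    # a zero Gaussian vector has probability 0; guard anyway
    norms[norms == 0] = 1.0
    return PointCloud(g / norms, "sphere", seed)


def _cosh_map(r: np.ndarray) -> np.ndarray:
    """Radial transformation r -> (cosh r - 1)/(2 + cosh r) into the unit ball."""
    c = np.cosh(r)
    return (c - 1.0) / (2.0 + c)


def _radial_draw(u: np.ndarray, R: float, dim: int, law: str) -> np.ndarray:
    """Hyperbolic radial coordinates on [0, R] under the chosen law."""
    if law == "quasi_uniform":
        # area-corrected CDF (cosh r - 1)/(cosh R - 1), density ~ sinh r;
        # the standard radial law of hyperbolic random-graph models
        return np.arccosh(1.0 + u * (np.cosh(R) - 1.0))
    if law == "ball":
        return R * u ** (1.0 / dim)
    if law == "uniform":
        return R * u
    if law == "sinh_n":
        # true hyperbolic volume element sinh^(dim-1) r, inverted in log space
        grid = np.linspace(0.0, R, 4097)
        with np.errstate(divide="ignore"):
            logd = (dim - 1) * np.log(np.sinh(np.maximum(grid, 1e-300)))
        logd[0] = -np.inf
        w = np.exp(logd - logd.max())
        cdf = np.concatenate([[0.0], np.cumsum((w[1:] + w[:-1]) / 2.0)])
        cdf /= cdf[-1]
        return np.interp(u, cdf, grid)
    raise ValueError(f"unknown radial_law {law!r}")


def sample_hyperbolic(
    n_points: int,
    dim: int,
    R: float,
    seed: int,
    radial_law: str = "quasi_uniform",
) -> PointCloud:
    """``n_points`` points in the unit Poincaré ball of H^dim.

    A direction is drawn uniformly on the sphere, a radial coordinate r is
    drawn on [0, R] under ``radial_law``, and the point is placed at Poincaré
    norm ``(cosh r - 1)/(2 + cosh r)`` along that direction.  All output
    norms are strictly below 1.

    Radial laws
    -----------
    ``"quasi_uniform"`` (default)
        Density proportional to sinh r (closed-form inverse CDF
        ``arccosh(1 + u (cosh R - 1))``): the area-corrected law standard in
        hyperbolic random-graph models.  In high ambient dimension its O(R)
        radial spread dominates the O(1/sqrt(dim)) angular fluctuations,
        producing the near-zero-cycle regime characteristic of hyperbolic
        clouds at small R.
    ``"ball"``
        Volume-uniform draw in the Euclidean ball B^dim_R (radius CDF
        ``(r/R)^dim``).  In high dimension all radii concentrate at R, so
        the cloud degenerates to a sphere sample.
    ``"uniform"``
        Radius uniform on [0, R] (the naive ball draw).
    ``"sinh_n"``
        True hyperbolic volume element ``sinh^(dim-1) r`` (numerical
        inverse CDF); concentrates like ``"ball"`` in high dimension.
    """
    if n_points < 1 or dim < 1:
        raise ValueError("n_points and dim must be positive")
    if R <= 0:
        raise ValueError("hyperbolic radius R must be positive")
    rng = _rng(seed, _STREAM_HYPERBOLIC)
    g = rng.standard_normal((n_points, dim))
    norms = np.linalg.norm(g, axis=1, keepdims=True)
    norms[norms == 0] = 1.0
    directions = g / norms
    u = rng.uniform(size=n_points)
    r = _radial_draw(u, R, dim, radial_law)
    pts = directions * _cosh_map(r)[:, None]
    return PointCloud(pts, "hyperbolic", seed, radius=float(R))


def _poincare_distances(p: np.ndarray) -> np.ndarray:
    sq = np.sum(p * p, axis=1)
    if np.any(sq >= 1.0):
        raise ValueError("hyperbolic geodesic requires all norms < 1 (Poincaré ball)")
    diff2 = squareform(pdist(p, metric="sqeuclidean"))
    denom = np.outer(1.0 - sq, 1.0 - sq)
    arg = 1.0 + 2.0 * diff2 / denom
    return np.arccosh(np.maximum(arg, 1.0))


def distance_matrix(cloud: PointCloud, metric: str = "geodesic") -> SymmetricMatrix:
    """Pairwise distance matrix of a point cloud.

    ``metric="geodesic"`` uses the intrinsic metric of the cloud's geometry:
    Euclidean norm in the hypercube, great-circle distance
    ``arccos(<x, y>)`` on the sphere (inner products clamped to [-1,1]), and
    the Poincaré-ball distance
    ``arccosh(1 + 2|u-v|^2 / ((1-|u|^2)(1-|v|^2)))`` in hyperbolic space.
    ``metric="chordal"`` uses the plain Euclidean distance between ambient
    coordinates for any geometry.
    """
    if cloud.n_points < 2:
        raise ValueError("distance_matrix requires at least 2 points")
    if metric not in ("geodesic", "chordal"):
        raise ValueError(f"unknown metric {metric!r}")
    p = cloud.points
    if metric == "chordal" or cloud.geometry == "euclidean":
        d = squareform(pdist(p, metric="euclidean"))
    elif cloud.geometry == "sphere":
        gram = np.clip(p @ p.T, -1.0, 1.0)
        d = np.arccos(gram)
    else:
        d = _poincare_distances(p)
    d = (d + d.T) / 2.0
    np.fill_diagonal(d, 0.0)
    return SymmetricMatrix(d, role="distance")
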