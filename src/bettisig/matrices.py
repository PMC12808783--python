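"""Symmetric-matrix and time-series containers, plus the non-geometric
reference matrix models.

Three families of reference matrices are generated here:

* i.i.d. random symmetric matrices (``random_symmetric``) — the fully
  non-geometric null model,
* random correlation matrices (``random_correlation``) — Pearson correlation
  of independent Gaussian white-noise series,
* modular correlation systems (``modular_time_series``) — low-rank confound
  model built by cyclically copying a few base series and adding small noise.

The downstream Betti-curve pipeline depends only on the ordering of matrix
entries, so the choice of a continuous entry distribution for the random
symmetric model is immaterial; Uniform(0,1) is used.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "SymmetricMatrix",
    "TimeSeriesSet",
    "random_symmetric",
    "random_correlation",
    "pearson_correlation",
    "modular_time_series",
]

# Distinct sub-streams per generator so that adding replicates of one model
# never perturbs draws of another model run under the same user seed.
_STREAM_RANDOM_SYMMETRIC = 4
_STREAM_RANDOM_CORRELATION = 5
_STREAM_MODULAR = 6


def _rng(seed: int, stream: int) -> np.random.Generator:
    """Generator on an independent, documented sub-stream of ``seed``."""
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(stream,)))


@dataclass
class SymmetricMatrix:
    """A square symmetric real matrix with a declared role.

    Parameters
    ----------
    values
        ``(N, N)`` real array; symmetry is validated to 1e-12.
    role
        One of ``"distance"`` (zero diagonal, non-negative entries),
        ``"correlation"`` (unit diagonal, entries in [-1, 1]) or
        ``"generic"`` (no constraint beyond symmetry).
    """

    values: np.ndarray
    role: str = "generic"

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ValueError(f"matrix must be square, got shape {v.shape}")
        if not np.all(np.isfinite(v)):
            raise ValueError("matrix contains NaN or infinite entries")
        if np.max(np.abs(v - v.T)) > 1e-12:
            raise ValueError("matrix is not symmetric within 1e-12")
        if self.role not in ("distance", "correlation", "generic"):
            raise ValueError(f"unknown role {self.role!r}")
        if self.role == "distance":
            if np.max(np.abs(np.diag(v))) > 0:
                raise ValueError("distance matrix must have zero diagonal")
            if np.min(v) < 0:
                raise ValueError("distance matrix must be non-negative")
        elif self.role == "correlation":
            if np.max(np.abs(np.diag(v) - 1.0)) > 1e-12:
                raise ValueError("correlation matrix must have unit diagonal")
            if np.min(v) < -1.0 - 1e-12 or np.max(v) > 1.0 + 1e-12:
                raise ValueError("correlation entries must lie in [-1, 1]")
        self.values = v

    @property
    def n(self) -> int:
        return self.values.shape[0]


@dataclass
class TimeSeriesSet:
    """A set of equally sampled time series, rows = time points.

    ``values`` has shape ``(T, N)``; ``labels`` names the N series.
    """

    values: np.ndarray
    labels: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2:
            raise ValueError("time series values must be a 2-D array (T, N)")
        if not np.all(np.isfinite(v)):
            raise ValueError("time series contain NaN or infinite values")
        if not self.labels:
            self.labels = [f"s{i:03d}" for i in range(v.shape[1])]
        if len(self.labels) != v.shape[1]:
            raise ValueError("number of labels must match number of series")
        self.values = v

    @property
    def n_timepoints(self) -> int:
        return self.values.shape[0]

    @property
    def n_series(self) -> int:
        return self.values.shape[1]


def random_symmetric(n: int, seed: int) -> SymmetricMatrix:
    """Symmetric matrix with i.i.d. Uniform(0,1) off-diagonal entries.

    The diagonal is zero and the strict upper triangle is mirrored; with
    probability one all off-diagonal values are distinct, so the induced
    edge ordering is unambiguous.
    """
    if n < 2:
        raise ValueError("random_symmetric requires n >= 2")
    rng = _rng(seed, _STREAM_RANDOM_SYMMETRIC)
    m = np.zeros((n, n))
    iu, ju = np.triu_indices(n, 1)
    m[iu, ju] = rng.uniform(size=iu.size)
    m += m.T
    return SymmetricMatrix(m, role="generic")


def random_correlation(n_series: int, length: int, seed: int) -> SymmetricMatrix:
    """Sample Pearson correlation matrix of independent Gaussian white noise.

    ``length`` plays the role of the series length T; for T comparable to
    ``n_series`` the matrix is far from the identity and carries the
    spherical geometry of normalized T-vectors.
    """
    if n_series < 2:
        raise ValueError("random_correlation requires n_series >= 2")
    if length < 3:
        raise ValueError("random_correlation requires length >= 3")
    rng = _rng(seed, _STREAM_RANDOM_CORRELATION)
    series = rng.standard_normal((length, n_series))
    return pearson_correlation(TimeSeriesSet(series))


def pearson_correlation(ts: TimeSeriesSet) -> SymmetricMatrix:
    """Pearson product-moment correlation matrix of a TimeSeriesSet."""
    v = ts.values
    if v.shape[0] < 2:
        raise ValueError("correlation requires at least 2 time points")
    sd = v.std(axis=0)
    zero = np.flatnonzero(sd == 0)
    if zero.size:
        names = ", ".join(ts.labels[i] for i in zero[:5])
        raise ValueError(f"zero-variance series cannot be correlated: {names}")
    c = np.corrcoef(v, rowvar=False)
    c = np.clip((c + c.T) / 2.0, -1.0, 1.0)
    np.fill_diagonal(c, 1.0)
    return SymmetricMatrix(c, role="correlation")


def modular_time_series(
    m: int,
    n_series: int = 90,
    length: int = 400,
    noise_sd: float = 0.01,
    seed: int = 0,
) -> TimeSeriesSet:
    """Modular system of ``n_series`` series built from ``m`` base series.

    Draws ``m`` independent standard-Gaussian base series and tiles them
    cyclically, ``[M_1..M_m, M_1..M_m, ..., M_1..M_k]`` with
    ``k = n_series mod m`` (the tail reuses the first base series), so
    columns i and j are copies of the same base series iff ``i == j (mod m)``.
    Independent Gaussian noise of standard deviation ``noise_sd`` is then
    added to every column.  The resulting correlation matrix has numerical
    rank ~ m as ``noise_sd -> 0``.

    Parameters
    ----------
    m
        Number of modules (distinct base series), ``1 <= m <= n_series``.
    noise_sd
        Standard deviation of the post-copy white noise; base series have
        unit standard deviation, so this is also the relative amplitude.
    """
    if not 1 <= m <= n_series:
        raise ValueError(f"m must lie in 1..{n_series}, got {m}")
    if noise_sd < 0:
        raise ValueError("noise_sd must be non-negative")
    rng = _rng(seed, _STREAM_MODULAR)
    base = rng.standard_normal((length, m))
    cols = base[:, np.arange(n_series) % m]
    noisy = cols + noise_sd * rng.standard_normal((length, n_series))
    labels = [f"m{(i % m) + 1:02d}_c{i:02d}" for i in range(n_series)]
    return TimeSeriesSet(noisy, labels=labels)
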