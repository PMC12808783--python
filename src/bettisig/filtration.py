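"""Order complexes: the ascending edge filtration induced by a symmetric matrix.

Given an N x N symmetric matrix read as edge weights of the complete graph,
the order complex is the nested graph sequence ``G_0 ⊆ G_1 ⊆ ... ⊆ G_K``
obtained by inserting the K = N(N-1)/2 edges one at a time in ascending
weight order (ties broken lexicographically by vertex pair).  Every
downstream topological quantity depends only on this edge ORDER, which is
what makes the pipeline invariant under strictly monotone entrywise
transformations of the matrix.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .matrices import SymmetricMatrix

__all__ = ["OrderComplex", "corr_to_distance", "build_order_complex"]


@dataclass
class OrderComplex:
    """Edge filtration of the complete graph on ``n_vertices``.

    ``edges`` is a ``(K, 2)`` int array with ``edges[t] = (i, j)``, ``i < j``,
    the edge added at step ``t + 1``; ``weights`` carries the corresponding
    matrix entries in non-decreasing order.  Step 0 is the empty graph.
    """

    n_vertices: int
    edges: np.ndarray
    weights: np.ndarray

    def __post_init__(self) -> None:
        e = np.asarray(self.edges, dtype=np.int64)
        w = np.asarray(self.weights, dtype=float)
        if e.ndim != 2 or e.shape[1] != 2 or e.shape[0] != w.shape[0]:
            raise ValueError("edges must be (K, 2) with matching weights")
        self.edges = e
        self.weights = w

    @property
    def n_steps(self) -> int:
        """Number of edges K (the filtration has K+1 graphs incl. empty G_0)."""
        return self.edges.shape[0]

    @property
    def densities(self) -> np.ndarray:
        """Edge density j/K of graph G_j, for j = 0..K."""
        k = self.n_steps
        return np.arange(k + 1) / k

    def edge_ranks(self) -> np.ndarray:
        """Dense (N, N) lookup: symmetric matrix of 0-based filtration ranks."""
        r = np.zeros((self.n_vertices, self.n_vertices), dtype=np.int64)
        r[self.edges[:, 0], self.edges[:, 1]] = np.arange(self.n_steps)
        r += r.T
        return r


def corr_to_distance(C: SymmetricMatrix) -> SymmetricMatrix:
    """Entrywise ``1 - C``: the standard correlation-to-distance conversion.

    The map is monotone decreasing, so the induced edge order agrees with
    the spherical angle ``arccos(C)`` — correlation matrices carry an
    intrinsic spherical geometry at the filtration level.
    """
    if C.role != "correlation":
        raise ValueError("corr_to_distance expects a correlation matrix")
    d = 1.0 - C.values
    np.fill_diagonal(d, 0.0)
    return SymmetricMatrix(d, role="distance")


def build_order_complex(D: SymmetricMatrix | np.ndarray, order: str = "ascending") -> OrderComplex:
    """Sort the off-diagonal entries of a symmetric matrix into a filtration.

    Parameters
    ----------
    D
        Symmetric matrix (any role); the diagonal is ignored.
    order
        ``"ascending"`` (default, min-to-max: the distance convention) or
        ``"descending"`` (max-to-min, for raw similarity input).  Ties are
        broken lexicographically by (i, j) in both directions.
    """
    if order not in ("ascending", "descending"):
        raise ValueError(f"unknown order {order!r}")
    if isinstance(D, SymmetricMatrix):
        v = D.values
    else:
        v = np.asarray(D, dtype=float)
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ValueError("matrix must be square")
        if np.max(np.abs(v - v.T)) > 1e-12:
            raise ValueError("matrix is not symmetric within 1e-12")
    n = v.shape[0]
    if n < 2:
        raise ValueError("order complex requires at least 2 vertices")
    iu, ju = np.triu_indices(n, 1)
    w = v[iu, ju]
    key = w if order == "ascending" else -w
    idx = np.lexsort((ju, iu, key))
    return OrderComplex(n, np.column_stack([iu[idx], ju[idx]]), w[idx])
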