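"""Betti curves of flag filtrations, validated against the brute-force oracle."""

import numpy as np
import pytest

from bettisig.filtration import build_order_complex
from bettisig.homology import (
    CapacityError,
    betti_curves,
    brute_force_betti,
    brute_force_curves,
)
from bettisig.matrices import random_symmetric


def _matrix_from_weights(n, pairs_weights):
    m = np.zeros((n, n))
    for (i, j), w in pairs_weights.items():
        m[i, j] = m[j, i] = w
    return m


class TestBruteForceOracle:
    def test_filled_triangle(self):
        # the 3-cycle spans a 2-simplex in the clique complex: no hole
        assert brute_force_betti([(0, 1), (1, 2), (0, 2)], 3, 1) == [1, 0]

    def test_chordless_4_cycle(self):
        assert brute_force_betti([(0, 1), (1, 2), (2, 3), (0, 3)], 4, 1) == [1, 1]

    def test_two_disjoint_edges(self):
        assert brute_force_betti([(0, 1), (2, 3)], 4, 1) == [2, 0]

    def test_empty_graph(self):
        assert brute_force_betti([], 5, 2) == [5, 0, 0]

    def test_oracle_cap(self):
        with pytest.raises(ValueError):
            brute_force_betti([], 17, 1)


class TestKnownComplexes:
    def test_square_then_diagonal(self):
        # short sides first: after 4 steps one loop; a diagonal fills it
        w = {(0, 1): 1, (1, 2): 2, (2, 3): 3, (0, 3): 4, (0, 2): 5, (1, 3): 6}
        bc = betti_curves(build_order_complex(_matrix_from_weights(4, w)), max_dim=1)
        assert bc.curves[0, 4] == 1 and bc.curves[1, 4] == 1
        assert bc.curves[1, 5] == 0  # diagonal splits the square into triangles

    def test_octahedron_two_sphere(self):
        # six vertices, adjacent pairs at weight 1, antipodal pairs at weight 2;
        # at the 12-edge step the flag complex is the octahedral 2-sphere
        antipodal = {(0, 5), (1, 4), (2, 3)}
        w = {}
        for i in range(6):
            for j in range(i + 1, 6):
                w[(i, j)] = 2.0 if (i, j) in antipodal else 1.0
        D = _matrix_from_weights(6, w)
        bc = betti_curves(build_order_complex(D), max_dim=2)
        assert list(bc.curves[:, 12]) == [1, 0, 1]
        # cross-check the fixture itself with the independent oracle
        oc = build_order_complex(D)
        edges12 = [tuple(e) for e in oc.edges[:12]]
        assert brute_force_betti(edges12, 6, 2) == [1, 0, 1]

    def test_two_vertex_filtration(self):
        bc = betti_curves(build_order_complex(random_symmetric(2, seed=1)), max_dim=1)
        assert list(bc.curves[0]) == [2, 1]
        assert list(bc.curves[1]) == [0, 0]


class TestCurveInvariants:
    @pytest.mark.parametrize("seed", range(4))
    def test_boundary_steps(self, seed):
        bc = betti_curves(build_order_complex(random_symmetric(9, seed)), max_dim=2)
        n, k = 9, bc.n_steps
        assert bc.curves[0, 0] == n and np.all(bc.curves[1:, 0] == 0)
        assert bc.curves[0, k] == 1 and np.all(bc.curves[1:, k] == 0)
        assert np.all(np.diff(bc.curves[0]) <= 0)  # beta0 never increases

    def test_oracle_equivalence_random_matrices(self):
        for seed in range(10):
            oc = build_order_complex(random_symmetric(10, seed))
            fast = betti_curves(oc, max_dim=2).curves
            slow = brute_force_curves(oc, 2)
            assert np.array_equal(fast, slow)

    def test_oracle_equivalence_dim3(self):
        for seed in range(3):
            oc = build_order_complex(random_symmetric(7, seed))
            assert np.array_equal(betti_curves(oc, max_dim=3).curves, brute_force_curves(oc, 3))

    def test_euler_characteristic(self):
        # with all cliques counted, alternating Betti sum == alternating simplex count
        from itertools import combinations

        for seed in range(3):
            n = 7
            M = random_symmetric(n, seed)
            oc = build_order_complex(M)
            bc = betti_curves(oc, max_dim=3)  # max clique has <= 5 vertices only late
            erank = oc.edge_ranks()
            for j in (3, 8, 14):
                edges = {tuple(e) for e in oc.edges[:j]}
                adj = np.zeros((n, n), bool)
                for a, b in edges:
                    adj[a, b] = adj[b, a] = True
                counts = [n]
                max_clique = 0
                for q in range(1, 5):
                    cs = [
                        c
                        for c in combinations(range(n), q + 1)
                        if all(adj[a, b] for a, b in combinations(c, 2))
                    ]
                    counts.append(len(cs))
                    if cs:
                        max_clique = q
                if max_clique + 1 <= 4:  # all cliques of this graph are counted
                    chi_simplices = sum((-1) ** q * c for q, c in enumerate(counts))
                    chi_betti = sum((-1) ** i * bc.curves[i, j] for i in range(4))
                    assert chi_betti == chi_simplices

    @pytest.mark.parametrize(
        "f", [lambda x: x + 2.0, np.exp, lambda x: x**3], ids=["shift", "exp", "cube"]
    )
    def test_monotone_invariance_bit_exact(self, f):
        for seed in range(3):
            D = random_symmetric(10, seed).values
            fD = f(D)
            np.fill_diagonal(fD, 0.0)
            a = betti_curves(build_order_complex(D), max_dim=2).curves
            b = betti_curves(build_order_complex(fD), max_dim=2).curves
            assert np.array_equal(a, b)

    def test_beta0_matches_oracle_on_ties(self):
        D = np.ones((5, 5)) - np.eye(5)  # fully degenerate weights
        oc = build_order_complex(D)
        assert np.array_equal(betti_curves(oc, max_dim=1).curves, brute_force_curves(oc, 1))


class TestGuards:
    def test_max_dim_range(self):
        oc = build_order_complex(random_symmetric(5, 0))
        with pytest.raises(ValueError):
            betti_curves(oc, max_dim=4)

    def test_vertex_cap_for_high_dims(self):
        oc = build_order_complex(random_symmetric(10, 0))
        with pytest.raises(CapacityError, match="max_dim"):
            betti_curves(oc, max_dim=2, vertex_cap=8)
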