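"""Entropy signatures, Hungarian alignment, and the integrated score."""

import math

import networkx as nx
import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from netpep.alignment import (
    align,
    align_graphs,
    cost_matrix,
    entropy_signature,
    integrated_score,
    s_ae,
    time_schedule,
    transition_matrix,
)
from netpep.graph_core import NetworkGraph
from oracles import assignment_bruteforce
from conftest import random_graph


def connected_random_graph(rng, n, p=0.4):
    while True:
        g = random_graph(rng, n, p)
        if g.n_nodes and nx.is_connected(g.to_networkx()):
            return g


class TestTransitionMatrix:
    def test_triangle_rows(self, triangle):
        _, t = transition_matrix(triangle)
        assert np.allclose(t, np.full((3, 3), 0.5) - 0.5 * np.eye(3))

    def test_star_rows(self):
        g = NetworkGraph([("C", "L1"), ("C", "L2"), ("C", "L3")])
        order, t = transition_matrix(g)
        i = order.index("C")
        assert np.allclose(t[i], [0 if n == "C" else 1 / 3 for n in order])
        for j, n in enumerate(order):
            if n != "C":
                assert t[j, i] == 1.0

    def test_rows_stochastic_with_isolated_node(self, rng):
        g = NetworkGraph([("A", "B")], nodes=["Z"])
        _, t = transition_matrix(g)
        assert np.allclose(t.sum(axis=1), 1.0)


class TestEntropySignature:
    def test_single_edge_point_mass(self):
        g = NetworkGraph([("A", "B")])
        sig = entropy_signature(g, [1])
        assert np.allclose(sig.m, 0.0)

    def test_complete_graph_approaches_uniform(self):
        k4 = NetworkGraph([(f"v{i}", f"v{j}") for i in range(4) for j in range(i + 1, 4)])
        sig = entropy_signature(k4, [1, 64])
        # at large t the walk mixes to uniform: normalised entropy -> 1
        assert np.all(sig.m[:, 1] > 0.99)

    def test_t2_matches_explicit_square(self, rng):
        g = connected_random_graph(rng, 7)
        _, t = transition_matrix(g)
        a2 = t @ t
        expected = np.array(
            [-sum(p * math.log(p) for p in row if p > 1e-15) for row in a2]
        ) / math.log(g.n_nodes)
        sig = entropy_signature(g, [2])
        assert np.allclose(sig.m[:, 0], expected)

    def test_relabeling_invariance(self, rng):
        g = connected_random_graph(rng, 8)
        mapping = {n: f"zz{n}" for n in sorted(g.nodes)}
        h = NetworkGraph.from_networkx(nx.relabel_nodes(g.to_networkx(), mapping))
        sg = entropy_signature(g, [1, 2, 4])
        sh = entropy_signature(h, [1, 2, 4])
        for i, n in enumerate(sg.nodes):
            j = sh.nodes.index(mapping[n])
            assert np.allclose(sg.m[i], sh.m[j])


class TestTimeSchedule:
    @pytest.mark.parametrize(
        "diameter,expected",
        [(1, [1, 2]), (3, [1, 2, 4, 8]), (4, [1, 2, 4, 8])],
    )
    def test_doubling_rule(self, diameter, expected):
        g = NetworkGraph([(f"p{i}", f"p{i+1}") for i in range(diameter)])  # path, diameter D
        assert g.diameter() == diameter
        assert time_schedule(g, g) == expected

    def test_uses_max_of_the_pair(self, triangle):
        path = NetworkGraph([("a", "b"), ("b", "c"), ("c", "d")])  # D=3
        assert time_schedule(triangle, path) == [1, 2, 4, 8]


class TestCostMatrixAndAlign:
    def test_identical_signatures_zero_diagonal(self, rng):
        g = connected_random_graph(rng, 6)
        sig = entropy_signature(g, [1, 2])
        c = cost_matrix(sig, sig)
        assert np.allclose(np.diag(c), 0.0)

    def test_single_time_squared_difference(self):
        from netpep.alignment import EntropySignature

        a = EntropySignature("a", ["x"], np.array([[0.2]]), [1])
        b = EntropySignature("b", ["y"], np.array([[0.5]]), [1])
        assert cost_matrix(a, b)[0, 0] == pytest.approx(0.09)

    def test_padding_to_square(self):
        from netpep.alignment import EntropySignature

        a = EntropySignature("a", ["x", "y"], np.array([[0.2], [0.4]]), [1])
        b = EntropySignature("b", ["z"], np.array([[0.5]]), [1])
        c = cost_matrix(a, b)
        assert c.shape == (2, 2)
        # column 1 is the all-zero padded node: cost = sum_t M^2
        assert c[0, 1] == pytest.approx(0.04) and c[1, 1] == pytest.approx(0.16)

    def test_mismatched_schedules_rejected(self):
        from netpep.alignment import EntropySignature

        a = EntropySignature("a", ["x"], np.array([[0.2]]), [1])
        b = EntropySignature("b", ["y"], np.array([[0.5]]), [2])
        with pytest.raises(ValueError):
            cost_matrix(a, b)

    def test_known_3x3_assignment(self):
        c = np.array([[4.0, 1, 3], [2, 0, 5], [3, 2, 2]])
        _, cost = align(c)
        assert cost == 5.0  # exhaustive 3! search gives 1 + 2 + 2

    def test_zero_diagonal_prefers_identity(self):
        c = np.array([[0.0, 2, 2], [2, 0, 2], [2, 2, 0]])
        assignment, cost = align(c)
        assert cost == 0.0 and all(r == col for r, col in assignment)

    def test_non_square_rejected(self):
        with pytest.raises(ValueError):
            align(np.zeros((2, 3)))

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 10_000), n=st.integers(2, 6))
    def test_matches_bruteforce_and_permutation_invariant(self, seed, n):
        rng = np.random.default_rng(seed)
        c = rng.random((n, n))
        _, cost = align(c)
        assert cost == pytest.approx(assignment_bruteforce(c))
        perm = rng.permutation(n)
        _, cost_p = align(c[perm])
        assert cost_p == pytest.approx(cost)


class TestSAEAndIntegratedScore:
    def test_self_similarity_is_one(self, rng):
        for _ in range(5):
            g = connected_random_graph(rng, int(rng.integers(4, 9)))
            assert s_ae(g, g) == 1.0

    def test_isomorphic_copies_score_one(self, rng):
        g = connected_random_graph(rng, 7)
        h = NetworkGraph.from_networkx(
            nx.relabel_nodes(g.to_networkx(), {n: f"m{n}" for n in g.nodes})
        )
        assert s_ae(g, h) == pytest.approx(1.0)

    def test_triangle_vs_path_below_one(self, triangle, path3):
        r = align_graphs(triangle, path3)
        assert 0 < r.s_ae < 1
        assert r.s_ae == pytest.approx(math.exp(-r.total_cost / 3))

    def test_integrated_self_score_is_two(self, rng):
        g = connected_random_graph(rng, 8)
        r = integrated_score(g, g)
        assert r.s_gdd == 1.0 and r.s_ae == 1.0 and r.s_integrated == 2.0

    def test_symmetry(self, rng):
        g = connected_random_graph(rng, 6)
        w = connected_random_graph(rng, 7)
        assert integrated_score(g, w).s_integrated == pytest.approx(
            integrated_score(w, g).s_integrated
        )

    def test_rewiring_degrades_median_similarity(self):
        # double-edge-swap noise: more swaps should not increase similarity
        base_nx = nx.connected_watts_strogatz_graph(16, 4, 0.1, seed=3)
        base = NetworkGraph.from_networkx(base_nx)
        medians = []
        for n_swaps in (1, 4, 16):
            vals = []
            for rep in range(8):
                h = base_nx.copy()
                nx.double_edge_swap(h, nswap=n_swaps, max_tries=500, seed=rep)
                vals.append(s_ae(base, NetworkGraph.from_networkx(h)))
            medians.append(np.median(vals))
        assert medians[0] >= medians[-1] - 0.02  # non-increasing trend, small slack
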