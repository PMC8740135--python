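"""Separation score, permutation null, FDR, and the pair filter."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from netpep.disease_similarity import (
    SeparationResult,
    fdr_adjust,
    filter_similar_pairs,
    mean_between_distance,
    mean_internal_distance,
    permutation_test,
    separation_score,
)
from netpep.graph_core import GeneSet, NetworkGraph, SetCategory
from oracles import nearest_neighbor_means
from conftest import random_graph


def gs(name, genes):
    return GeneSet(name, frozenset(genes), SetCategory.disease)


class TestDistanceMeans:
    def test_triangle_all_nodes(self, triangle):
        assert mean_internal_distance(triangle, gs("a", {"A", "B", "C"})) == 1.0

    def test_path_endpoints(self):
        g = NetworkGraph([("A", "B"), ("B", "C"), ("C", "D")])
        assert mean_internal_distance(g, gs("a", {"A", "D"})) == 3.0

    def test_identical_sets_have_zero_between(self, triangle):
        a = gs("a", {"A", "B"})
        assert mean_between_distance(triangle, a, a) == 0.0

    def test_path_between(self, path3):
        assert mean_between_distance(path3, gs("a", {"A"}), gs("b", {"C"})) == 2.0

    def test_degenerate_set_rejected(self, triangle):
        with pytest.raises(ValueError, match="degenerate"):
            mean_internal_distance(triangle, gs("a", {"A", "ZZZ"}))

    def test_disconnected_sets_rejected(self):
        g = NetworkGraph([("A", "B"), ("C", "D")])
        with pytest.raises(ValueError, match="disconnected"):
            mean_between_distance(g, gs("a", {"A", "B"}), gs("b", {"C", "D"}))

    @settings(max_examples=40, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 10_000))
    def test_means_match_exhaustive_oracle(self, seed):
        rng = np.random.default_rng(seed)
        g = random_graph(rng, 12, p=0.35)
        nodes = sorted(g.nodes)
        a = set(rng.choice(nodes, size=4, replace=False))
        b = set(rng.choice(nodes, size=4, replace=False))
        o_aa, o_bb, o_ab = nearest_neighbor_means(g.to_networkx(), a, b)
        assert mean_internal_distance(g, gs("a", a)) == pytest.approx(o_aa)
        assert mean_internal_distance(g, gs("b", b)) == pytest.approx(o_bb)
        assert mean_between_distance(g, gs("a", a), gs("b", b)) == pytest.approx(o_ab)


class TestSeparationScore:
    def test_self_pair_is_minus_internal(self, rng):
        g = random_graph(rng, 10, p=0.5)
        a = gs("a", set(list(sorted(g.nodes))[:4]))
        assert separation_score(g, a, a) == pytest.approx(-mean_internal_distance(g, a))

    def test_interleaved_sets_on_clique_are_zero(self):
        nodes = [f"V{i}" for i in range(6)]
        g = NetworkGraph([(u, v) for i, u in enumerate(nodes) for v in nodes[i + 1 :]])
        assert separation_score(g, gs("a", set(nodes[:3])), gs("b", set(nodes[3:]))) == 0.0

    def test_far_components_give_large_positive_s(self):
        # dumbbell: two triangles joined by a long path
        edges = [("A1", "A2"), ("A2", "A3"), ("A3", "A1"),
                 ("B1", "B2"), ("B2", "B3"), ("B3", "B1"),
                 ("A1", "p1"), ("p1", "p2"), ("p2", "p3"), ("p3", "B1")]
        g = NetworkGraph(edges)
        s = separation_score(g, gs("a", {"A1", "A2", "A3"}), gs("b", {"B1", "B2", "B3"}))
        assert s > 2.0

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 10_000))
    def test_symmetry(self, seed):
        rng = np.random.default_rng(seed)
        g = random_graph(rng, 10, p=0.4)
        nodes = sorted(g.nodes)
        a = gs("a", set(rng.choice(nodes, size=3, replace=False)))
        b = gs("b", set(rng.choice(nodes, size=3, replace=False)))
        assert separation_score(g, a, b) == pytest.approx(separation_score(g, b, a))


class TestPermutationTest:
    def test_deterministic_under_seed(self, rng):
        g = random_graph(rng, 40, p=0.15)
        nodes = sorted(g.nodes)
        a = gs("a", set(nodes[:5]))
        b = gs("b", set(nodes[5:10]))
        r1 = permutation_test(g, a, b, n_perm=100, seed=11)
        r2 = permutation_test(g, a, b, n_perm=100, seed=11)
        assert r1 == r2

    def test_tight_module_scores_below_null(self):
        # a clique planted in a scale-free background, compared with itself:
        # S_obs = -d_aa sits far below the degree-matched null, so the raw
        # z is strongly negative (= highly similar)
        import networkx as nx

        ba = nx.barabasi_albert_graph(120, 2, seed=1)
        clique_nodes = [f"C{i}" for i in range(6)]
        g_nx = nx.relabel_nodes(ba, {i: f"B{i}" for i in range(120)})
        g_nx.add_edges_from(
            (u, v) for i, u in enumerate(clique_nodes) for v in clique_nodes[i + 1 :]
        )
        g_nx.add_edge("C0", "B0")
        g = NetworkGraph.from_networkx(g_nx)
        a = gs("a", set(clique_nodes))
        z, p = permutation_test(g, a, a, n_perm=200, seed=5)
        assert z < -1.6 and p < 0.05


class TestFDRAndFilter:
    def test_bh_hand_example(self):
        # p*(m/rank) = .04, .04, .04, .04 after the step-up pass
        assert fdr_adjust([0.01, 0.02, 0.03, 0.04]) == pytest.approx([0.04] * 4)

    def test_single_p_unchanged_and_all_ones(self):
        assert fdr_adjust([0.3]) == pytest.approx([0.3])
        assert fdr_adjust([1.0, 1.0, 1.0]) == pytest.approx([1.0] * 3)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            fdr_adjust([0.5, 1.5])

    def test_monotone_in_p_rank(self, rng):
        p = rng.random(50)
        q = fdr_adjust(p)
        order = np.argsort(p)
        assert np.all(np.diff(q[order]) >= -1e-12)

    def test_filter_inclusive_bounds(self):
        def res(z, q):
            return SeparationResult("a", "b", 1, 1, 1, 0, z, 0.001, q)

        kept = filter_similar_pairs([res(1.6, 0.001), res(1.59, 0.001), res(1.6, 0.0011)])
        assert len(kept) == 1 and kept[0].z_score == 1.6

    def test_empty_input(self):
        assert filter_similar_pairs([]) == []
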