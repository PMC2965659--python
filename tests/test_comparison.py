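"""Graph-to-graph distances, correlation with attainable bounds, and the
coincidence similarity."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from netcompare.comparison import (
    costa_similarity,
    compare_all,
    graph_correlation,
    hamming_distance,
    structural_distance,
)
from netcompare.graph import Graph

from conftest import complete_graph, random_graph


def path4():
    a = np.zeros((4, 4), dtype=np.int8)
    for i in range(3):
        a[i, i + 1] = a[i + 1, i] = 1
    return Graph(a)


def star4():
    a = np.zeros((4, 4), dtype=np.int8)
    a[0, 1:] = 1
    a[1:, 0] = 1
    return Graph(a)


def complement(g: Graph) -> Graph:
    a = 1 - g.adjacency
    np.fill_diagonal(a, 0)
    return Graph(a)


def brute_force_structural(g1: Graph, g2: Graph) -> int:
    """Independent exhaustive-permutation oracle."""
    n = g1.n_nodes
    off = ~np.eye(n, dtype=bool)
    best = None
    for perm in itertools.permutations(range(n)):
        p = np.array(perm)
        d = int(np.sum((g1.adjacency != g2.adjacency[np.ix_(p, p)]) & off))
        best = d if best is None else min(best, d)
    return best


class TestHamming:
    def test_identical_graphs(self, rng):
        g = random_graph(6, 0.5, rng)
        assert hamming_distance(g, g) == 0

    def test_single_edge_difference_counts_twice_ordered(self, rng):
        g1 = random_graph(6, 0.5, rng)
        a = g1.adjacency.copy()
        i, j = 0, 1
        a[i, j] = a[j, i] = 1 - a[i, j]
        g2 = Graph(a)
        assert hamming_distance(g1, g2, "ordered") == 2
        assert hamming_distance(g1, g2, "unordered") == 1

    def test_empty_vs_complete(self):
        empty = Graph(np.zeros((4, 4), dtype=np.int8))
        assert hamming_distance(empty, complete_graph(4)) == 12

    def test_size_mismatch_errors(self, rng):
        with pytest.raises(ValueError, match="match in size"):
            hamming_distance(random_graph(4, 0.5, rng), random_graph(5, 0.5, rng))

    @settings(derandomize=True, max_examples=40, deadline=None)
    @given(st.integers(0, 100_000))
    def test_metric_axioms(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(3, 8))
        g1, g2, g3 = (random_graph(n, rng.uniform(0.2, 0.8), rng) for _ in range(3))
        d12 = hamming_distance(g1, g2)
        d21 = hamming_distance(g2, g1)
        d13 = hamming_distance(g1, g3)
        d23 = hamming_distance(g2, g3)
        assert d12 == d21
        assert hamming_distance(g1, g1) == 0
        assert (d12 == 0) == np.array_equal(g1.adjacency, g2.adjacency)
        assert d13 <= d12 + d23


class TestStructuralDistance:
    def test_relabeled_copy_has_distance_zero(self, rng):
        g = random_graph(6, 0.4, rng)
        perm = rng.permutation(6)
        g2 = Graph(g.adjacency[np.ix_(perm, perm)])
        d, flag = structural_distance(g, g2, "exact")
        assert d == 0 and flag == "exact"

    def test_path_vs_star_matches_oracle(self):
        d, _ = structural_distance(path4(), star4(), "exact")
        assert d == brute_force_structural(path4(), star4())

    def test_exact_matches_oracle_on_random_pairs(self, rng):
        for _ in range(15):
            g1 = random_graph(6, rng.uniform(0.3, 0.7), rng)
            g2 = random_graph(6, rng.uniform(0.3, 0.7), rng)
            d, _ = structural_distance(g1, g2, "exact")
            assert d == brute_force_structural(g1, g2)

    def test_invariant_under_relabeling(self, rng):
        g1 = random_graph(6, 0.5, rng)
        g2 = random_graph(6, 0.5, rng)
        perm = rng.permutation(6)
        g2p = Graph(g2.adjacency[np.ix_(perm, perm)])
        assert structural_distance(g1, g2, "exact")[0] == structural_distance(g1, g2p, "exact")[0]

    def test_anneal_bounded_by_exact_and_hamming(self, rng):
        for t in range(20):
            g1 = random_graph(7, 0.5, rng)
            g2 = random_graph(7, 0.5, rng)
            exact, _ = structural_distance(g1, g2, "exact")
            anneal, flag = structural_distance(g1, g2, "anneal", seed=t, n_proposals=2000)
            assert flag == "anneal"
            assert exact <= anneal <= hamming_distance(g1, g2)

    def test_exact_refuses_large_n(self, rng):
        g1 = random_graph(9, 0.5, rng)
        g2 = random_graph(9, 0.5, rng)
        with pytest.raises(ValueError, match="anneal"):
            structural_distance(g1, g2, "exact")


class TestGraphCorrelation:
    def test_identical_graphs_correlate_one(self, rng):
        g = random_graph(8, 0.4, rng)
        assert graph_correlation(g, g).correlation == pytest.approx(1.0)

    def test_complement_correlates_minus_one(self, rng):
        g = random_graph(8, 0.4, rng)
        res = graph_correlation(g, complement(g))
        assert res.correlation == pytest.approx(-1.0)

    def test_means_are_densities(self, rng):
        g1, g2 = random_graph(10, 0.3, rng), random_graph(10, 0.6, rng)
        res = graph_correlation(g1, g2)
        assert res.graph_means[0] == pytest.approx(g1.density)
        assert res.graph_means[1] == pytest.approx(g2.density)

    def test_max_bound_matches_exhaustive_overlap_check(self):
        # E1=3, E2=5 on N=6: enumerate every feasible overlap count
        N, M = 6, 30
        e1, e2 = 6, 10  # ordered-entry counts for 3 and 5 undirected edges

        def corr(o):
            return (o * M - e1 * e2) / np.sqrt(e1 * (M - e1) * e2 * (M - e2))

        feasible = [corr(o) for o in range(max(0, e1 + e2 - M), min(e1, e2) + 1, 2)]
        rng = np.random.default_rng(5)
        while True:
            g1 = random_graph(6, 0.4, rng)
            g2 = random_graph(6, 0.6, rng)
            if g1.n_edges == 3 and g2.n_edges == 5:
                break
        res = graph_correlation(g1, g2)
        assert res.correlation_bounds[1] == pytest.approx(max(feasible))
        assert res.correlation_bounds[1] < 1.0

    def test_correlation_within_bounds_on_random_pairs(self, rng):
        for _ in range(500):
            n = int(rng.integers(5, 12))
            g1 = random_graph(n, rng.uniform(0.2, 0.8), rng)
            g2 = random_graph(n, rng.uniform(0.2, 0.8), rng)
            try:
                res = graph_correlation(g1, g2)
            except ValueError:
                continue  # empty or complete draw
            lo, hi = res.correlation_bounds
            assert lo - 1e-12 <= res.correlation <= hi + 1e-12

    def test_zero_variance_names_graph(self, rng):
        g = random_graph(5, 0.5, rng)
        with pytest.raises(ValueError, match="second graph"):
            graph_correlation(g, complete_graph(5))


class TestCostaSimilarity:
    def test_identical_graphs(self, rng):
        g = random_graph(7, 0.5, rng)
        assert costa_similarity(g, g) == 1.0

    def test_complement_pair(self, rng):
        g = random_graph(7, 0.5, rng)
        assert costa_similarity(g, complement(g)) == 0.0

    def test_worked_four_node_pair(self):
        g1 = path4()
        g2 = star4()
        # hand enumeration (ordered entries): ones of path = {01,10,12,21,23,32};
        # star ones = {01,10,02,20,03,30}; matched ones = {01,10} -> 2/6;
        # zeros of path = {02,20,03,30,13,31}; star zeros = {12,21,13,31,23,32};
        # matched zeros = {13,31} -> 2/6
        assert costa_similarity(g1, g2) == pytest.approx(np.sqrt((2 / 6) * (2 / 6)))

    def test_similarity_one_iff_identical(self, rng):
        g1 = random_graph(6, 0.5, rng)
        a = g1.adjacency.copy()
        a[0, 1] = a[1, 0] = 1 - a[0, 1]
        assert costa_similarity(g1, Graph(a)) < 1.0

    def test_empty_first_graph_rejected(self):
        empty = Graph(np.zeros((4, 4), dtype=np.int8))
        with pytest.raises(ValueError, match="empty or complete"):
            costa_similarity(empty, star4())


def test_compare_all_collects_consistent_fields(rng):
    g1 = random_graph(6, 0.5, rng)
    g2 = random_graph(6, 0.5, rng)
    res = compare_all(g1, g2, seed=1)
    assert res.hamming >= res.structural >= 0
    assert res.structural_method == "exact"
    lo, hi = res.correlation_bounds
    assert lo <= res.correlation <= hi
    assert 0.0 <= res.costa_similarity <= 1.0
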