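import numpy as np
import pytest

import cloudcircuit as cc
from cloudcircuit import topology as tp

from conftest import random_digraph
from oracles import (brute_maximal_simplices, brute_simplex_counts,
                     brute_triad_census)


def cycle3():
    A = np.zeros((3, 3), dtype=bool)
    A[0, 1] = A[1, 2] = A[2, 0] = True
    return A


def clique3():
    A = np.ones((3, 3), dtype=bool)
    np.fill_diagonal(A, False)
    return A


def transitive_triangle():
    A = np.zeros((3, 3), dtype=bool)
    A[0, 1] = A[0, 2] = A[1, 2] = True
    return A


class TestSimplexCounts:
    def test_transitive_triangle_is_a_2_simplex(self):
        assert cc.count_simplices(transitive_triangle()) == [3, 3, 1]

    def test_3_cycle_has_no_2_simplex(self):
        assert cc.count_simplices(cycle3()) == [3, 3]

    def test_reciprocal_3_clique(self):
        # every ordered triple is a 2-simplex: 3! = 6
        assert cc.count_simplices(clique3()) == [3, 6, 6]

    def test_max_dim_caps_enumeration(self):
        A = clique3()
        assert cc.count_simplices(A, max_dim=1) == [3, 6]
        assert cc.count_simplices(A, max_dim=0) == [3]

    def test_matches_bruteforce_on_random_graphs(self):
        rng = np.random.default_rng(101)
        for _ in range(12):
            n = int(rng.integers(3, 11))
            A = random_digraph(rng, n, float(rng.choice([0.2, 0.4])))
            assert cc.count_simplices(A) == brute_simplex_counts(A)

    def test_python_scan_agrees_with_kernel(self):
        rng = np.random.default_rng(55)
        for _ in range(5):
            A = random_digraph(rng, 12, 0.4)
            assert tp._simplex_scan(A) == cc.count_simplices(A)


class TestMaximalSimplices:
    def test_transitive_triangle_single_maximal(self):
        counts, found = cc.count_maximal_simplices(transitive_triangle())
        assert counts == [0, 0, 1]
        assert found == [(0, 1, 2)]

    def test_3_cycle_edges_all_maximal(self):
        counts, found = cc.count_maximal_simplices(cycle3())
        assert counts == [0, 3]

    def test_isolated_vertex_is_maximal(self):
        A = np.zeros((3, 3), dtype=bool)
        A[0, 1] = True
        counts, found = cc.count_maximal_simplices(A)
        assert counts == [1, 1]
        assert (2,) in found and (0, 1) in found

    def test_maximality_against_insertion_not_just_append(self):
        # edge 0->2 extends to (0,1,2) by inserting 1 in the middle:
        # not maximal even though nothing can be appended after 2
        A = transitive_triangle()
        counts, found = cc.count_maximal_simplices(A, max_dim=1)
        assert (0, 2) not in found

    def test_matches_bruteforce_on_random_graphs(self):
        rng = np.random.default_rng(202)
        for _ in range(12):
            n = int(rng.integers(3, 11))
            A = random_digraph(rng, n, float(rng.choice([0.2, 0.4])))
            _, found = cc.count_maximal_simplices(A)
            assert sorted(found) == sorted(brute_maximal_simplices(A))


class TestNdInDegreeAndParticipation:
    def test_nd1_is_in_degree(self):
        rng = np.random.default_rng(3)
        A = random_digraph(rng, 20, 0.3)
        assert (cc.nd_in_degree(A, 1) == A.sum(axis=0)).all()

    def test_sink_counts_on_transitive_triangle(self):
        assert list(cc.nd_in_degree(transitive_triangle(), 2)) == [0, 0, 1]

    def test_sink_counts_match_bruteforce(self):
        rng = np.random.default_rng(4)
        A = random_digraph(rng, 10, 0.4)
        sims = [t for t in __import__("oracles").brute_simplex_list(A, 2)
                if len(t) == 3]
        expected = np.zeros(10, dtype=int)
        for t in sims:
            expected[t[-1]] += 1
        assert (cc.nd_in_degree(A, 2) == expected).all()

    def test_participation_totals_and_polarity(self):
        A = transitive_triangle()
        rec = cc.connection_participation(A, 2)
        # one 2-simplex (0,1,2): source edge 0->1, sink edge 1->2
        by_edge = {tuple(e): (s, k) for e, s, k in
                   zip(rec.edges, rec.n_source, rec.n_sink)}
        assert by_edge[(0, 1)] == (1, 0)
        assert by_edge[(1, 2)] == (0, 1)
        assert by_edge[(0, 2)] == (0, 0)
        pol = rec.polarity
        assert np.isnan(pol[[tuple(e) for e in rec.edges].index((0, 2))])
        assert rec.mean_abs_polarity == 1.0

    def test_invalid_N(self):
        with pytest.raises(ValueError):
            cc.nd_in_degree(np.zeros((2, 2), dtype=bool), 0)
        with pytest.raises(ValueError):
            cc.connection_participation(np.zeros((2, 2), dtype=bool), 1)


class TestEulerBetti:
    def test_3_cycle_betti(self):
        # one connected component, one directed cycle not filled in
        assert cc.betti_numbers(cycle3()) == [1, 1]

    def test_transitive_triangle_contractible(self):
        assert cc.betti_numbers(transitive_triangle()) == [1]

    def test_euler_characteristic_consistency(self):
        rng = np.random.default_rng(9)
        for _ in range(5):
            A = random_digraph(rng, 9, 0.35)
            counts = cc.count_simplices(A)
            chi = cc.euler_characteristic(counts)
            betti = cc.betti_numbers(A)
            assert chi == sum((-1) ** k * b for k, b in enumerate(betti))

    def test_guard(self):
        with pytest.raises(ValueError):
            cc.betti_numbers(np.zeros((65, 65), dtype=bool))


class TestTriadCensus:
    def test_matches_networkx_oracle(self):
        rng = np.random.default_rng(12)
        A = random_digraph(rng, 15, 0.3)
        assert cc.triad_census(A) == brute_triad_census(A)

    def test_known_graph(self):
        assert cc.triad_census(transitive_triangle())["030T"] == 1
        assert cc.triad_census(cycle3())["030C"] == 1


class TestPathLengthClustering:
    def test_3_cycle_closed_forms(self):
        A = cycle3()
        # ordered mutually reachable pairs: 6, distances 1,1,1,2,2,2
        res = cc.characteristic_path_length(A)
        assert res.exact and res.n_pairs == 6 and res.l == 1.5
        clus = cc.clustering_coefficients(A)
        assert np.allclose(clus.c_i, 0.5)

    def test_reciprocal_clique_clustering_is_1(self):
        clus = cc.clustering_coefficients(clique3())
        assert np.allclose(clus.c_i, 1.0)

    def test_sampled_estimator_close_to_exact(self):
        rng = np.random.default_rng(77)
        A = random_digraph(rng, 300, 0.05)
        exact = cc.characteristic_path_length(A, exact_limit=4000)
        approx = cc.characteristic_path_length(A, exact_limit=10,
                                               sample_size=150, seed=1)
        assert not approx.exact
        assert abs(approx.l - exact.l) < 5 * max(approx.stderr, 1e-3)

    def test_small_world_stats(self):
        rng = np.random.default_rng(31)
        A = random_digraph(rng, 120, 0.1)
        sw = cc.small_world_stats(A, seed=0)
        assert sw.ratio == pytest.approx(sw.c / sw.l)
        p = A.sum() / (120 * 119)
        assert sw.sigma_er == pytest.approx(np.sqrt(119 * p * (1 - p)))
        assert sw.l_er > 1 and 0 < sw.c_er < 1


class TestDegreesHubsER:
    def test_degree_summary_std(self):
        A = np.zeros((4, 4), dtype=bool)
        A[0, 1] = A[0, 2] = A[0, 3] = True
        s = cc.degree_summary(A)
        assert list(s.out_degree) == [3, 0, 0, 0]
        assert s.sigma_out == pytest.approx(np.std([3, 0, 0, 0]))

    def test_hub_set_ties_break_to_lower_id(self):
        A = np.zeros((4, 4), dtype=bool)
        A[1, 0] = A[2, 0] = A[1, 3] = A[2, 3] = True
        s = cc.degree_summary(A)
        hubs = cc.hub_set(s, fraction=0.25)  # k = 1
        assert list(hubs["in"]) == [0]
        assert list(hubs["out"]) == [1]

    def test_er_reference_counts_and_sigma(self):
        ref = tp.er_reference(50, 300, seed=3)
        assert ref.adjacency.sum() == 300
        assert not ref.adjacency.diagonal().any()
        p = 300 / (50 * 49)
        assert ref.sigma_closed_form == pytest.approx(np.sqrt(49 * p * (1 - p)))
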