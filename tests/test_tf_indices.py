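import math

import networkx as nx
import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from tfcoop.resources import BenchmarkPairSet, PairScoreTable, PCTFPSet, PPINetwork, TFPair
from tfcoop.tf_indices import (
    benchmark_overlap_score,
    evaluate_tf_indices,
    functional_similarity_score,
    hypergeom_overlap_pvalue,
    ppi_partner_overlap_score,
    shortest_path_score,
)

from .conftest import (
    brute_force_fisher_tail,
    brute_force_overlap_tail,
    brute_force_shortest_path,
    hub_pair_universe,
    hub_tf_universe,
)


class TestPartnerOverlapSignificance:
    @pytest.mark.parametrize(
        "n,n1,n2",
        [(n, n1, n2) for n in (5, 8, 12) for n1 in (0, 2, n // 2) for n2 in (1, n // 2, n - 1)],
    )
    def test_tail_matches_subset_enumeration(self, n, n1, n2):
        for c in range(0, min(n1, n2) + 1):
            expected = brute_force_overlap_tail(c, n, n1, n2)
            assert hypergeom_overlap_pvalue(c, n, n1, n2) == pytest.approx(
                expected, abs=1e-12
            )

    def test_known_small_case(self):
        # universe 10, partner counts 3 and 4, overlap 2: P = 70/210
        p = hypergeom_overlap_pvalue(2, 10, 3, 4)
        assert p == pytest.approx(1 / 3, abs=1e-12)
        net = PPINetwork(
            [("a", "p1"), ("a", "p2"), ("a", "p3"),
             ("b", "p1"), ("b", "p2"), ("b", "p4"), ("b", "p5")]
        )
        s = ppi_partner_overlap_score(net, TFPair("a", "b"), universe_size=10)
        assert s.detail["c"] == 2 and s.detail["N1"] == 3 and s.detail["N2"] == 4
        assert s.value == pytest.approx(-math.log10(1 / 3), abs=1e-12)

    def test_disjoint_partner_sets_score_zero(self):
        net = PPINetwork([("a", "p1"), ("b", "p2")])
        s = ppi_partner_overlap_score(net, TFPair("a", "b"), universe_size=100)
        assert s.detail["c"] == 0
        assert s.value == 0.0

    def test_absent_tf_scores_zero(self):
        net = PPINetwork([("a", "p1")])
        s = ppi_partner_overlap_score(net, TFPair("a", "zzz"), universe_size=100)
        assert s.value == 0.0

    def test_symmetric_in_pair_order(self):
        net = PPINetwork([("a", "p1"), ("a", "p2"), ("b", "p1"), ("b", "p3"), ("c", "p1")])
        sa = ppi_partner_overlap_score(net, TFPair("a", "b"), universe_size=50)
        sb = ppi_partner_overlap_score(net, TFPair("b", "a"), universe_size=50)
        assert sa.value == sb.value

    def test_universe_smaller_than_partner_count_is_error(self):
        net = PPINetwork([("a", f"p{i}") for i in range(5)] + [("b", "p0")])
        with pytest.raises(ValueError):
            ppi_partner_overlap_score(net, TFPair("a", "b"), universe_size=3)

    @settings(max_examples=150, derandomize=True)
    @given(
        n=st.integers(4, 40),
        data=st.data(),
    )
    def test_score_non_decreasing_in_overlap(self, n, data):
        n1 = data.draw(st.integers(1, n))
        n2 = data.draw(st.integers(1, n))
        tails = [
            hypergeom_overlap_pvalue(c, n, n1, n2) for c in range(0, min(n1, n2) + 1)
        ]
        assert all(a >= b - 1e-15 for a, b in zip(tails, tails[1:]))
        assert tails[0] == 1.0


class TestShortestPathScore:
    def test_direct_edge_scores_one(self):
        net = PPINetwork([("a", "b"), ("b", "c")])
        assert shortest_path_score(net, TFPair("a", "b")).value == 1.0

    def test_disconnected_and_absent_score_zero(self, path_network):
        assert shortest_path_score(path_network, TFPair("a", "u")).value == 0.0
        assert shortest_path_score(path_network, TFPair("a", "nope")).value == 0.0

    def test_three_edge_path(self, path_network):
        s = shortest_path_score(path_network, TFPair("a", "b"))
        assert s.value == pytest.approx(1 / 3)
        assert s.detail["path_length"] == 3

    @pytest.mark.parametrize("seed", range(8))
    def test_matches_exhaustive_path_enumeration(self, seed):
        g = nx.gnp_random_graph(10, 0.25, seed=seed)
        g = nx.relabel_nodes(g, {i: f"n{i}" for i in g.nodes})
        net = PPINetwork(list(g.edges) or [("n0", "n1")])
        for a, b in [("n0", "n9"), ("n2", "n7"), ("n4", "n5")]:
            expected = brute_force_shortest_path(net.graph, a, b)
            got = shortest_path_score(net, TFPair(a, b)).value
            assert got == (0.0 if expected is None else pytest.approx(1 / expected))

    @pytest.mark.parametrize("seed", range(5))
    def test_adding_an_edge_never_decreases_score(self, seed):
        rng = np.random.default_rng(seed)
        nodes = [f"n{i}" for i in range(8)]
        edges = [("n0", "n1"), ("n2", "n3"), ("n4", "n5")]
        net = PPINetwork(edges)
        pair = TFPair("n0", "n5")
        prev = shortest_path_score(net, pair).value
        for _ in range(12):
            a, b = rng.choice(nodes, size=2, replace=False)
            edges.append((a, b))
            net = PPINetwork(edges)
            cur = shortest_path_score(net, pair).value
            assert cur >= prev - 1e-15
            prev = cur


class TestFunctionalSimilarity:
    def test_lookup_and_symmetry(self):
        t = PairScoreTable({("a", "b"): 0.8})
        assert functional_similarity_score(t, TFPair("a", "b")).value == 0.8
        assert functional_similarity_score(t, TFPair("b", "a")).value == 0.8

    def test_absent_pair_is_undefined(self):
        s = functional_similarity_score(PairScoreTable(), TFPair("a", "b"))
        assert s.value is None and s.reason == "missing"


class TestBenchmarkOverlap:
    def test_known_small_case(self):
        # 10-pair universe, 3 benchmark, 4 predicted, 2 shared: P = 70/210
        pool = hub_pair_universe(10)
        bench = BenchmarkPairSet(pairs=frozenset(pool[:3]), tf_universe=hub_tf_universe(pool))
        predicted = PCTFPSet(name="x", pairs=pool[1:5])  # overlap = 2
        s = benchmark_overlap_score(predicted, bench, universe_pair_count=10)
        assert 10 ** (-s) == pytest.approx(1 / 3, rel=1e-9)

    @pytest.mark.parametrize("n_universe,n_bench,n_pred", [
        (6, 2, 3), (8, 3, 4), (10, 4, 5), (12, 5, 4),
    ])
    def test_matches_placement_enumeration(self, n_universe, n_bench, n_pred):
        pool = hub_pair_universe(n_universe)
        bench_idx = set(range(n_bench))
        bench = BenchmarkPairSet(pairs=frozenset(pool[i] for i in bench_idx),
                                 tf_universe=hub_tf_universe(pool))
        for shift in range(n_universe - n_pred + 1):
            chosen = list(range(shift, shift + n_pred))
            predicted = PCTFPSet(name="x", pairs=[pool[i] for i in chosen])
            k = len(bench_idx & set(chosen))
            expected = brute_force_fisher_tail(n_universe, bench_idx, n_pred, k)
            got = benchmark_overlap_score(predicted, bench, universe_pair_count=n_universe)
            assert 10 ** (-got) == pytest.approx(expected, abs=1e-12)

    def test_predicted_set_covering_universe_has_p_one(self):
        pool = hub_pair_universe(8)
        bench = BenchmarkPairSet(pairs=frozenset(pool[:3]), tf_universe=hub_tf_universe(pool))
        predicted = PCTFPSet(name="all", pairs=pool)
        assert benchmark_overlap_score(predicted, bench, universe_pair_count=8) == 0.0

    def test_adding_benchmark_pair_never_decreases_score(self):
        pool = hub_pair_universe(12)
        bench = BenchmarkPairSet(pairs=frozenset(pool[:5]), tf_universe=hub_tf_universe(pool))
        prev = None
        for k in range(1, 6):
            predicted = PCTFPSet(name="x", pairs=pool[:k] + pool[8:10])
            s = benchmark_overlap_score(predicted, bench, universe_pair_count=12)
            if prev is not None:
                assert s >= prev - 1e-12
            prev = s

    def test_universe_smaller_than_margins_is_error(self):
        pool = hub_pair_universe(6)
        bench = BenchmarkPairSet(pairs=frozenset(pool[:3]), tf_universe=hub_tf_universe(pool))
        predicted = PCTFPSet(name="x", pairs=pool)
        with pytest.raises(ValueError):
            benchmark_overlap_score(predicted, bench, universe_pair_count=4)

    def test_pairs_outside_tf_universe_are_dropped(self):
        pool = hub_pair_universe(6)
        bench = BenchmarkPairSet(pairs=frozenset(pool[:2]), tf_universe=hub_tf_universe(pool))
        outside = TFPair("ZZ1", "ZZ2")
        with_outside = PCTFPSet(name="x", pairs=pool[:3] + [outside])
        without = PCTFPSet(name="y", pairs=pool[:3])
        s1 = benchmark_overlap_score(with_outside, bench, universe_pair_count=6)
        s2 = benchmark_overlap_score(without, bench, universe_pair_count=6)
        assert s1 == s2


class TestSetLevelSummaries:
    def make_inputs(self):
        net = PPINetwork([("a", "x"), ("b", "x"), ("c", "y")])
        sim = PairScoreTable({("a", "b"): 1.0, ("a", "c"): 2.0})  # (b, c) missing
        bench = BenchmarkPairSet(pairs=frozenset({TFPair("a", "b")}),
                                 tf_universe=frozenset({"a", "b", "c", "d"}))
        pset = PCTFPSet(name="s", pairs=[TFPair("a", "b"), TFPair("a", "c"), TFPair("b", "c")])
        return pset, net, sim, bench

    def test_mean_excludes_undefined_pairs(self):
        pset, net, sim, bench = self.make_inputs()
        res = evaluate_tf_indices(pset, net, sim, bench, universe_size=50)
        fs = res["tf3_functional_similarity"]
        assert fs.n_undefined == 1
        assert fs.score == pytest.approx(1.5)  # mean of {1.0, 2.0}

    def test_median_summary(self):
        pset, net, sim, bench = self.make_inputs()
        sim = PairScoreTable({("a", "b"): 1.0, ("a", "c"): 2.0, ("b", "c"): 9.0})
        res = evaluate_tf_indices(pset, net, sim, bench, universe_size=50, stat="median")
        assert res["tf3_functional_similarity"].score == pytest.approx(2.0)

    def test_all_undefined_gives_undefined_index(self):
        pset, net, _, bench = self.make_inputs()
        res = evaluate_tf_indices(pset, net, PairScoreTable(), bench, universe_size=50)
        assert res["tf3_functional_similarity"].score is None
        assert res["tf3_functional_similarity"].n_undefined == 3

    def test_scores_invariant_to_pair_order_and_orientation(self):
        pset, net, sim, bench = self.make_inputs()
        flipped = PCTFPSet(
            name="s", pairs=[TFPair("c", "b"), TFPair("c", "a"), TFPair("b", "a")]
        )
        r1 = evaluate_tf_indices(pset, net, sim, bench, universe_size=50)
        r2 = evaluate_tf_indices(flipped, net, sim, bench, universe_size=50)
        for label in r1:
            assert r1[label].score == r2[label].score
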