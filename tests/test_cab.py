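import itertools
import math

import networkx as nx
import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from netmod import (
    CabParams,
    GeneSet,
    closeness_zscore,
    cohesion_zscore,
    edge_length,
    min_weighted_distance,
    score_candidates,
    set_distance,
)

from conftest import geneset, random_weighted_graph, wgraph

E = math.e


def brute_force_distance(G, source, target, p):
    """Minimum ln(p/w) path cost by exhaustive simple-path enumeration."""
    if source == target:
        return 0.0
    best = math.inf
    for path in nx.all_simple_paths(G, source, target):
        cost = sum(
            edge_length(G[u][v]["weight"], p) for u, v in zip(path, path[1:])
        )
        best = min(best, cost)
    return best


class TestEdgeLength:
    @pytest.mark.parametrize(
        "w,p,expected",
        [(1.0, 1.0, 0.0), (0.5, E, 1 + math.log(2)), (1.0, E**10, 10.0)],
    )
    def test_closed_forms(self, w, p, expected):
        assert edge_length(w, p) == pytest.approx(expected, abs=1e-12)

    def test_zero_confidence_rejected(self):
        with pytest.raises(ValueError):
            edge_length(0.0, E)

    def test_p_below_one_rejected(self):
        with pytest.raises(ValueError):
            edge_length(0.5, 0.9)

    @given(w=st.floats(1e-6, 1.0), p=st.floats(1.0, 1e6))
    @settings(derandomize=True, max_examples=200)
    def test_nonnegative_and_monotone(self, w, p):
        length = edge_length(w, p)
        assert length >= 0.0
        # costlier with larger p, cheaper with stronger confidence
        assert edge_length(w, p * 2) >= length
        assert edge_length(min(1.0, w * 2), p) <= length + 1e-12


class TestMinWeightedDistance:
    def test_confidence_dominates_at_p_one(self, triangle_weighted):
        res = min_weighted_distance(triangle_weighted, "A", "B", p=1.0)
        assert res.path == ["A", "C", "B"]
        assert res.length == pytest.approx(2 * math.log(1 / 0.9), abs=1e-9)

    def test_hops_dominate_at_large_p(self, triangle_weighted):
        res = min_weighted_distance(triangle_weighted, "A", "B", p=E**10)
        assert res.path == ["A", "B"]
        assert res.hops == 1
        assert res.length == pytest.approx(10 + math.log(10), abs=1e-9)

    def test_source_equals_target(self, triangle_weighted):
        res = min_weighted_distance(triangle_weighted, "A", "A", p=E)
        assert res.length == 0.0 and res.hops == 0

    def test_unreachable_is_infinite(self):
        G = wgraph([("A", "B", 1.0), ("X", "Y", 1.0)])
        res = min_weighted_distance(G, "A", "X", p=E)
        assert math.isinf(res.length)
        assert res.path == []

    def test_unknown_gene_errors(self, path_ab):
        with pytest.raises(ValueError, match="unknown"):
            min_weighted_distance(path_ab, "A", "Z", p=E)

    def test_matches_exhaustive_enumeration(self):
        rng = np.random.default_rng(20)
        for _ in range(20):
            n = int(rng.integers(4, 9))
            G = random_weighted_graph(rng, n, p_edge=0.5)
            nodes = sorted(G.nodes)
            for p in (1.0, E, E**2, E**10):
                for s, t in itertools.islice(itertools.combinations(nodes, 2), 6):
                    res = min_weighted_distance(G, s, t, p)
                    assert res.length == pytest.approx(
                        brute_force_distance(G, s, t, p), abs=1e-9
                    )

    def test_path_cost_consistency(self):
        rng = np.random.default_rng(21)
        G = random_weighted_graph(rng, 10, p_edge=0.3)
        res = min_weighted_distance(G, "N0", "N9", p=E)
        recomputed = sum(
            edge_length(G[u][v]["weight"], E) for u, v in zip(res.path, res.path[1:])
        )
        assert res.length == pytest.approx(recomputed, abs=1e-9)
        assert res.hops == len(res.path) - 1

    def test_monotonicity_under_edge_addition_and_strengthening(self):
        rng = np.random.default_rng(22)
        for rep in range(5):
            G = random_weighted_graph(rng, 8, p_edge=0.4)
            nodes = sorted(G.nodes)
            pairs = list(itertools.combinations(nodes, 2))
            before = {
                pair: min_weighted_distance(G, *pair, p=E).length for pair in pairs
            }
            # add a random absent edge
            absent = [pr for pr in pairs if not G.has_edge(*pr)]
            if absent:
                u, v = absent[int(rng.integers(len(absent)))]
                G.add_edge(u, v, weight=0.5)
            # strengthen one existing edge
            eu, ev = sorted(G.edges)[int(rng.integers(G.number_of_edges()))]
            G[eu][ev]["weight"] = min(1.0, G[eu][ev]["weight"] * 1.5)
            for pair in pairs:
                after = min_weighted_distance(G, *pair, p=E).length
                assert after <= before[pair] + 1e-12


class TestSetDistance:
    def test_star_center_symmetry(self, star5):
        module = geneset("L1", "L2", "L3")
        res = set_distance(star5, "H", module, p=E)
        assert res.mean_length == pytest.approx(1.0, abs=1e-12)

    def test_path_mean(self):
        G = wgraph([("A", "B", 1.0), ("B", "C", 1.0)])
        res = set_distance(G, "A", geneset("B", "C"), p=E)
        assert res.mean_length == pytest.approx(1.5, abs=1e-12)

    def test_source_in_target_set_excluded(self, path_ab):
        res = set_distance(path_ab, "A", geneset("A", "B"), p=E)
        assert res.mean_length == pytest.approx(1.0, abs=1e-12)
        assert res.n_reachable == 1

    def test_sum_mode(self):
        G = wgraph([("A", "B", 1.0), ("B", "C", 1.0)])
        res = set_distance(G, "A", geneset("B", "C"), p=E, reduce="sum")
        assert res.mean_length == pytest.approx(3.0, abs=1e-12)

    def test_unreachable_counted_and_all_unreachable_errors(self):
        G = wgraph([("A", "B", 1.0), ("X", "Y", 1.0)])
        res = set_distance(G, "A", geneset("B", "X"), p=E)
        assert res.n_unreachable == 1
        with pytest.raises(ValueError, match="reachable"):
            set_distance(G, "A", geneset("X", "Y"), p=E)


def planted_graph(seed=30, n=300, module_size=30):
    """Sparse random graph containing a clique module and one candidate
    adjacent to every module gene."""
    G = nx.gnp_random_graph(n, 0.02, seed=seed)
    G = nx.relabel_nodes(G, {i: f"G{i:03d}" for i in G.nodes})
    nx.set_edge_attributes(G, 0.5, "weight")
    module = [f"G{i:03d}" for i in range(module_size)]
    for i, a in enumerate(module):
        for b in module[i + 1 :]:
            G.add_edge(a, b, weight=1.0)
    cand = "CAND"
    for m in module:
        G.add_edge(cand, m, weight=1.0)
    return G, GeneSet.from_iterable("module", module), cand


class TestClosenessZscore:
    def test_planted_adjacent_candidate_significant(self):
        G, module, cand = planted_graph()
        params = CabParams(p_grid=(E,), reporting_p=E, n_rand=1000, rng_seed=1)
        (res,) = closeness_zscore(G, cand, module, params)
        assert res.z < -1.6
        assert res.significant
        assert res.empirical_p < 0.05

    def test_candidate_in_module_errors(self):
        G, module, _ = planted_graph()
        with pytest.raises(ValueError, match="inside the module"):
            closeness_zscore(G, "G000", module)

    def test_degenerate_null_errors(self):
        G = nx.complete_graph(5)
        G = nx.relabel_nodes(G, {i: f"K{i}" for i in G.nodes})
        nx.set_edge_attributes(G, 1.0, "weight")
        module = geneset("K0", "K1", "K2")
        with pytest.raises(ValueError, match="degenerate"):
            closeness_zscore(G, "K3", module, CabParams(p_grid=(E,), n_rand=100))

    def test_zscores_invariant_under_order_preserving_relabel(self):
        G, module, cand = planted_graph(seed=31, n=100, module_size=10)
        params = CabParams(p_grid=(E,), n_rand=200, rng_seed=5)
        (r1,) = closeness_zscore(G, cand, module, params)
        # prefix every label identically: sorted order, hence sampling, is preserved
        relabel = {g: f"X{g}" for g in G.nodes}
        G2 = nx.relabel_nodes(G, relabel)
        module2 = GeneSet.from_iterable("m", [f"X{g}" for g in module.members])
        (r2,) = closeness_zscore(G2, f"X{cand}", module2, params)
        assert r2.z == pytest.approx(r1.z, abs=1e-12)


class TestScoreCandidates:
    def test_empty_candidate_list(self):
        G, module, _ = planted_graph(seed=32, n=100, module_size=10)
        results, sig, unmapped = score_candidates(
            G, GeneSet.from_iterable("c", []), module, CabParams(p_grid=(E,), n_rand=100)
        )
        assert results == [] and sig.size == 0

    def test_absent_candidate_reported_unmapped(self):
        G, module, cand = planted_graph(seed=33, n=100, module_size=10)
        cands = GeneSet.from_iterable("c", [cand, "NOT_IN_GRAPH"])
        results, sig, unmapped = score_candidates(
            G, cands, module, CabParams(p_grid=(E,), n_rand=100, rng_seed=2)
        )
        assert "NOT_IN_GRAPH" in unmapped.members
        assert {r.candidate for r in results} == {cand}

    def test_results_sorted_by_z(self):
        G, module, cand = planted_graph(seed=34, n=150, module_size=12)
        cands = GeneSet.from_iterable("c", [cand, "G100", "G120", "G140"])
        results, _, _ = score_candidates(
            G, cands, module, CabParams(p_grid=(E,), n_rand=200, rng_seed=3)
        )
        zs = [r.z for r in results]
        assert zs == sorted(zs)
        assert results[0].candidate == cand  # planted candidate is closest


class TestCohesionZscore:
    def test_clique_is_cohesive(self):
        G = nx.gnp_random_graph(200, 0.03, seed=40)
        G = nx.relabel_nodes(G, {i: f"G{i:03d}" for i in G.nodes})
        nx.set_edge_attributes(G, 0.5, "weight")
        clique = [f"G{i:03d}" for i in range(5)]
        for i, a in enumerate(clique):
            for b in clique[i + 1 :]:
                G.add_edge(a, b, weight=1.0)
        res = cohesion_zscore(
            G, GeneSet.from_iterable("clique", clique), CabParams(n_rand=1000, rng_seed=4)
        )
        assert res.z < -2

    def test_single_adjacent_pair_observed_one(self):
        G = nx.gnp_random_graph(50, 0.1, seed=41)
        G = nx.relabel_nodes(G, {i: f"G{i:02d}" for i in G.nodes})
        nx.set_edge_attributes(G, 1.0, "weight")
        G.add_edge("G00", "G01", weight=1.0)
        res = cohesion_zscore(
            G, geneset("G00", "G01"), CabParams(n_rand=100, rng_seed=5), p=E
        )
        assert res.observed_mean_pairwise == pytest.approx(1.0, abs=1e-12)

    def test_fewer_than_two_mapped_errors(self, path_ab):
        with pytest.raises(ValueError, match=">= 2"):
            cohesion_zscore(path_ab, geneset("A"), CabParams(n_rand=100))
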