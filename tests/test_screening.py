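"""The two-stage median-threshold cascade and its recorded thresholds."""

import networkx as nx
import numpy as np
import pytest

import oracles
from conftest import random_graph
from netpharm.centrality import compute_all
from netpharm.network import SeedSet, build_seed_network
from netpharm.screening import (
    core_target_filter,
    hit_hub_filter,
    median,
    run_screening,
    top_k_by_degree,
)
from netpharm.simulate import SimulationConfig, sample_seed_sets, simulate_interactome


class TestMedian:
    @pytest.mark.parametrize(
        "values, expected", [([1, 2, 3], 2.0), ([1, 2, 3, 4], 2.5), ([5], 5.0)]
    )
    def test_definition(self, values, expected):
        assert median(values) == expected

    def test_empty_errors(self):
        with pytest.raises(ValueError):
            median([])


class TestHitHubFilter:
    def test_star_keeps_only_center(self, star9):
        hubs, threshold = hit_hub_filter(star9)
        assert threshold == 2.0  # degrees 8,1x8 -> median 1
        assert set(hubs.nodes) == {"C"}
        assert hubs.number_of_edges() == 0

    def test_regular_graph_empties(self):
        hubs, threshold = hit_hub_filter(nx.cycle_graph(6))
        assert threshold == 4.0
        assert hubs.number_of_nodes() == 0

    def test_single_node_empties(self):
        g = nx.Graph()
        g.add_node("A")
        hubs, threshold = hit_hub_filter(g)
        assert threshold == 0.0
        assert hubs.number_of_nodes() == 0

    def test_isolates_count_toward_median(self):
        g = nx.Graph([("A", "B"), ("A", "C"), ("A", "D")])
        g.add_nodes_from(["X", "Y", "Z"])  # degree 0, pull the median down
        hubs, threshold = hit_hub_filter(g)
        assert threshold == 2.0 * median([3, 1, 1, 1, 0, 0, 0])
        assert set(hubs.nodes) == {"A", "B", "C", "D"} - {
            v for v in "BCD" if g.degree(v) <= threshold
        }

    def test_rerun_on_own_output_is_not_idempotent(self, star9):
        hubs, _ = hit_hub_filter(star9)
        assert set(hubs.nodes) == {"C"}
        again, _ = hit_hub_filter(hubs)
        # the surviving hub is alone, cannot exceed twice its own median
        assert again.number_of_nodes() == 0

    def test_frozen_threshold_is_monotone_under_failing_node_edges(self):
        g = random_graph(3, n_max=12, p=0.4)
        hubs, threshold = hit_hub_filter(g)
        survivors = set(hubs.nodes)
        failing = sorted(set(g.nodes) - survivors)
        g2 = g.copy()
        for u in failing:
            for v in failing:
                if u < v:
                    g2.add_edge(u, v)
        still = {v for v in g2.nodes if g2.degree(v) > threshold}
        assert survivors <= still


class TestCoreTargetFilter:
    def test_vertex_transitive_graph_empties(self):
        core, cuts = core_target_filter(nx.cycle_graph(8))
        assert core.number_of_nodes() == 0
        assert cuts.rule == "median"

    def test_k5_with_pendants_keeps_only_clique_nodes(self):
        g = nx.complete_graph(5)
        g = nx.relabel_nodes(g, {i: f"K{i}" for i in range(5)})
        for i in range(5):
            g.add_edge(f"K{i}", f"L{i}")
        g.add_edge("K0", "L5")
        g.add_edge("K1", "L6")
        core, cuts = core_target_filter(g)
        assert set(core.nodes) <= {f"K{i}" for i in range(5)}
        # oracle: recompute the five metrics and medians from first principles
        metrics = {
            "degree": oracles.brute_degree(g),
            "betweenness": oracles.brute_betweenness(g),
            "closeness": oracles.brute_closeness(g),
            "neighborhood_connectivity": oracles.brute_neighborhood_connectivity(g),
            "lac": oracles.brute_lac(g),
        }
        expected = set(g.nodes)
        for vals in metrics.values():
            med = float(np.median(list(vals.values())))
            expected &= {v for v in g.nodes if vals[v] > med}
        assert set(core.nodes) == expected

    @pytest.mark.parametrize("seed", range(12))
    def test_matches_first_principles_evaluation(self, seed):
        g = random_graph(seed, n_max=12, p=0.45)
        core, cuts = core_target_filter(g)
        metrics = {
            "degree": oracles.brute_degree(g),
            "betweenness": oracles.brute_betweenness(g),
            "closeness": oracles.brute_closeness(g),
            "neighborhood_connectivity": oracles.brute_neighborhood_connectivity(g),
            "lac": oracles.brute_lac(g),
        }
        expected = set(g.nodes)
        for vals in metrics.values():
            med = float(np.median(list(vals.values())))
            expected &= {v for v in g.nodes if vals[v] > med}
        assert set(core.nodes) == expected


class TestRunScreening:
    def test_star_cascade_hand_evaluation(self, star9):
        result = run_screening(star9, star9)
        assert set(result.intersection.nodes) == set(star9.nodes)
        assert set(result.hit_hubs.nodes) == {"C"}
        assert result.core.number_of_nodes() == 0

    def test_disjoint_networks_empty_everywhere(self, triangle):
        other = nx.Graph([("X", "Y"), ("Y", "Z")])
        result = run_screening(triangle, other)
        assert result.stage_counts() == {
            "intersection_nodes": 0, "intersection_edges": 0,
            "hit_hub_nodes": 0, "hit_hub_edges": 0,
            "core_nodes": 0, "core_edges": 0,
        }

    @pytest.mark.parametrize("median_scope", ["stage", "intersection"])
    @pytest.mark.parametrize("seed", range(5))
    def test_nesting_and_strict_threshold_exceedance(self, seed, median_scope):
        cfg = SimulationConfig(
            n_proteins=150, attachment_edges=3, core_size=15, core_density=0.8,
            n_drug_seeds=20, n_disease_seeds=20, seed_core_fraction=0.8,
            n_terms=10, term_size_range=(5, 10), n_enriched_terms=0, rng_seed=seed,
        )
        interactome, truth = simulate_interactome(cfg)
        drug, disease = sample_seed_sets(interactome, truth, cfg)
        result = run_screening(
            build_seed_network(interactome, drug),
            build_seed_network(interactome, disease),
            median_scope=median_scope,
        )
        assert set(result.core.nodes) <= set(result.hit_hubs.nodes)
        assert set(result.hit_hubs.nodes) <= set(result.intersection.nodes)
        # strictness, re-checked from the stored stage tables
        inter_table = result.tables["intersection"]
        for v in result.hit_hubs.nodes:
            assert inter_table.loc[v, "degree"] > result.hit_hub_threshold
        stage_table = result.tables["hit_hubs"]
        cuts = result.core_thresholds.column_cuts()
        for v in result.core.nodes:
            for col, cut in cuts.items():
                assert stage_table.loc[v, col] > cut

    def test_stage_scope_self_competition_on_core_dominated_hubs(self):
        """When the hit-hub network is mostly the planted core, stage-scope
        medians are medians of the core itself, so the strict five-way cut
        removes most of it; intersection scope does not self-compete."""
        cfg = SimulationConfig(rng_seed=0)
        interactome, truth = simulate_interactome(cfg)
        drug, disease = sample_seed_sets(interactome, truth, cfg)
        dn = build_seed_network(interactome, drug)
        zn = build_seed_network(interactome, disease)
        stage = run_screening(dn, zn, median_scope="stage")
        inter = run_screening(dn, zn, median_scope="intersection")
        hub_nodes = set(stage.hit_hubs.nodes)
        assert len(hub_nodes & truth.core_nodes) / len(hub_nodes) > 0.5
        recall_stage = len(set(stage.core.nodes) & truth.core_nodes) / len(truth.core_nodes)
        recall_inter = len(set(inter.core.nodes) & truth.core_nodes) / len(truth.core_nodes)
        assert recall_stage <= 0.5 < recall_inter

    def test_invalid_scope_rejected(self, triangle):
        with pytest.raises(ValueError, match="median_scope"):
            run_screening(triangle, triangle, median_scope="both")


class TestTopK:
    def test_tie_break_lexicographic(self):
        table = compute_all(nx.Graph([("A", "B"), ("A", "C"), ("B", "C"), ("B", "D"), ("C", "D")]))
        # degrees: A 2, B 3, C 3, D 2
        assert top_k_by_degree(table, 2) == [("B", 3), ("C", 3)]
        assert top_k_by_degree(table, 3) == [("B", 3), ("C", 3), ("A", 2)]

    def test_k_larger_than_table_clamps(self, triangle):
        table = compute_all(triangle)
        assert len(top_k_by_degree(table, 15)) == 3

    def test_k_must_be_positive(self, triangle):
        with pytest.raises(ValueError):
            top_k_by_degree(compute_all(triangle), 0)
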