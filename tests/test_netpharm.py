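"""Set filtering, network degree and over-representation contracts."""

import itertools
import math

import networkx as nx
import numpy as np
import pandas as pd
import pytest

from pvsignal.netpharm import (build_network, degree_stats, filter_targets,
                               intersect_sets, load_edge_list,
                               ora_hypergeometric, read_gmt, select_core)
from pvsignal.simulate import write_gmt


def _table(rows):
    return pd.DataFrame(rows, columns=["gene", "source", "score"])


class TestFilterTargets:
    def test_threshold_keeps_passing_genes(self):
        t = _table([("A", "s", 12.0), ("B", "s", 9.0)])
        assert filter_targets(t, 10.0, ">=") == {"A"}

    def test_duplicate_symbol_max_score_wins(self):
        t = _table([("A", "s1", 5.0), ("a ", "s2", 15.0), ("B", "s1", 8.0)])
        # oracle: exhaustive scan keeping any symbol with some passing score
        oracle = {g.strip().upper() for g, _, s in t.itertuples(index=False) if s >= 10}
        assert filter_targets(t, 10.0, ">=") == oracle == {"A"}

    def test_cutoff_above_max_empties_the_set(self):
        t = _table([("A", "s", 1.0)])
        assert filter_targets(t, 2.0, ">=") == set()

    def test_empty_table(self):
        assert filter_targets(_table([]), 0.0, ">") == set()

    def test_unknown_comparator_rejected(self):
        with pytest.raises(ValueError):
            filter_targets(_table([("A", "s", 1.0)]), 0.0, "~")


class TestIntersect:
    def test_plain_intersection(self):
        assert intersect_sets({"A", "B", "C"}, {"B", "C", "D"}) == {"B", "C"}

    def test_disjoint_sets(self):
        assert intersect_sets({"A"}, {"B"}) == set()

    def test_symbol_case_normalised(self):
        assert intersect_sets({"tp53"}, {"TP53 "}) == {"TP53"}


class TestNetwork:
    def test_triangle_degrees(self):
        g = build_network(pd.DataFrame({"gene_a": ["A", "B", "C"],
                                        "gene_b": ["B", "C", "A"]}))
        deg, avg = degree_stats(g)
        assert deg.tolist() == [2, 2, 2]
        assert avg == 2.0

    def test_degree_sum_is_twice_edges(self):
        g = nx.gnm_random_graph(30, 60, seed=2)
        g = nx.relabel_nodes(g, {i: f"G{i}" for i in g.nodes})
        deg, avg = degree_stats(g)
        assert deg.sum() == 2 * g.number_of_edges()
        assert avg == pytest.approx(2 * 60 / 30)

    def test_isolated_node_lowers_average(self):
        g = build_network(pd.DataFrame({"gene_a": ["A"], "gene_b": ["B"]}),
                          nodes=["A", "B", "C"])
        deg, avg = degree_stats(g)
        assert deg["C"] == 0
        assert avg == pytest.approx(2 / 3)

    def test_self_loops_and_duplicate_edges_dropped(self):
        g = build_network(pd.DataFrame({"gene_a": ["A", "A", "a"],
                                        "gene_b": ["A", "B", "B"]}))
        assert g.number_of_edges() == 1

    def test_worked_average_degree(self, gene_fixtures):
        edges = gene_fixtures.edges
        g = build_network(edges[edges["combined_score"] >= 0.7])
        deg, avg = degree_stats(g)
        assert g.number_of_nodes() == 76
        assert g.number_of_edges() == 198
        assert round(avg, 2) == 5.21

    def test_confidence_filter_on_load(self, tmp_path, gene_fixtures):
        path = tmp_path / "edges.tsv"
        gene_fixtures.edges.to_csv(path, sep="\t", index=False)
        strong = load_edge_list(path, min_score=0.7)
        assert len(strong) == 198
        assert len(load_edge_list(path)) > 198


class TestSelectCore:
    def test_strictly_greater_cutoff(self):
        g = nx.Graph()
        for node, degree in (("A", 11), ("B", 10), ("C", 12)):
            for i in range(degree):
                g.add_edge(node, f"{node}_{i}")
        assert select_core(g, cutoff=10)[:2] == ["C", "A"]
        assert "B" not in select_core(g, cutoff=10)

    def test_empty_network(self):
        assert select_core(nx.Graph(), cutoff=10) == []

    def test_fixture_has_exactly_eleven_hubs(self, gene_fixtures):
        edges = gene_fixtures.edges
        g = build_network(edges[edges["combined_score"] >= 0.7])
        core = select_core(g, cutoff=10)
        assert len(core) == 11
        deg, _ = degree_stats(g)
        assert all(deg[c] > 10 for c in core)
        assert sorted(deg[core], reverse=True) == list(deg[core])


def _enumeration_p(universe, annotation, study_size, k_obs):
    """Oracle: exhaustive enumeration of all study sets of the given size."""
    hits = total = 0
    for combo in itertools.combinations(sorted(universe), study_size):
        total += 1
        if len(set(combo) & annotation) >= k_obs:
            hits += 1
    return hits / total


class TestOra:
    def _run(self, study, universe, sets, **kw):
        return ora_hypergeometric(study, universe, sets, **kw).set_index("set")

    def test_worked_tail_probability(self):
        universe = [f"G{i}" for i in range(20)]
        annot = {"S": set(universe[:4])}
        study = set(universe[:3]) | {universe[10], universe[11]}  # k=3, n=5
        out = self._run(study, universe, annot)
        assert out.loc["S", "overlap"] == 3
        assert out.loc["S", "p"] == pytest.approx(0.0320, abs=2e-4)

    def test_zero_overlap_p_is_one(self):
        universe = [f"G{i}" for i in range(10)]
        out = self._run(set(universe[:3]), universe, {"S": set(universe[5:])})
        assert out.loc["S", "p"] <= 1.0
        out0 = self._run(set(universe[:2]), universe, {"S": set(universe[8:])})
        assert out0.loc["S", "p"] == pytest.approx(
            _enumeration_p(universe, set(universe[8:]), 2, int(out0.loc["S", "overlap"])))

    def test_annotation_equal_to_universe_forces_full_overlap(self):
        universe = [f"G{i}" for i in range(12)]
        out = self._run(set(universe[:5]), universe, {"ALL": set(universe)})
        assert out.loc["ALL", "overlap"] == 5
        assert out.loc["ALL", "p"] == pytest.approx(1.0)

    def test_empty_study_set_gives_p_one(self):
        universe = [f"G{i}" for i in range(8)]
        out = self._run(set(), universe, {"S": set(universe[:4])})
        assert (out["p"] == 1.0).all()

    @pytest.mark.parametrize("m,k_set,n_study,seed", [
        (20, 4, 5, 0), (25, 7, 6, 1), (15, 5, 5, 2)])
    def test_matches_exhaustive_enumeration(self, m, k_set, n_study, seed):
        rng = np.random.default_rng(seed)
        universe = [f"G{i}" for i in range(m)]
        annot = set(rng.choice(universe, size=k_set, replace=False))
        study = set(rng.choice(universe, size=n_study, replace=False))
        out = self._run(study, universe, {"S": annot})
        k_obs = int(out.loc["S", "overlap"])
        assert out.loc["S", "p"] == pytest.approx(
            _enumeration_p(universe, annot, n_study, k_obs), rel=1e-9)

    def test_bh_is_monotone_and_not_below_raw(self):
        rng = np.random.default_rng(3)
        universe = [f"G{i}" for i in range(60)]
        sets = {f"S{i}": set(rng.choice(universe, size=rng.integers(5, 25),
                                        replace=False)) for i in range(12)}
        study = set(rng.choice(universe, size=15, replace=False))
        out = ora_hypergeometric(study, universe, sets)
        assert (out["p_adj"] >= out["p"] - 1e-12).all()
        by_raw = out.sort_values(["p", "set"])["p_adj"].to_numpy()
        assert (np.diff(by_raw) >= -1e-12).all()

    def test_per_namespace_adjustment(self, gene_fixtures):
        fx = gene_fixtures
        from pvsignal.netpharm import filter_targets, intersect_sets
        study = intersect_sets(filter_targets(fx.drug_table, 0.0, ">"),
                               filter_targets(fx.disease_table, 10.0, ">="))
        out = ora_hypergeometric(study, fx.universe, fx.annotations,
                                 namespaces=fx.namespaces)
        enriched = out[out["set"].str.startswith("ENRICHED")]
        assert enriched["significant"].all()

    def test_study_outside_universe_rejected(self):
        with pytest.raises(ValueError):
            ora_hypergeometric({"X"}, {"A", "B"}, {"S": {"A"}})


class TestGmtRoundTrip:
    def test_write_then_read(self, tmp_path):
        sets = {"S1": {"A", "B"}, "S2": {"C"}}
        path = tmp_path / "sets.gmt"
        write_gmt(sets, path, {"S1": "BP", "S2": "KEGG"})
        back, desc = read_gmt(path)
        assert back == sets
        assert desc == {"S1": "BP", "S2": "KEGG"}
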