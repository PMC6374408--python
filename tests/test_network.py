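"""Network parsing, guide scoring, hub enrichment and ranking mechanics."""

import itertools
import math

import networkx as nx
import numpy as np
import pytest

from coexcand import (
    connected_pathway_subset,
    guide_predict,
    hub_overlap_pvalue,
    hub_predict,
    read_network,
    top_n,
    write_network,
)
from coexcand.network import read_ranking, write_ranking


def graph_from_edges(edges):
    g = nx.Graph()
    g.add_weighted_edges_from(edges)
    return g


class TestReadNetwork:
    def test_parses_simple_edge_list(self, tmp_path):
        path = tmp_path / "net.tsv"
        path.write_text("# comment\nA\tB\t1.5\nB\tC\t2.0\nC\tD\t0.7\n")
        g = read_network(path)
        assert g.number_of_nodes() == 4
        assert g.number_of_edges() == 3
        assert g["A"]["B"]["weight"] == 1.5

    def test_duplicate_pair_keeps_max_weight_and_warns(self, tmp_path, caplog):
        path = tmp_path / "net.tsv"
        path.write_text("A\tB\t1.5\nB\tA\t2.0\n")
        with caplog.at_level("WARNING"):
            g = read_network(path)
        assert g.number_of_edges() == 1
        assert g["A"]["B"]["weight"] == 2.0
        assert any("duplicate" in rec.message for rec in caplog.records)

    def test_self_loop_rejected_with_line_number(self, tmp_path):
        path = tmp_path / "net.tsv"
        path.write_text("A\tB\t1.0\nA\tA\t1.0\n")
        with pytest.raises(ValueError, match="2: self-loop"):
            read_network(path)

    @pytest.mark.parametrize("bad", ["A\tB\t-1.0", "A\tB\t0", "A\tB\tx", "A\tB"])
    def test_malformed_lines_rejected(self, tmp_path, bad):
        path = tmp_path / "net.tsv"
        path.write_text(bad + "\n")
        with pytest.raises(ValueError):
            read_network(path)

    def test_round_trip_preserves_graph_exactly(self, tmp_path):
        rng = np.random.default_rng(5)
        g = nx.gnp_random_graph(30, 0.2, seed=4)
        g = nx.relabel_nodes(g, {i: f"G{i:03d}" for i in g})
        for _, _, d in g.edges(data=True):
            d["weight"] = float(rng.uniform(0.1, 5.0))
        path = tmp_path / "net.tsv"
        write_network(g, path)
        back = read_network(path)
        assert set(back.nodes) == {n for n in g if g.degree(n) > 0}
        assert set(map(frozenset, back.edges)) == set(map(frozenset, g.edges))
        for a, b, d in g.edges(data=True):
            assert back[a][b]["weight"] == d["weight"]


class TestConnectedPathwaySubset:
    def test_clique_fully_returned(self):
        g = graph_from_edges(
            (a, b, 1.0) for a, b in itertools.combinations("ABCD", 2)
        )
        assert connected_pathway_subset(g, set("ABCD")) == set("ABCD")

    def test_gene_with_only_outside_edges_excluded(self):
        g = graph_from_edges([("A", "B", 1.0), ("C", "X", 1.0)])
        assert connected_pathway_subset(g, {"A", "B", "C"}) == {"A", "B"}

    def test_absent_and_empty(self):
        g = graph_from_edges([("A", "B", 1.0)])
        assert connected_pathway_subset(g, {"Z"}) == set()
        assert connected_pathway_subset(g, set()) == set()


class TestGuidePredict:
    def test_summation_example(self):
        g = graph_from_edges(
            [("X", "G1", 1.5), ("X", "G2", 2.5), ("Y", "G1", 1.0)]
        )
        ranking = guide_predict(g, {"G1", "G2"})
        assert list(ranking.entries.itertuples(index=False, name=None)) == [
            (1, "X", 4.0),
            (2, "Y", 1.0),
        ]

    def test_gene_without_guide_edge_omitted(self):
        g = graph_from_edges([("X", "G1", 1.0), ("Y", "Z", 9.0)])
        assert set(guide_predict(g, {"G1"}).genes) == {"X"}

    def test_no_guides_in_network_rejected(self):
        g = graph_from_edges([("A", "B", 1.0)])
        with pytest.raises(ValueError):
            guide_predict(g, {"Z"})
        with pytest.raises(ValueError):
            guide_predict(g, set())

    def test_guides_included_when_not_excluded(self):
        g = graph_from_edges([("G1", "G2", 2.0), ("X", "G1", 1.0)])
        ranking = guide_predict(g, {"G1", "G2"}, exclude_guides=False)
        scores = dict(zip(ranking.entries["gene"], ranking.entries["statistic"]))
        assert scores["G1"] == 2.0 and scores["G2"] == 2.0 and scores["X"] == 1.0

    def test_edge_deletion_changes_only_that_score(self):
        rng = np.random.default_rng(17)
        g = nx.gnp_random_graph(25, 0.3, seed=2)
        g = nx.relabel_nodes(g, {i: f"N{i:02d}" for i in g})
        for _, _, d in g.edges(data=True):
            d["weight"] = float(rng.integers(1, 17)) / 4.0
        guides = {"N00", "N01", "N02", "N03"}
        before = dict(
            zip(*(guide_predict(g, guides).entries[c] for c in ("gene", "statistic")))
        )
        target = next(
            (u, v) for u, v in g.edges if (u in guides) != (v in guides)
        )
        gene = target[0] if target[0] not in guides else target[1]
        w = g.edges[target]["weight"]
        g2 = g.copy()
        g2.remove_edge(*target)
        after = dict(
            zip(*(guide_predict(g2, guides).entries[c] for c in ("gene", "statistic")))
        )
        for other in before:
            if other == gene:
                assert after.get(other, 0.0) == before[other] - w
            else:
                assert after[other] == before[other]


def brute_force_guide_scores(graph, guides):
    """Independent double loop over all (gene, guide) pairs."""
    scores = {}
    for gene in graph.nodes:
        if gene in guides:
            continue
        total = 0.0
        for guide in guides:
            if graph.has_edge(gene, guide):
                total += graph[gene][guide]["weight"]
        if total != 0.0:
            scores[gene] = total
    return scores


def test_guide_scores_match_brute_force_on_random_graphs():
    """Summed-LLS scores agree exactly with a brute-force double loop.

    Weights are quarter-integers so float summation order cannot perturb
    the sums, making exact equality meaningful.
    """
    rng = np.random.default_rng(123)
    for trial in range(100):
        n = int(rng.integers(5, 51))
        g = nx.gnp_random_graph(n, float(rng.uniform(0.05, 0.5)), seed=int(rng.integers(1 << 30)))
        g = nx.relabel_nodes(g, {i: f"N{i:02d}" for i in g})
        for _, _, d in g.edges(data=True):
            d["weight"] = float(rng.integers(1, 33)) / 4.0
        guides = set(rng.choice(sorted(g.nodes), size=int(rng.integers(1, max(2, n // 3))), replace=False))
        expected = brute_force_guide_scores(g, guides)
        ranking = guide_predict(g, guides)
        got = dict(zip(ranking.entries["gene"], ranking.entries["statistic"]))
        assert got == expected
        # descending score with lexicographic tie-break
        stats = ranking.entries["statistic"].to_numpy()
        assert (stats[:-1] >= stats[1:]).all()


def enumerate_tail_probability(k, universe, n_deg, degree):
    """P(overlap >= k) by exhaustive enumeration of all DEG-set placements."""
    neighbors = set(range(degree))
    hits = 0
    total = 0
    for deg_set in itertools.combinations(range(universe), n_deg):
        total += 1
        if len(neighbors & set(deg_set)) >= k:
            hits += 1
    return hits / total


class TestHubEnrichment:
    def test_textbook_example(self):
        # C(4,3)*C(6,0)/C(10,3) = 4/120
        assert hub_overlap_pvalue(3, 10, 4, 3) == pytest.approx(4 / 120, abs=1e-12)

    def test_zero_overlap_is_certain(self):
        assert hub_overlap_pvalue(0, 50, 10, 5) == 1.0

    def test_tail_monotone_in_overlap(self):
        ps = [hub_overlap_pvalue(k, 30, 8, 6) for k in range(0, 7)]
        assert all(a > b for a, b in zip(ps, ps[1:]))

    def test_matches_exhaustive_enumeration(self):
        """Hypergeometric tails agree with subset enumeration for N <= 12."""
        for universe in range(2, 13):
            for n_deg in range(1, universe + 1):
                for degree in range(1, universe + 1):
                    for k in range(0, min(n_deg, degree) + 1):
                        expected = enumerate_tail_probability(
                            k, universe, n_deg, degree
                        )
                        got = hub_overlap_pvalue(k, universe, n_deg, degree)
                        assert got == pytest.approx(expected, abs=1e-12)

    def test_hub_ranking_wiring(self):
        # star hub H with 5 neighbors, 3 of them differential
        g = graph_from_edges([("H", f"N{i}", 1.0) for i in range(5)])
        ranking = hub_predict(g, {"N0", "N1", "N2"}, min_degree=5)
        assert ranking.genes == ["H"]
        row = ranking.entries.iloc[0]
        assert row["overlap_k"] == 3 and row["neighborhood_n"] == 5
        assert row["statistic"] == pytest.approx(
            hub_overlap_pvalue(3, g.number_of_nodes(), 3, 5), abs=1e-15
        )

    def test_small_universe_rejected(self):
        g = graph_from_edges([("H", f"N{i}", 1.0) for i in range(5)])
        with pytest.raises(ValueError):
            hub_predict(g, {"N0"}, min_degree=1, universe=3)

    def test_no_degs_in_network_rejected(self):
        g = graph_from_edges([("A", "B", 1.0)])
        with pytest.raises(ValueError):
            hub_predict(g, {"Z"})


class TestTopN:
    def _ranking(self, pairs):
        g = graph_from_edges([(gene, "G1", w) for gene, w in pairs])
        return guide_predict(g, {"G1"})

    def test_short_ranking_returned_whole(self):
        r = self._ranking([(f"N{i}", float(i + 1)) for i in range(7)])
        assert len(top_n(r, 20)) == 7

    def test_prefix_and_renumbering(self):
        r = self._ranking([(f"N{i}", float(10 - i)) for i in range(10)])
        t = top_n(r, 3)
        assert t.genes == r.genes[:3]
        assert list(t.entries["rank"]) == [1, 2, 3]

    def test_tie_at_boundary_prefers_smaller_gene_id(self):
        r = self._ranking([("B", 1.0), ("A", 1.0), ("C", 2.0)])
        assert top_n(r, 2).genes == ["C", "A"]

    def test_n_must_be_positive(self):
        r = self._ranking([("A", 1.0)])
        with pytest.raises(ValueError):
            top_n(r, 0)


def test_ranking_round_trip(tmp_path):
    g = graph_from_edges([("X", "G1", 1.5), ("Y", "G1", 1.0)])
    ranking = guide_predict(g, {"G1"})
    path = tmp_path / "r.tsv"
    write_ranking(ranking, path)
    back = read_ranking(path)
    assert back.approach == "guide"
    assert back.genes == ranking.genes
    assert np.allclose(back.entries["statistic"], ranking.entries["statistic"])
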