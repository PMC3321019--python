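"""Network construction, filtering, summary tables, and export formats."""

import random

import networkx as nx
import pytest

from pinminer import examples
from pinminer.corpus import Sentence
from pinminer.network import (
    FilterSpec,
    InteractionNetwork,
    build_network,
    direction_degree_table,
    edge_strength_table,
    export_network,
    focus_subnetwork,
    highlight_sentence,
    neighbor_table,
)
from pinminer.normalization import NormalizedGene
from pinminer.relation import LR, NONE, RL, CandidateTriplet, ScoredInteraction
from pinminer.tagger import Mention


def _mention(text, start, end, kind="protein"):
    return Mention(kind=kind, surface=text[start:end], start=start, end=end,
                   matched_entry=text[start:end], sentence_ref=("1", 0))


def interaction(a, b, word="binds", prob=0.96, direction=NONE,
                pmid="1", index=0, resolved=True):
    text = f"{a} {word} {b}"
    ta = _mention(text, 0, len(a))
    tb = _mention(text, len(a) + len(word) + 2, len(text))
    tw = _mention(text, len(a) + 1, len(a) + 1 + len(word), "interaction")
    triplet = CandidateTriplet(protein_a=ta, protein_b=tb, interaction=tw,
                               sentence_ref=(pmid, index))
    norm = lambda sym: NormalizedGene(surface=sym, gene_ids=(sym + "_id",),
                                      official_symbol=sym, taxon_id="9606",
                                      resolution_stage="cs_exact") \
        if resolved else NormalizedGene(surface=sym)
    return ScoredInteraction(
        triplet=triplet, probability=prob, interaction_type=word,
        direction=direction,
        direction_probability=None if direction == NONE else 0.9,
        normalized_a=norm(a), normalized_b=norm(b))


def ctx(pmid, index=None):
    return Mention(kind="context", surface="asthma", start=0, end=6,
                   matched_entry="asthma", sentence_ref=(pmid, index))


class TestBuildNetwork:
    def test_parallel_edges_for_repeated_findings(self):
        net = build_network([interaction("A", "B", pmid="1", index=1),
                             interaction("A", "B", pmid="2", index=3)],
                            spec=FilterSpec(min_probability=0.9))
        assert net.n_edges() == 2
        assert edge_strength_table(net).iloc[0]["n_links"] == 2

    def test_probability_threshold_excludes(self):
        si = interaction("A", "B", prob=0.95)
        net = build_network([si], spec=FilterSpec(min_probability=0.99))
        assert net.n_edges() == 0

    def test_interaction_type_filter(self):
        sis = [interaction("A", "B", word="binds"),
               interaction("A", "C", word="phosphorylates", direction=LR)]
        net = build_network(sis, spec=FilterSpec(
            min_probability=0.5, interaction_types={"phosphorylates"}))
        assert [d["interaction_type"] for _, _, d in net.graph.edges(data=True)] \
            == ["phosphorylates"]

    def test_context_cooccurrence_document_vs_sentence(self):
        sis = [interaction("A", "B", pmid="1", index=2)]
        doc_ctx = [ctx("1", None)]  # abstract scope only
        doc_net = build_network(sis, doc_ctx,
                                FilterSpec(min_probability=0.5,
                                           context_granularity="document"))
        sent_net = build_network(sis, doc_ctx,
                                 FilterSpec(min_probability=0.5,
                                            context_granularity="sentence"))
        assert doc_net.n_edges() == 1
        assert sent_net.n_edges() == 0  # no sentence-scope co-occurrence

    def test_sentence_network_subset_of_document_network(self):
        sis = [interaction("A", "B", pmid="1", index=1),
               interaction("C", "D", pmid="1", index=5)]
        mentions = [ctx("1", None), ctx("1", 1)]
        doc = build_network(sis, mentions, FilterSpec(
            min_probability=0.5, context_granularity="document"))
        sent = build_network(sis, mentions, FilterSpec(
            min_probability=0.5, context_granularity="sentence"))
        doc_edges = {(u, v) for u, v in doc.graph.edges()}
        sent_edges = {(u, v) for u, v in sent.graph.edges()}
        assert sent_edges <= doc_edges

    def test_rl_edge_stored_target_to_source(self):
        net = build_network([interaction("A", "B", word="phosphorylates",
                                         direction=RL)],
                            spec=FilterSpec(min_probability=0.5))
        assert list(net.graph.edges()) == [("B", "A")]

    def test_unresolved_node_keeps_surface(self):
        net = build_network([interaction("A", "B", resolved=False)],
                            spec=FilterSpec(min_probability=0.5))
        assert set(net.graph.nodes) == {"A", "B"}
        assert net.graph.nodes["A"]["gene_ids"] == ""

    def test_raising_threshold_is_monotone(self):
        rng = random.Random(5)
        sis = [interaction(f"P{rng.randint(0, 5)}", f"Q{rng.randint(0, 5)}",
                           prob=rng.random()) for _ in range(30)]
        prev_nodes, prev_edges = None, None
        for threshold in (0.2, 0.5, 0.8, 0.95):
            net = build_network(sis, spec=FilterSpec(min_probability=threshold))
            if prev_edges is not None:
                assert net.n_edges() <= prev_edges
                assert net.graph.number_of_nodes() <= prev_nodes
            prev_nodes = net.graph.number_of_nodes()
            prev_edges = net.n_edges()


class TestFocusSubnetwork:
    def base(self):
        return build_network(
            [interaction("A", "B"), interaction("B", "C"),
             interaction("C", "D"), interaction("A", "C")],
            spec=FilterSpec(min_probability=0.5))

    def test_focus_keeps_neighbors_only(self):
        sub = focus_subnetwork(self.base(), "A")
        assert set(sub.graph.nodes) == {"A", "B", "C"}

    def test_edges_not_incident_removed(self):
        net = self.base()
        sub = focus_subnetwork(net, "A")
        expected = [(u, v) for u, v in net.graph.edges() if "A" in (u, v)]
        assert sorted(sub.graph.edges()) == sorted(expected)

    def test_unknown_focus_empty(self):
        sub = focus_subnetwork(self.base(), "ZZZ")
        assert sub.graph.number_of_nodes() == 0

    def test_focus_with_k_neighbors_has_k_plus_one_nodes(self):
        net = self.base()
        k = len(net.neighbors_of("C"))
        sub = focus_subnetwork(net, "C")
        assert sub.graph.number_of_nodes() == k + 1


class TestSummaryTables:
    def test_published_hub_neighbor_counts(self):
        """The asthma hub edge list reproduces its published hub degrees."""
        table = neighbor_table(examples.asthma_hub_network())
        rows = table.set_index("protein")
        assert rows.loc["IL4", "n_neighbors"] == 3     # MAPK21, STAT6, FLG
        assert rows.loc["GRP", "n_neighbors"] == 2     # AHR, GRPR
        assert rows.loc["STAT6", "n_neighbors"] == 2

    def test_top_pair_multiplicity(self):
        table = edge_strength_table(examples.asthma_hub_network())
        top = table.iloc[0]
        assert {top["protein_1"], top["protein_2"]} == {"IL17A", "IL13"}
        assert top["n_links"] == 2
        assert (table["n_links"].iloc[1:] == 1).all()

    def test_single_edge_coverage(self):
        net = build_network([interaction("A", "B")],
                            spec=FilterSpec(min_probability=0.5))
        table = neighbor_table(net)
        assert (table["n_neighbors"] == 1).all()
        assert (table["percent_coverage"] == 50.0).all()

    def test_neighbor_counts_ignore_parallel_edges(self):
        net = build_network([interaction("A", "B")] * 3,
                            spec=FilterSpec(min_probability=0.5))
        assert neighbor_table(net)["n_neighbors"].tolist() == [1, 1]

    def test_direction_degree_rows(self):
        sis = [interaction("A", "B", word="phosphorylates", direction=LR),
               interaction("A", "C", word="phosphorylates", direction=LR),
               interaction("D", "A", word="methylates", direction=LR),
               interaction("A", "E", word="binds", direction=NONE)]
        net = build_network(sis, spec=FilterSpec(min_probability=0.5))
        rows = direction_degree_table(net).set_index("protein")
        assert tuple(rows.loc["A"]) == (2, 1, 1)
        assert tuple(rows.loc["B"]) == (0, 1, 0)

    def test_degree_sum_conservation(self):
        net = examples.asthma_hub_network()
        rows = direction_degree_table(net)
        total = (rows.outward + rows.inward + rows.undirected).sum()
        assert total == 2 * net.n_edges()

    def test_reversing_directed_edges_swaps_columns(self):
        sis = [interaction("A", "B", word="phosphorylates", direction=LR),
               interaction("C", "A", word="methylates", direction=LR)]
        net = build_network(sis, spec=FilterSpec(min_probability=0.5))
        fwd = direction_degree_table(net).set_index("protein")
        reversed_net = InteractionNetwork(graph=net.graph.reverse(copy=True))
        rev = direction_degree_table(reversed_net).set_index("protein")
        assert (fwd["outward"] == rev["inward"]).all()
        assert (fwd["inward"] == rev["outward"]).all()

    def test_empty_network_tables(self):
        net = InteractionNetwork()
        assert neighbor_table(net).empty
        assert edge_strength_table(net).empty

    def test_hub_definition(self):
        net = examples.asthma_hub_network()
        assert net.hub_nodes() == ["GRP", "IL13", "IL4", "STAT6"]


class TestExport:
    def net(self):
        return build_network(
            [interaction("A", "B", word="binds"),
             interaction("A", "C", word="phosphorylates", direction=LR)],
            spec=FilterSpec(min_probability=0.5))

    def test_sif_one_line_per_edge(self, tmp_path):
        path = tmp_path / "net.sif"
        export_network(self.net(), path, "SIF")
        lines = path.read_text().splitlines()
        assert sorted(lines) == ["A\tbinds\tB", "A\tphosphorylates\tC"]

    def test_graphml_round_trip(self, tmp_path):
        path = tmp_path / "net.graphml"
        net = self.net()
        export_network(net, path, "GraphML")
        again = nx.read_graphml(path, force_multigraph=True)
        assert set(again.nodes) == set(net.graph.nodes)
        assert sorted((u, v, d["interaction_type"])
                      for u, v, d in again.edges(data=True)) == \
               sorted((u, v, d["interaction_type"])
                      for u, v, d in net.graph.edges(data=True))

    def test_tsv_report_highlights_triplet(self, tmp_path):
        sentence = Sentence.from_raw("1", 0, "A binds B")
        si = interaction("A", "B")
        si = ScoredInteraction(
            triplet=si.triplet, probability=si.probability,
            interaction_type=si.interaction_type, direction=si.direction,
            direction_probability=None, normalized_a=si.normalized_a,
            normalized_b=si.normalized_b,
            evidence=highlight_sentence(sentence.raw, [(0, 1), (2, 7), (8, 9)]))
        net = build_network([si], spec=FilterSpec(min_probability=0.5))
        path = tmp_path / "report.tsv"
        export_network(net, path, "TSV")
        text = path.read_text()
        assert "[[A]] [[binds]] [[B]]" in text

    def test_unknown_format_rejected(self, tmp_path):
        with pytest.raises(ValueError):
            export_network(self.net(), tmp_path / "x", "XGMML")


class TestRandomNetworkInvariants:
    def test_invariants_on_random_networks(self):
        """Degree conservation, filter monotonicity, granularity containment."""
        rng = random.Random(42)
        for trial in range(100):
            n_int = rng.randint(1, 15)
            sis = []
            for i in range(n_int):
                a, b = rng.sample("ABCDEFGH", 2)
                direction = rng.choice([LR, RL, NONE])
                word = "binds" if direction == NONE else "phosphorylates"
                sis.append(interaction(a, b, word=word, prob=rng.random(),
                                       direction=direction,
                                       pmid=str(rng.randint(1, 4)),
                                       index=rng.randint(0, 3)))
            mentions = [ctx(str(p), idx) for p in range(1, 5)
                        for idx in rng.sample([None, 0, 1, 2, 3], 2)]
            lo = build_network(sis, mentions, FilterSpec(
                min_probability=0.3, context_granularity="document"))
            hi = build_network(sis, mentions, FilterSpec(
                min_probability=0.7, context_granularity="document"))
            sent = build_network(sis, mentions, FilterSpec(
                min_probability=0.3, context_granularity="sentence"))

            rows = direction_degree_table(lo)
            assert (rows.outward + rows.inward + rows.undirected).sum() \
                == 2 * lo.n_edges()
            assert hi.n_edges() <= lo.n_edges()
            assert set(hi.graph.nodes) <= set(lo.graph.nodes)

            def edge_multiset(net):
                return sorted((u, v, d["pmid"], d["sentence_index"])
                              for u, v, d in net.graph.edges(data=True))
            assert set(edge_multiset(sent)) <= set(edge_multiset(lo))

            table = neighbor_table(lo)
            n_nodes = lo.graph.number_of_nodes()
            for row in table.itertuples():
                back = row.percent_coverage * n_nodes / 100.0
                assert abs(back - round(back)) < 0.01 * n_nodes
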