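"""Knowledge-graph construction, statistics, novelty comparison, export."""

import itertools
import random

import networkx as nx
import numpy as np
import pytest
from scipy import stats as scipy_stats

from cellkine.corpus import Document, segment_sentences
from cellkine.graph import (
    KGEdge,
    KnowledgeGraph,
    build_graph,
    compare_graphs,
    confidence_evidence_correlation,
    export_graph,
    graph_stats,
    load_graphml,
    reference_graph_from_pairs,
)
from cellkine.lexicon import Lexicon
from cellkine.ner import annotate, resolve_overlaps
from cellkine.pairs import build_bags, generate_instances


def _edge(cell, cytokine, conf=0.9, freq=0.1, n_ev=1):
    return KGEdge(cell, cytokine, conf, freq, tuple((f"p{i}", "S.") for i in range(n_ev)))


def _scored_bags(texts, pairs_conf):
    cells = Lexicon("cell", {"t cell": "T cell", "b cell": "B cell", "monocyte": "monocyte"})
    cyts = Lexicon("cytokine", {"il6": "IL6", "tnf": "TNF", "ifng": "IFNG"})
    docs = [segment_sentences(Document(f"p{i}", "", t)) for i, t in enumerate(texts)]
    instances = []
    for d in docs:
        mentions = resolve_overlaps(annotate(d, cells) + annotate(d, cyts))
        instances.extend(generate_instances(d, mentions))
    bags = build_bags(instances)
    scored = [(b, pairs_conf.get(b.pair_key, 0.5), 0.1) for b in bags]
    return scored, {d.pmid: d for d in docs}


class TestBuildGraph:
    def test_threshold_above_one_gives_empty_graph(self):
        scored, corpus = _scored_bags(["T cell secretes IL6."], {})
        g = build_graph(scored, 1.01, corpus)
        assert len(g) == 0

    def test_star_shape(self):
        scored, corpus = _scored_bags(
            ["T cell secretes IL6.", "B cell secretes IL6.", "Monocyte secretes IL6."],
            {},
        )
        g = build_graph(scored, 0.0, corpus)
        assert len(g.nodes) == 4 and len(g) == 3
        assert g.cytokines == {"IL6"}

    def test_edges_match_score_table_filter(self):
        conf = {("T cell", "IL6"): 0.9, ("T cell", "TNF"): 0.3}
        scored, corpus = _scored_bags(["T cell secretes IL6 and TNF."], conf)
        g = build_graph(scored, 0.5, corpus)
        assert g.pair_set == {("T cell", "IL6")}

    def test_evidence_sentences_recovered_from_corpus(self):
        scored, corpus = _scored_bags(["T cell secretes IL6 constantly."], {})
        g = build_graph(scored, 0.0, corpus)
        assert g.edges[0].evidence == (("p0", "T cell secretes IL6 constantly."),)

    def test_raising_threshold_shrinks_edge_set(self):
        conf = {("T cell", "IL6"): 0.9, ("T cell", "TNF"): 0.6, ("B cell", "IL6"): 0.2}
        scored, corpus = _scored_bags(
            ["T cell secretes IL6 and TNF.", "B cell secretes IL6."], conf
        )
        prev = None
        for t in (0.0, 0.3, 0.7, 1.0):
            edges = build_graph(scored, t, corpus).pair_set
            if prev is not None:
                assert edges <= prev
            prev = edges

    def test_bipartite_and_simple(self):
        scored, corpus = _scored_bags(
            ["T cell secretes IL6.", "T cell secretes IL6 again here."], {}
        )
        g = build_graph(scored, 0.0, corpus)
        assert len(g) == 1  # one edge per pair even with two documents
        nxg = g.to_networkx()
        assert nx.is_bipartite(nxg)


class TestStats:
    def test_path_graph(self):
        edges = [
            _edge("c1", "k1"),
            _edge("c2", "k1"),
            _edge("c2", "k2"),
        ]  # path: k2 - c2 - k1 - c1
        stats = graph_stats(KnowledgeGraph(edges))
        assert stats["diameter"] == 3
        assert stats["center_nodes"] == ["c2", "k1"]

    def test_star_graph(self):
        edges = [_edge(f"c{i}", "hub") for i in range(4)]
        stats = graph_stats(KnowledgeGraph(edges))
        assert stats["diameter"] == 2
        assert stats["center_nodes"] == ["hub"]

    def test_mean_sentences_per_edge(self):
        g = KnowledgeGraph([_edge("c1", "k1", n_ev=3), _edge("c2", "k2", n_ev=1)])
        assert graph_stats(g)["mean_sentences_per_edge"] == pytest.approx(2.0)

    def test_counts(self):
        g = KnowledgeGraph([_edge("c1", "k1"), _edge("c1", "k2"), _edge("c2", "k1")])
        stats = graph_stats(g)
        assert stats["n_nodes"] == 4
        assert stats["n_cells"] == 2 and stats["n_cytokines"] == 2
        assert stats["n_edges"] == 3

    def test_diameter_and_center_match_floyd_warshall_oracle(self):
        rng = random.Random(4)
        for _ in range(10):
            cells = [f"c{i}" for i in range(rng.randint(3, 12))]
            cyts = [f"k{i}" for i in range(rng.randint(3, 12))]
            pairs = rng.sample(
                list(itertools.product(cells, cyts)),
                k=rng.randint(len(cells), min(len(cells) * len(cyts), 30)),
            )
            g = KnowledgeGraph([_edge(c, k) for c, k in pairs])
            stats = graph_stats(g)
            nxg = g.to_networkx()
            comp = max(nx.connected_components(nxg), key=lambda c: (len(c), sorted(c)))
            sub = nxg.subgraph(comp)
            dist = dict(nx.floyd_warshall(sub))
            ecc = {u: max(dist[u].values()) for u in sub}
            assert stats["diameter"] == max(ecc.values())
            radius = min(ecc.values())
            assert stats["center_nodes"] == sorted(u for u, e in ecc.items() if e == radius)

    def test_empty_graph_rejected(self):
        with pytest.raises(ValueError):
            graph_stats(KnowledgeGraph([]))


class TestCorrelation:
    def test_perfectly_linear_gives_one(self):
        edges = [_edge(f"c{i}", "k", conf=i / 10, n_ev=i) for i in range(1, 6)]
        assert confidence_evidence_correlation(KnowledgeGraph(edges)) == pytest.approx(1.0)

    def test_anti_ordered_linear_gives_minus_one(self):
        edges = [_edge(f"c{i}", "k", conf=1 - i / 10, n_ev=i) for i in range(1, 6)]
        assert confidence_evidence_correlation(KnowledgeGraph(edges)) == pytest.approx(-1.0)

    def test_matches_textbook_formula(self):
        rng = random.Random(8)
        edges = [
            _edge(f"c{i}", "k", conf=rng.random(), n_ev=rng.randint(1, 9)) for i in range(10)
        ]
        g = KnowledgeGraph(edges)
        x = np.array([e.confidence for e in edges])
        y = np.array([len(e.evidence) for e in edges], dtype=float)
        hand = float(
            np.sum((x - x.mean()) * (y - y.mean()))
            / np.sqrt(np.sum((x - x.mean()) ** 2) * np.sum((y - y.mean()) ** 2))
        )
        assert confidence_evidence_correlation(g) == pytest.approx(hand, abs=1e-12)
        assert confidence_evidence_correlation(g) == pytest.approx(
            scipy_stats.pearsonr(x, y).statistic
        )

    def test_constant_input_reported_undefined(self):
        g = KnowledgeGraph([_edge("c1", "k1", conf=0.5), _edge("c2", "k2", conf=0.5)])
        with pytest.raises(ValueError):
            confidence_evidence_correlation(g)


class TestCompareGraphs:
    def test_identical_graphs_all_shared(self):
        g = KnowledgeGraph([_edge("c1", "k1"), _edge("c2", "k2")])
        counts = compare_graphs(g, g)
        assert counts == {
            "shared": 2,
            "new_edge_known_nodes": 0,
            "one_new_node": 0,
            "both_new_nodes": 0,
        }

    def test_empty_reference_all_novel(self):
        g = KnowledgeGraph([_edge("c1", "k1")])
        counts = compare_graphs(g, KnowledgeGraph([]))
        assert counts["both_new_nodes"] == 1

    def test_two_edges_per_category_by_construction(self):
        ref = reference_graph_from_pairs(
            [("c1", "k1"), ("c2", "k2"), ("c1", "k2"), ("c3", "k3")]
        )
        g = KnowledgeGraph(
            [
                _edge("c1", "k1"),  # shared
                _edge("c2", "k2"),  # shared
                _edge("c2", "k1"),  # known nodes, new edge
                _edge("c3", "k2"),  # known nodes, new edge
                _edge("c1", "kX"),  # one new node
                _edge("cX", "k1"),  # one new node
                _edge("cY", "kY"),  # both new
                _edge("cZ", "kZ"),  # both new
            ]
        )
        counts = compare_graphs(g, ref)
        assert counts == {
            "shared": 2,
            "new_edge_known_nodes": 2,
            "one_new_node": 2,
            "both_new_nodes": 2,
        }

    def test_categories_partition_edges(self):
        rng = random.Random(1)
        g = KnowledgeGraph([_edge(f"c{i}", f"k{rng.randint(0, 5)}") for i in range(12)])
        ref = reference_graph_from_pairs([("c0", "k0"), ("c1", "k1"), ("c5", "k2")])
        counts = compare_graphs(g, ref)
        assert sum(counts.values()) == len(g)


class TestExport:
    def test_graphml_round_trip_preserves_structure(self, tmp_path):
        g = KnowledgeGraph([_edge("c1", "k1", conf=0.8, n_ev=2), _edge("c2", "k1", conf=0.6)])
        export_graph(g, tmp_path, formats=("graphml",))
        again = load_graphml(tmp_path / "graph.graphml")
        assert again.pair_set == g.pair_set
        by_pair = {(e.cell, e.cytokine): e for e in again.edges}
        assert by_pair[("c1", "k1")].confidence == pytest.approx(0.8)
        assert len(by_pair[("c1", "k1")].evidence) == 2

    def test_empty_graph_writes_header_only_files(self, tmp_path):
        export_graph(KnowledgeGraph([]), tmp_path, formats=("edge-tsv", "evidence-tsv"))
        assert (tmp_path / "edges.tsv").read_text().count("\n") == 1
        assert (tmp_path / "evidence.tsv").read_text().count("\n") == 1

    def test_evidence_rows_one_per_supporting_sentence(self, tmp_path):
        g = KnowledgeGraph(
            [_edge("c1", "k1", n_ev=2), _edge("c2", "k1"), _edge("c3", "k2")]
        )
        export_graph(g, tmp_path, formats=("evidence-tsv",))
        lines = (tmp_path / "evidence.tsv").read_text().strip().splitlines()
        assert len(lines) == 1 + 4  # header + 2 + 1 + 1

    def test_edge_tsv_columns(self, tmp_path):
        g = KnowledgeGraph([_edge("c1", "k1", conf=0.8, freq=0.2, n_ev=2)])
        export_graph(g, tmp_path, formats=("edge-tsv",))
        header, row = (tmp_path / "edges.tsv").read_text().strip().splitlines()
        assert header.split("\t") == ["cell", "cytokine", "confidence", "frequency", "pmids"]
        cells = row.split("\t")
        assert cells[:2] == ["c1", "k1"]
        assert cells[4] == "p0;p1"
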