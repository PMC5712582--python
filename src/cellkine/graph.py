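"""Evidence-backed bipartite cell–cytokine knowledge graph.

Edges connect a cell node to a cytokine node; each edge carries a
confidence score, a pair-frequency score, and the list of (pmid, sentence)
pairs that support it. Structural statistics (diameter, center) follow the
usual convention of being computed on the largest connected component,
since literature-derived graphs are rarely connected.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import networkx as nx
from scipy import stats as _scipy_stats

from .corpus import Document
from .pairs import Bag

logger = logging.getLogger(__name__)

__all__ = [
    "KGEdge",
    "KnowledgeGraph",
    "build_graph",
    "graph_stats",
    "confidence_evidence_correlation",
    "compare_graphs",
    "export_graph",
    "load_graphml",
    "reference_graph_from_pairs",
]

NOVELTY_CATEGORIES = (
    "shared",  # edge present in the reference graph
    "new_edge_known_nodes",  # both endpoints known, not connected there
    "one_new_node",  # exactly one endpoint absent from the reference
    "both_new_nodes",  # both endpoints absent
)


@dataclass(frozen=True)
class KGEdge:
    cell: str
    cytokine: str
    confidence: float
    frequency: float
    evidence: tuple[tuple[str, str], ...]  # (pmid, sentence text)

    def __post_init__(self) -> None:
        if not self.evidence:
            raise ValueError("an edge needs at least one evidence sentence")


@dataclass
class KnowledgeGraph:
    """Simple undirected bipartite graph over typed nodes."""

    edges: list[KGEdge] = field(default_factory=list)

    def __post_init__(self) -> None:
        seen: set[tuple[str, str]] = set()
        for e in self.edges:
            key = (e.cell, e.cytokine)
            if key in seen:
                raise ValueError(f"duplicate edge {key}")
            seen.add(key)
        cells = {e.cell for e in self.edges}
        cytokines = {e.cytokine for e in self.edges}
        clash = cells & cytokines
        if clash:
            raise ValueError(f"nodes typed both cell and cytokine: {sorted(clash)[:5]}")

    @property
    def cells(self) -> set[str]:
        return {e.cell for e in self.edges}

    @property
    def cytokines(self) -> set[str]:
        return {e.cytokine for e in self.edges}

    @property
    def nodes(self) -> set[str]:
        return self.cells | self.cytokines

    @property
    def pair_set(self) -> set[tuple[str, str]]:
        return {(e.cell, e.cytokine) for e in self.edges}

    def __len__(self) -> int:
        return len(self.edges)

    def to_networkx(self) -> nx.Graph:
        g = nx.Graph()
        for c in self.cells:
            g.add_node(c, type="cell")
        for k in self.cytokines:
            g.add_node(k, type="cytokine")
        for e in self.edges:
            g.add_edge(
                e.cell,
                e.cytokine,
                confidence=e.confidence,
                frequency=e.frequency,
                n_evidence=len(e.evidence),
            )
        return g


def build_graph(
    scored_bags: Sequence[tuple[Bag, float, float]],
    threshold: float,
    corpus: Mapping[str, Document] | Sequence[Document],
) -> KnowledgeGraph:
    """Keep one edge per bag with confidence >= threshold.

    ``scored_bags`` holds (bag, confidence, frequency) triples; evidence
    sentences are recovered from the corpus, one per distinct
    (pmid, sentence) location among the bag's instances.
    """
    doc_by_pmid = (
        dict(corpus) if isinstance(corpus, Mapping) else {d.pmid: d for d in corpus}
    )
    edges = []
    for bag, conf, freq in scored_bags:
        if conf < threshold:
            continue
        locations = sorted({(i.doc, i.sentence_index) for i in bag.instances})
        evidence = tuple(
            (pmid, doc_by_pmid[pmid].sentences[si].text) for pmid, si in locations
        )
        edges.append(
            KGEdge(
                cell=bag.pair_key[0],
                cytokine=bag.pair_key[1],
                confidence=conf,
                frequency=freq,
                evidence=evidence,
            )
        )
    return KnowledgeGraph(edges=edges)


def graph_stats(g: KnowledgeGraph) -> dict:
    """Node/edge counts, diameter and center (largest component), and mean
    evidence sentences per edge."""
    if not g.edges:
        raise ValueError("empty graph has no statistics")
    nxg = g.to_networkx()
    largest = max(nx.connected_components(nxg), key=lambda c: (len(c), sorted(c)))
    sub = nxg.subgraph(largest)
    return {
        "n_nodes": nxg.number_of_nodes(),
        "n_cells": len(g.cells),
        "n_cytokines": len(g.cytokines),
        "n_edges": nxg.number_of_edges(),
        "diameter": nx.diameter(sub),
        "center_nodes": sorted(nx.center(sub)),
        "mean_sentences_per_edge": sum(len(e.evidence) for e in g.edges) / len(g.edges),
    }


def confidence_evidence_correlation(g: KnowledgeGraph) -> float:
    """Pearson correlation between edge confidence and evidence count.

    Undefined (ValueError) when either variable is constant.
    """
    if len(g.edges) < 2:
        raise ValueError("need at least two edges")
    conf = [e.confidence for e in g.edges]
    counts = [float(len(e.evidence)) for e in g.edges]
    if len(set(conf)) < 2 or len(set(counts)) < 2:
        raise ValueError("correlation undefined for constant input")
    r, _p = _scipy_stats.pearsonr(conf, counts)
    return float(r)


def compare_graphs(g: KnowledgeGraph, ref: KnowledgeGraph) -> dict[str, int]:
    """Assign every edge of ``g`` to one of four novelty categories.

    (i) shared with the reference; (ii) both endpoints known but not
    connected there; (iii) exactly one endpoint unknown; (iv) both
    endpoints unknown. Counts always sum to ``len(g)``. Node matching is
    exact on canonical strings; near-miss synonyms are logged, not merged.
    """
    ref_pairs = ref.pair_set
    ref_nodes = ref.nodes
    counts = dict.fromkeys(NOVELTY_CATEGORIES, 0)
    for e in g.edges:
        known = (e.cell in ref_nodes) + (e.cytokine in ref_nodes)
        if (e.cell, e.cytokine) in ref_pairs:
            counts["shared"] += 1
        elif known == 2:
            counts["new_edge_known_nodes"] += 1
        elif known == 1:
            counts["one_new_node"] += 1
        else:
            counts["both_new_nodes"] += 1
    return counts


# --------------------------------------------------------------------------
# export / import
# --------------------------------------------------------------------------


def export_graph(
    g: KnowledgeGraph,
    out_dir: str | Path,
    formats: Iterable[str] = ("graphml", "edge-tsv", "evidence-tsv"),
) -> dict[str, Path]:
    """Write the graph in the requested formats under ``out_dir``.

    ``edge-tsv``: one row per edge with semicolon-joined supporting pmids;
    ``evidence-tsv``: one row per (edge, pmid, sentence); ``graphml``:
    loadable by standard graph tools, nodes carry a ``type`` attribute.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written: dict[str, Path] = {}
    for fmt in formats:
        if fmt == "graphml":
            path = out_dir / "graph.graphml"
            nx.write_graphml(g.to_networkx(), path)
        elif fmt == "edge-tsv":
            path = out_dir / "edges.tsv"
            with open(path, "w", encoding="utf-8", newline="") as fh:
                writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
                writer.writerow(["cell", "cytokine", "confidence", "frequency", "pmids"])
                for e in sorted(g.edges, key=lambda e: (e.cell, e.cytokine)):
                    pmids = sorted({pmid for pmid, _ in e.evidence})
                    writer.writerow(
                        [e.cell, e.cytokine, f"{e.confidence:.6f}", f"{e.frequency:.6f}",
                         ";".join(pmids)]
                    )
        elif fmt == "evidence-tsv":
            path = out_dir / "evidence.tsv"
            with open(path, "w", encoding="utf-8", newline="") as fh:
                writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
                writer.writerow(["cell", "cytokine", "pmid", "sentence"])
                for e in sorted(g.edges, key=lambda e: (e.cell, e.cytokine)):
                    for pmid, sentence in e.evidence:
                        writer.writerow([e.cell, e.cytokine, pmid, sentence])
        else:
            raise ValueError(f"unknown export format: {fmt!r}")
        written[fmt] = path
    return written


def load_graphml(path: str | Path) -> KnowledgeGraph:
    """Load a graph written by :func:`export_graph` (evidence counts only;
    sentences live in the evidence TSV)."""
    nxg = nx.read_graphml(str(path))
    edges = []
    for u, v, data in nxg.edges(data=True):
        if nxg.nodes[u].get("type") == "cell":
            cell, cytokine = u, v
        else:
            cell, cytokine = v, u
        n_ev = max(1, int(data.get("n_evidence", 1)))
        edges.append(
            KGEdge(
                cell=cell,
                cytokine=cytokine,
                confidence=float(data.get("confidence", 0.0)),
                frequency=float(data.get("frequency", 0.0)),
                evidence=tuple(("?", "?") for _ in range(n_ev)),
            )
        )
    return KnowledgeGraph(edges=edges)


def reference_graph_from_pairs(pairs: Iterable[tuple[str, str]]) -> KnowledgeGraph:
    """Build a reference graph (unit confidence/frequency, placeholder
    evidence) from bare (cell, cytokine) pairs, e.g. a relation database."""
    edges = [
        KGEdge(cell=c, cytokine=k, confidence=1.0, frequency=1.0, evidence=(("ref", ""),))
        for c, k in sorted(set(pairs))
    ]
    return KnowledgeGraph(edges=edges)
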