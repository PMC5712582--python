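"""Manual-validation tooling: edge sampling, Fleiss' kappa, accuracy.

A curation round samples edges from the knowledge graph, assigns a shared
subset to every curator (for interannotator agreement) and splits the rest
evenly. Agreement is the standard Fleiss' kappa for a fixed number of
raters; graph accuracy is the accepted fraction of distinct edges, with the
shared edges decided by majority verdict.
"""

from __future__ import annotations

import csv
import random
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .graph import KnowledgeGraph

__all__ = [
    "CurationAssignment",
    "sample_edges",
    "fleiss_kappa",
    "accuracy",
    "write_assignment",
]

EdgeKey = tuple[str, str]


@dataclass(frozen=True)
class CurationAssignment:
    sampled_edges: tuple[EdgeKey, ...]
    per_curator: tuple[tuple[EdgeKey, ...], ...]
    shared: tuple[EdgeKey, ...]
    seed: int


def sample_edges(
    g: KnowledgeGraph,
    n_total: int = 60,
    n_curators: int = 3,
    n_shared: int = 15,
    seed: int = 0,
) -> CurationAssignment:
    """Sample ``n_total`` edges uniformly without replacement and assign them.

    The first ``n_shared`` sampled edges go to every curator; the remaining
    ``n_total - n_shared`` are split as evenly as possible. With the
    default 60/3/15 design each curator rates 30 edges: 15 shared + 15 own.
    """
    edges = sorted(g.pair_set)
    if len(edges) < n_total:
        raise ValueError(f"graph has {len(edges)} edges, cannot sample {n_total}")
    if not 0 <= n_shared <= n_total:
        raise ValueError("need 0 <= n_shared <= n_total")
    if n_curators < 1:
        raise ValueError("need at least one curator")
    rng = random.Random(seed)
    sampled = rng.sample(edges, n_total)
    shared = tuple(sampled[:n_shared])
    rest = sampled[n_shared:]
    per_curator = []
    for c in range(n_curators):
        own = tuple(rest[c::n_curators])
        per_curator.append(shared + own)
    return CurationAssignment(
        sampled_edges=tuple(sampled),
        per_curator=tuple(per_curator),
        shared=shared,
        seed=seed,
    )


def fleiss_kappa(matrix: Sequence[Sequence[int]]) -> float:
    """Fleiss' kappa for a ratings matrix (items x categories of counts).

    Every item must have the same total number of raters ``n >= 2``. With
    per-item agreement ``P_i = (sum_j n_ij^2 - n) / (n (n-1))`` and chance
    agreement ``Pe = sum_j p_j^2`` over the pooled category proportions,
    kappa is ``(mean(P_i) - Pe) / (1 - Pe)``. Raises when all ratings fall
    in one category (chance agreement 1, kappa undefined).
    """
    m = np.asarray(matrix, dtype=float)
    if m.ndim != 2 or m.shape[0] < 2:
        raise ValueError("need a 2-D matrix with at least two items")
    if (m < 0).any() or not np.allclose(m, np.round(m)):
        raise ValueError("ratings must be non-negative integer counts")
    n_raters = m.sum(axis=1)
    if not np.all(n_raters == n_raters[0]):
        raise ValueError("every item must have the same number of raters")
    n = float(n_raters[0])
    if n < 2:
        raise ValueError("need at least two raters per item")
    p_i = ((m**2).sum(axis=1) - n) / (n * (n - 1))
    p_bar = float(p_i.mean())
    p_j = m.sum(axis=0) / m.sum()
    p_e = float((p_j**2).sum())
    if p_e >= 1.0:
        raise ValueError("all ratings in one category: kappa undefined")
    return (p_bar - p_e) / (1.0 - p_e)


def accuracy(verdicts: Mapping[EdgeKey, Sequence[str]]) -> float:
    """Fraction of distinct edges accepted.

    ``verdicts`` maps an edge to the verdicts it received ("accept" /
    "reject"); multi-rated (shared) edges count once with the majority
    verdict, ties resolved toward reject (an edge is kept only on positive
    majority evidence).
    """
    if not verdicts:
        raise ValueError("no verdicts")
    accepted = 0
    for votes in verdicts.values():
        n_acc = sum(1 for v in votes if v == "accept")
        if n_acc * 2 > len(votes):
            accepted += 1
    return accepted / len(verdicts)


def write_assignment(assignment: CurationAssignment, path: str | Path) -> None:
    """TSV: edge_key, curator_id, shared flag; verdict columns left blank
    for the curators to fill."""
    with open(path, "w", encoding="utf-8", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(["cell", "cytokine", "curator_id", "shared", "verdict", "cause"])
        shared = set(assignment.shared)
        for cid, edges in enumerate(assignment.per_curator):
            for cell, cytokine in edges:
                writer.writerow(
                    [cell, cytokine, cid, int((cell, cytokine) in shared), "", ""]
                )
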