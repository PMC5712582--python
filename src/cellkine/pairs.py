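"""Sentence-level co-occurrence instances, bags, and distant supervision.

An instance is one co-occurrence of a (cell, cytokine) pair inside a single
sentence; a bag collects every instance of one pair across the whole corpus.
Distant supervision labels a bag positive exactly when its pair exists in a
reference relation database — no sentence-level annotation is ever needed.
The pair-frequency score of a bag is the number of distinct abstracts
supporting the pair divided by the corpus size.
"""

from __future__ import annotations

import csv
import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

from .corpus import Document
from .ner import EntityMention

logger = logging.getLogger(__name__)

__all__ = [
    "Instance",
    "Bag",
    "ReferenceDB",
    "generate_instances",
    "build_bags",
    "label_bags",
    "pair_frequency",
    "load_reference_db",
    "save_reference_db",
    "write_bags",
]

PairKey = tuple[str, str]  # (cell canonical, cytokine canonical)


@dataclass(frozen=True)
class Instance:
    pair_key: PairKey
    doc: str
    sentence_index: int
    cell_mention: EntityMention
    cytokine_mention: EntityMention

    def __post_init__(self) -> None:
        cm, km = self.cell_mention, self.cytokine_mention
        if cm.doc != km.doc or cm.sentence_index != km.sentence_index:
            raise ValueError("instance mentions must share one sentence of one document")
        if cm.entity_type != "cell" or km.entity_type != "cytokine":
            raise ValueError("pair order is (cell, cytokine)")
        # overlap resolution must have run first
        assert not cm.overlaps(km), "overlapping mentions in one instance"


@dataclass
class Bag:
    """All instances of one pair across the corpus, plus its label."""

    pair_key: PairKey
    instances: list[Instance]
    label: str = "unlabeled"  # positive | negative | unlabeled

    def __post_init__(self) -> None:
        if not self.instances:
            raise ValueError("a bag needs at least one instance")
        if any(i.pair_key != self.pair_key for i in self.instances):
            raise ValueError("bag instances must share the pair key")

    @property
    def supporting_docs(self) -> set[str]:
        return {i.doc for i in self.instances}

    def __len__(self) -> int:
        return len(self.instances)


@dataclass(frozen=True)
class ReferenceDB:
    """Silver-standard set of known cell–cytokine relations."""

    relations: frozenset[PairKey]
    provenance: str = ""

    def __contains__(self, pair: PairKey) -> bool:
        return pair in self.relations

    def __len__(self) -> int:
        return len(self.relations)


def generate_instances(doc: Document, mentions: Sequence[EntityMention]) -> list[Instance]:
    """Cartesian product of cell × cytokine mentions within each sentence.

    ``mentions`` must already be overlap-resolved. Pairs never cross
    sentence boundaries.
    """
    by_sentence: dict[int, tuple[list[EntityMention], list[EntityMention]]] = {}
    for m in mentions:
        if m.doc != doc.pmid:
            raise ValueError(f"mention of {m.doc} passed with document {doc.pmid}")
        cells, cytokines = by_sentence.setdefault(m.sentence_index, ([], []))
        (cells if m.entity_type == "cell" else cytokines).append(m)
    instances: list[Instance] = []
    for sent_idx in sorted(by_sentence):
        cells, cytokines = by_sentence[sent_idx]
        for cm in cells:
            for km in cytokines:
                instances.append(
                    Instance(
                        pair_key=(cm.canonical, km.canonical),
                        doc=doc.pmid,
                        sentence_index=sent_idx,
                        cell_mention=cm,
                        cytokine_mention=km,
                    )
                )
    return instances


def build_bags(instances: Iterable[Instance]) -> list[Bag]:
    """Partition instances into one bag per distinct pair key."""
    groups: dict[PairKey, list[Instance]] = {}
    for inst in instances:
        groups.setdefault(inst.pair_key, []).append(inst)
    return [Bag(pair_key=k, instances=v) for k, v in sorted(groups.items())]


def label_bags(bags: Iterable[Bag], db: ReferenceDB) -> list[Bag]:
    """Distant supervision: positive iff the pair is in the reference DB."""
    db_entities = {e for pair in db.relations for e in pair}
    labeled = []
    for bag in bags:
        cell, cytokine = bag.pair_key
        if cell not in db_entities and cytokine not in db_entities and db.relations:
            logger.debug("pair %r shares no entity with the reference DB", bag.pair_key)
        labeled.append(
            replace_label(bag, "positive" if bag.pair_key in db else "negative")
        )
    return labeled


def replace_label(bag: Bag, label: str) -> Bag:
    return Bag(pair_key=bag.pair_key, instances=list(bag.instances), label=label)


def pair_frequency(bag: Bag, corpus_size: int) -> float:
    """Fraction of corpus abstracts containing a sentence-level
    co-occurrence of the bag's pair."""
    if corpus_size <= 0:
        raise ValueError("corpus_size must be positive")
    n_docs = len(bag.supporting_docs)
    if n_docs > corpus_size:
        raise ValueError("supporting documents exceed corpus size")
    return n_docs / corpus_size


# --------------------------------------------------------------------------
# serialization
# --------------------------------------------------------------------------


def load_reference_db(path: str | Path) -> ReferenceDB:
    """Read a reference DB TSV: cell<TAB>cytokine, optional header."""
    relations: set[PairKey] = set()
    with open(path, encoding="utf-8") as fh:
        for row in csv.reader(fh, delimiter="\t"):
            if len(row) < 2 or not row[0].strip():
                continue
            if row[0].strip().lower() == "cell" and row[1].strip().lower() == "cytokine":
                continue
            relations.add((row[0].strip(), row[1].strip()))
    return ReferenceDB(frozenset(relations), provenance=f"tsv:{Path(path).name}")


def save_reference_db(db: ReferenceDB, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(["cell", "cytokine"])
        for cell, cytokine in sorted(db.relations):
            writer.writerow([cell, cytokine])


def write_bags(bags: Iterable[Bag], path: str | Path) -> None:
    """Serialize bags as JSONL: pair_key, label, instance locations."""
    with open(path, "w", encoding="utf-8") as fh:
        for bag in bags:
            fh.write(
                json.dumps(
                    {
                        "cell": bag.pair_key[0],
                        "cytokine": bag.pair_key[1],
                        "label": bag.label,
                        "instances": [
                            {
                                "pmid": i.doc,
                                "sentence_index": i.sentence_index,
                                "cell_span": [i.cell_mention.start, i.cell_mention.end],
                                "cytokine_span": [
                                    i.cytokine_mention.start,
                                    i.cytokine_mention.end,
                                ],
                            }
                            for i in bag.instances
                        ],
                    },
                    ensure_ascii=False,
                )
                + "\n"
            )
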