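"""Dictionary-based named entity recognition.

Matching is exact, case-insensitive and token-boundary aligned: an
occurrence of a lexicon synonym counts only when it is not flanked by
letters or digits, so "IL6R" never matches the synonym "IL6", while a hyphen
does act as a boundary ("anti-IL-6" contains a match for "IL-6"). Every
mention carries 0-based half-open character offsets into the abstract — in
"The dendritic cells were safely tolerated." the cell mention spans
characters 4 to 19 ("dendritic cells").
"""

from __future__ import annotations

import csv
import re
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

from .corpus import Document
from .lexicon import Lexicon

__all__ = ["EntityMention", "annotate", "resolve_overlaps", "evaluate_ner", "write_annotations"]


@dataclass(frozen=True)
class EntityMention:
    """A typed entity span within one sentence of a document."""

    doc: str  # pmid
    sentence_index: int
    start: int  # offset into the abstract, 0-based inclusive
    end: int  # exclusive
    surface: str
    entity_type: str  # "cell" | "cytokine"
    canonical: str

    def overlaps(self, other: "EntityMention") -> bool:
        return self.doc == other.doc and self.start < other.end and other.start < self.end

    @property
    def length(self) -> int:
        return self.end - self.start


_TYPE_ORDER = {"cell": 0, "cytokine": 1}


def _boundary_pattern(synonym: str) -> re.Pattern[str]:
    # not flanked by letters/digits; hyphen and other punctuation are boundaries
    return re.compile(
        r"(?<![A-Za-z0-9])" + re.escape(synonym) + r"(?![A-Za-z0-9])", re.IGNORECASE
    )


def annotate(doc: Document, lex: Lexicon) -> list[EntityMention]:
    """Find every occurrence of every lexicon synonym in ``doc``.

    The document must be sentence-segmented. All matches are returned,
    including mutually overlapping ones — feed the result through
    :func:`resolve_overlaps` before pairing. Mentions are sorted by
    (start, end).
    """
    if not doc.sentences:
        raise ValueError(f"document {doc.pmid} is not segmented")
    if len(lex) == 0:
        raise ValueError("empty lexicon")
    text = doc.abstract
    lowered = text.lower()
    mentions: list[EntityMention] = []
    for synonym, canonical in lex.entries.items():
        if synonym not in lowered:  # cheap prefilter before the regex scan
            continue
        pattern = _boundary_pattern(synonym)
        for m in pattern.finditer(text):
            sent_idx = _sentence_of(doc, m.start(), m.end())
            if sent_idx is None:
                continue  # spans a sentence boundary; cannot be paired
            mentions.append(
                EntityMention(
                    doc=doc.pmid,
                    sentence_index=sent_idx,
                    start=m.start(),
                    end=m.end(),
                    surface=text[m.start() : m.end()],
                    entity_type=lex.entity_type,
                    canonical=canonical,
                )
            )
    mentions.sort(key=lambda mm: (mm.start, mm.end))
    return mentions


def _sentence_of(doc: Document, start: int, end: int) -> int | None:
    for i, s in enumerate(doc.sentences):
        if start >= s.start and end <= s.end:
            return i
    return None


def resolve_overlaps(mentions: Sequence[EntityMention]) -> list[EntityMention]:
    """Keep a non-overlapping subset of mentions, longest span first.

    Among overlapping candidates the longest span wins ("natural killer
    cell" beats the embedded cytokine synonym "killer"); ties go to the
    earlier start, then to cells over cytokines. Idempotent.
    """
    ordered = sorted(
        mentions,
        key=lambda m: (-m.length, m.start, _TYPE_ORDER.get(m.entity_type, 2)),
    )
    kept: list[EntityMention] = []
    by_doc: dict[str, list[EntityMention]] = {}
    for m in ordered:
        if any(m.overlaps(k) for k in by_doc.get(m.doc, ())):
            continue
        kept.append(m)
        by_doc.setdefault(m.doc, []).append(m)
    kept.sort(key=lambda m: (m.doc, m.start, m.end))
    return kept


def evaluate_ner(
    predicted: Iterable[EntityMention],
    reference: set[tuple[str, str, str]],
) -> tuple[float, float]:
    """Document-level precision and recall against a reference of
    (pmid, entity_type, canonical) triples.

    Mention multiplicity is collapsed: a triple predicted five times counts
    once. With an empty reference and empty predictions both scores are 1.0
    by convention; with a non-empty reference and no predictions precision
    is defined as 0.
    """
    pred_triples = {(m.doc, m.entity_type, m.canonical) for m in predicted}
    if not reference and not pred_triples:
        return 1.0, 1.0
    tp = len(pred_triples & reference)
    precision = tp / len(pred_triples) if pred_triples else 0.0
    recall = tp / len(reference) if reference else 1.0
    return precision, recall


def write_annotations(mentions: Iterable[EntityMention], path: str | Path) -> None:
    """Write mentions as TSV: pmid, sentence_index, start, end, surface,
    entity_type, canonical."""
    with open(path, "w", encoding="utf-8", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(
            ["pmid", "sentence_index", "start", "end", "surface", "entity_type", "canonical"]
        )
        for m in mentions:
            writer.writerow(
                [m.doc, m.sentence_index, m.start, m.end, m.surface, m.entity_type, m.canonical]
            )
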