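"""Cell and cytokine lexicons: synonym -> canonical reference string.

The cell lexicon is compiled from an OBO ontology (every non-obsolete term
contributes its primary label and all synonyms, each mapped to the primary
label). The cytokine lexicon comes from a registry TSV mapping synonyms to a
canonical gene-style name. Two curation passes mirror common practice for
dictionary NER: plural expansion of cell names (so "dendritic cells" still
normalizes to the "dendritic cell" concept) and removal of synonyms that are
ordinary English words ("light", "killer", ...) which otherwise fire inside
unrelated phrases such as "natural killer cell".
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping

logger = logging.getLogger(__name__)

__all__ = [
    "Lexicon",
    "build_cell_lexicon",
    "build_cytokine_lexicon",
    "expand_plurals",
    "filter_common_words",
    "load_common_words",
    "pluralize",
    "load_lexicon",
    "save_lexicon",
]


@dataclass(frozen=True)
class Lexicon:
    """Case-insensitive synonym table for one entity type.

    ``entries`` maps a lower-cased synonym to its canonical reference
    string. Lookups go through :meth:`lookup` which lower-cases the query.
    """

    entity_type: str  # "cell" | "cytokine"
    entries: Mapping[str, str]
    provenance: str = ""

    def __post_init__(self) -> None:
        if self.entity_type not in ("cell", "cytokine"):
            raise ValueError(f"entity_type must be cell|cytokine, got {self.entity_type!r}")
        for syn in self.entries:
            if not syn or not syn.strip():
                raise ValueError("empty synonym in lexicon")

    def lookup(self, synonym: str) -> str | None:
        return self.entries.get(synonym.lower())

    def __len__(self) -> int:
        return len(self.entries)

    def __contains__(self, synonym: str) -> bool:
        return synonym.lower() in self.entries

    @property
    def canonicals(self) -> set[str]:
        return set(self.entries.values())


def _merge(entries: dict[str, str], synonym: str, canonical: str) -> None:
    """Insert, resolving duplicate synonyms to the lexicographically first canonical."""
    key = synonym.strip().lower()
    if not key:
        return
    prev = entries.get(key)
    if prev is None:
        entries[key] = canonical
    elif prev != canonical:
        keep = min(prev, canonical)
        logger.warning(
            "synonym %r maps to both %r and %r; keeping %r", key, prev, canonical, keep
        )
        entries[key] = keep


# --------------------------------------------------------------------------
# builders
# --------------------------------------------------------------------------


def build_cell_lexicon(obo_path: str | Path) -> Lexicon:
    """Compile a cell lexicon from an OBO ontology file.

    Every non-obsolete term contributes one entry for its primary label and
    one per synonym, all canonicalized to the primary label.
    """
    import obonet

    graph = obonet.read_obo(str(obo_path))
    entries: dict[str, str] = {}
    for _term_id, data in graph.nodes(data=True):
        name = data.get("name")
        if not name:
            continue
        _merge(entries, name, name)
        for syn_line in data.get("synonym", []):
            # OBO synonym lines look like: "DC" EXACT []
            if syn_line.startswith('"'):
                close = syn_line.find('"', 1)
                syn = syn_line[1:close] if close > 0 else syn_line.strip('"')
            else:
                syn = syn_line
            _merge(entries, syn, name)
    return Lexicon("cell", entries, provenance=f"obo:{Path(obo_path).name}")


def build_cytokine_lexicon(registry_path: str | Path) -> Lexicon:
    """Compile a cytokine lexicon from a registry TSV with columns
    ``canonical<TAB>synonym`` (header optional). The canonical name itself is
    always a valid lookup."""
    entries: dict[str, str] = {}
    with open(registry_path, encoding="utf-8") as fh:
        reader = csv.reader(fh, delimiter="\t")
        for row in reader:
            if not row or all(not c.strip() for c in row):
                continue
            if len(row) < 2:
                raise ValueError(f"registry row needs 2 columns: {row!r}")
            canonical, synonym = row[0].strip(), row[1].strip()
            if canonical.lower() == "canonical" and synonym.lower() == "synonym":
                continue  # header
            _merge(entries, canonical, canonical)
            _merge(entries, synonym, canonical)
    return Lexicon("cytokine", entries, provenance=f"registry:{Path(registry_path).name}")


# --------------------------------------------------------------------------
# plural expansion
# --------------------------------------------------------------------------

_IRREGULAR_PLURALS = {
    "is": "es",  # hypothesis -> hypotheses, analysis -> analyses
    "us": "i",  # thymus -> thymi, nucleus -> nuclei
    "um": "a",  # bacterium -> bacteria
    "on": "a",  # criterion -> criteria (rare in cell names; harmless)
}


def _looks_plural(word: str) -> bool:
    w = word.lower()
    return w.endswith("s") and not w.endswith(("ss", "us", "is"))


def pluralize(term: str) -> str:
    """Pluralize the final word of ``term`` with English inflection rules.

    Returns ``term`` unchanged when the final word already looks plural, so
    repeated application is a fixed point.
    """
    head, sep, word = term.rpartition(" ")
    if not word:
        return term
    if _looks_plural(word):
        return term
    lower = word.lower()
    for suffix, repl in _IRREGULAR_PLURALS.items():
        if lower.endswith(suffix) and len(lower) > len(suffix) + 1:
            plural = word[: -len(suffix)] + repl
            return head + sep + plural
    if lower.endswith("y") and len(lower) > 1 and lower[-2] not in "aeiou":
        return head + sep + word[:-1] + "ies"
    if lower.endswith(("s", "x", "z", "ch", "sh")):
        return head + sep + word + "es"
    return head + sep + word + "s"


def expand_plurals(lex: Lexicon) -> Lexicon:
    """Add a plural variant of every synonym, mapping to the same canonical.

    Idempotent: plural forms are fixed points of :func:`pluralize` and
    already-present synonyms are never overwritten.
    """
    entries = dict(lex.entries)
    for syn, canonical in lex.entries.items():
        plural = pluralize(syn).lower()
        if plural != syn and plural not in entries:
            entries[plural] = canonical
    return Lexicon(lex.entity_type, entries, provenance=lex.provenance)


# --------------------------------------------------------------------------
# common-word filtering
# --------------------------------------------------------------------------


def load_common_words(path: str | Path | None = None) -> frozenset[str]:
    """Load the common-English-word list (one word per line, ``#`` comments).

    Defaults to the list bundled with the package.
    """
    if path is None:
        text = (resources.files("cellkine") / "data" / "common_words.txt").read_text("utf-8")
    else:
        text = Path(path).read_text("utf-8")
    words = {
        line.strip().lower()
        for line in text.splitlines()
        if line.strip() and not line.startswith("#")
    }
    return frozenset(words)


def filter_common_words(lex: Lexicon, common_words: Iterable[str]) -> Lexicon:
    """Drop single-token synonyms that are ordinary English words.

    Canonical names are kept even when common (removing them would orphan
    the concept); multi-word synonyms are never filtered because only a
    single token can be an ambiguous English word.
    """
    common = {w.lower() for w in common_words}
    entries = {
        syn: canonical
        for syn, canonical in lex.entries.items()
        if " " in syn or syn not in common or syn == canonical.lower()
    }
    return Lexicon(lex.entity_type, entries, provenance=lex.provenance)


# --------------------------------------------------------------------------
# serialization: 2-column TSV (synonym, canonical)
# --------------------------------------------------------------------------


def save_lexicon(lex: Lexicon, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(["synonym", "canonical"])
        for syn in sorted(lex.entries):
            writer.writerow([syn, lex.entries[syn]])


def load_lexicon(path: str | Path, entity_type: str) -> Lexicon:
    entries: dict[str, str] = {}
    with open(path, encoding="utf-8") as fh:
        reader = csv.reader(fh, delimiter="\t")
        header = next(reader, None)
        if header is not None and [c.lower() for c in header[:2]] != ["synonym", "canonical"]:
            if len(header) >= 2:
                _merge(entries, header[0], header[1])
        for row in reader:
            if len(row) >= 2 and row[0].strip():
                _merge(entries, row[0], row[1])
    return Lexicon(entity_type, entries, provenance=f"tsv:{Path(path).name}")
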