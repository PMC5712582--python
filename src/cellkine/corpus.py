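"""Corpus I/O and sentence segmentation.

A corpus is a collection of :class:`Document` objects, each holding a PubMed
identifier, a title and an abstract. Sentences are stored as character-offset
spans into the raw abstract string (0-based, half-open), so every downstream
annotation can be mapped back to the exact source text. Two on-disk dialects
are supported: Medline/PubMed XML (``PubmedArticleSet``) and a JSON-lines
format with one ``{"pmid": ..., "title": ..., "abstract": ...}`` object per
line.
"""

from __future__ import annotations

import json
import logging
import re
import unicodedata
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Iterator, Sequence

from lxml import etree

logger = logging.getLogger(__name__)

__all__ = [
    "Sentence",
    "Document",
    "load_corpus",
    "write_corpus",
    "segment_sentences",
    "fetch_pubmed",
]


@dataclass(frozen=True)
class Sentence:
    """A sentence span within an abstract.

    ``abstract[start:end] == text`` always holds; offsets are 0-based and
    half-open.
    """

    start: int
    end: int
    text: str

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(f"invalid sentence span [{self.start}, {self.end})")


@dataclass(frozen=True)
class Document:
    """One abstract with optional pre-computed sentence spans."""

    pmid: str
    title: str
    abstract: str
    sentences: tuple[Sentence, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        for s in self.sentences:
            if self.abstract[s.start : s.end] != s.text:
                raise ValueError(
                    f"sentence span [{s.start}, {s.end}) does not match abstract of {self.pmid}"
                )


# --------------------------------------------------------------------------
# sentence segmentation
# --------------------------------------------------------------------------

#: Tokens after which a period does not end a sentence. Tuned to biomedical
#: abstracts: latinisms, measurement shorthand, figure/table references and
#: species-style abbreviations.
ABBREVIATIONS = frozenset(
    {
        "e.g", "i.e", "i.v", "i.p", "s.c", "p.o", "et al", "al", "vs", "cf",
        "ca", "approx", "fig", "figs", "ref", "refs", "no", "nos", "vol",
        "dr", "prof", "inc", "ltd", "spp", "sp", "subsp", "st", "resp",
        "min", "max", "mol", "wt",
    }
)

# Sentence boundary: terminal punctuation, optional closing bracket/quote,
# whitespace, then an upper-case letter or digit.
_BOUNDARY = re.compile(r"[.!?]+[\)\]\"']*\s+(?=[A-Z0-9(\[])")


def _is_abbreviation(text: str, dot_pos: int) -> bool:
    """True when the period at ``dot_pos`` terminates a known abbreviation."""
    prefix = text[:dot_pos]
    m = re.search(r"[A-Za-z][A-Za-z.]*$", prefix)
    if m is None:
        return False
    token = m.group(0).rstrip(".").lower()
    if token in ABBREVIATIONS:
        return True
    # "et al." style two-word latinisms
    two = re.search(r"([a-z]+ [a-z.]+)$", prefix.lower())
    if two and two.group(1).rstrip(".") in ABBREVIATIONS:
        return True
    return False


def split_spans(text: str) -> list[tuple[int, int]]:
    """Split ``text`` into sentence spans (start, end), whitespace-trimmed.

    Rule-based: a run of ``.!?`` followed by whitespace and an upper-case
    letter, digit or opening bracket ends a sentence, unless the period
    belongs to a known abbreviation or sits between digits (decimals).
    Falls back to a single span when no boundary is found.
    """
    spans: list[tuple[int, int]] = []
    start = 0
    for m in _BOUNDARY.finditer(text):
        dot = m.start()
        if dot > 0 and text[dot] == "." and text[dot - 1].isdigit():
            after = m.end()
            if after < len(text) and text[after].isdigit():
                continue
        if text[dot] == "." and _is_abbreviation(text, dot):
            continue
        end = dot
        while end < len(text) and text[end] in ".!?)]\"'":
            end += 1
        spans.append((start, end))
        start = m.end()
    if start < len(text):
        spans.append((start, len(text)))
    # trim whitespace from each span; drop spans that are all whitespace
    trimmed: list[tuple[int, int]] = []
    for s, e in spans:
        while s < e and text[s].isspace():
            s += 1
        while e > s and text[e - 1].isspace():
            e -= 1
        if s < e:
            trimmed.append((s, e))
    return trimmed


def segment_sentences(doc: Document) -> Document:
    """Return a copy of ``doc`` with sentence spans populated.

    Idempotent; the concatenation of spans covers all non-whitespace
    characters of the abstract.
    """
    if not doc.abstract:
        raise ValueError(f"document {doc.pmid} has an empty abstract")
    spans = split_spans(doc.abstract)
    sentences = tuple(Sentence(s, e, doc.abstract[s:e]) for s, e in spans)
    return replace(doc, sentences=sentences)


# --------------------------------------------------------------------------
# I/O
# --------------------------------------------------------------------------


def _nfc(text: str) -> str:
    return unicodedata.normalize("NFC", text)


def _iter_jsonl(path: Path) -> Iterator[Document]:
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            try:
                rec = json.loads(line)
            except json.JSONDecodeError:
                logger.warning("%s line %d: malformed JSON, skipped", path, lineno)
                continue
            pmid = str(rec.get("pmid", "")).strip()
            abstract = rec.get("abstract") or ""
            if not pmid or not abstract:
                logger.warning("%s line %d: record without pmid/abstract, skipped", path, lineno)
                continue
            yield Document(pmid=pmid, title=_nfc(rec.get("title") or ""), abstract=_nfc(abstract))


def _iter_medline_xml(path: Path) -> Iterator[Document]:
    tree = etree.parse(str(path))
    for art in tree.iter("PubmedArticle"):
        pmid_el = art.find(".//PMID")
        pmid = pmid_el.text.strip() if pmid_el is not None and pmid_el.text else ""
        title_el = art.find(".//ArticleTitle")
        title = "".join(title_el.itertext()).strip() if title_el is not None else ""
        abs_parts = [
            "".join(el.itertext()).strip() for el in art.findall(".//Abstract/AbstractText")
        ]
        abstract = " ".join(p for p in abs_parts if p)
        if not pmid or not abstract:
            logger.warning("%s: PubmedArticle %r without pmid/abstract, skipped", path, pmid)
            continue
        yield Document(pmid=pmid, title=_nfc(title), abstract=_nfc(abstract))


def load_corpus(path: str | Path, format: str | None = None) -> list[Document]:
    """Load a corpus of documents from ``path``.

    Parameters
    ----------
    path:
        Input file.
    format:
        ``"jsonl"`` or ``"medline-xml"``; inferred from the extension when
        omitted (``.xml`` -> Medline XML, everything else -> JSONL).

    Records without an abstract are skipped with a logged warning; duplicate
    pmids raise ``ValueError``.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format is None:
        format = "medline-xml" if path.suffix.lower() == ".xml" else "jsonl"
    if format == "jsonl":
        docs = list(_iter_jsonl(path))
    elif format == "medline-xml":
        docs = list(_iter_medline_xml(path))
    else:
        raise ValueError(f"unknown corpus format: {format!r}")
    seen: set[str] = set()
    for d in docs:
        if d.pmid in seen:
            raise ValueError(f"duplicate pmid in corpus: {d.pmid}")
        seen.add(d.pmid)
    return docs


def write_corpus(docs: Iterable[Document], path: str | Path) -> None:
    """Write documents as JSON-lines (one object per line, UTF-8)."""
    path = Path(path)
    with open(path, "w", encoding="utf-8") as fh:
        for d in docs:
            fh.write(
                json.dumps(
                    {"pmid": d.pmid, "title": d.title, "abstract": d.abstract},
                    ensure_ascii=False,
                )
                + "\n"
            )


# --------------------------------------------------------------------------
# PubMed fetch (thin convenience; all tests run on files)
# --------------------------------------------------------------------------


def fetch_pubmed(
    query: str,
    date_range: tuple[str, str] | None,
    cache_dir: str | Path,
    out_path: str | Path,
    email: str = "cellkine@example.org",
    batch_size: int = 200,
) -> Path:
    """Fetch abstracts matching ``query`` from PubMed into a JSONL corpus.

    Results are cached per (query, date_range) under ``cache_dir``; a repeat
    call with a warm cache performs no network requests. Requires network
    access on a cold cache.
    """
    from Bio import Entrez  # imported lazily: network-only path

    cache_dir = Path(cache_dir)
    cache_dir.mkdir(parents=True, exist_ok=True)
    key = re.sub(r"\W+", "_", f"{query}_{date_range}")[:120]
    cache_file = cache_dir / f"{key}.jsonl"
    if cache_file.exists():
        docs = load_corpus(cache_file, format="jsonl")
        write_corpus(docs, out_path)
        return Path(out_path)

    Entrez.email = email
    term = query
    kwargs: dict = {"db": "pubmed", "term": term, "retmax": 100000}
    if date_range is not None:
        kwargs.update(mindate=date_range[0], maxdate=date_range[1], datetype="pdat")
    with Entrez.esearch(**kwargs) as handle:
        ids: Sequence[str] = Entrez.read(handle)["IdList"]
    docs = []
    for i in range(0, len(ids), batch_size):
        chunk = ids[i : i + batch_size]
        with Entrez.efetch(db="pubmed", id=",".join(chunk), rettype="xml") as handle:
            data = handle.read()
        tmp = cache_dir / "_batch.xml"
        tmp.write_bytes(data if isinstance(data, bytes) else data.encode())
        docs.extend(load_corpus(tmp, format="medline-xml"))
        tmp.unlink()
    write_corpus(docs, cache_file)
    write_corpus(docs, out_path)
    return Path(out_path)
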