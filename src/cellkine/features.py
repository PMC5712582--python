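"""Context-window tf-idf features for pair instances.

Each instance is represented by the lemmas of up to three tokens before and
after each of its two entity mentions, taken inside the sentence. Tokens
that fall inside any entity mention are replaced by a type placeholder
(``CELL`` / ``CYTOKINE``) so the classifier learns from context words, not
from the identity of specific entities. Term weights are tf-idf with
idf(t) = ln(n_docs / df(t)) + 1 and L2 normalization; terms appearing in
fewer than ``min_df`` (a fraction, default 1%) of the documents are pruned.
The vocabulary and idf weights are frozen at fit time: transforming new
data never mutates them.
"""

from __future__ import annotations

import csv
import math
import re
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import scipy.sparse as sp

from .corpus import Document
from .ner import EntityMention
from .pairs import Instance

__all__ = [
    "tokenize_spans",
    "lemmatize",
    "extract_context",
    "Vocabulary",
    "fit_vocabulary",
    "vectorize",
    "vectorize_many",
]

CELL_PLACEHOLDER = "CELL"
CYTOKINE_PLACEHOLDER = "CYTOKINE"

# words and hyphenated biomedical tokens kept whole (IL-6, CD4+, alpha-7)
_TOKEN = re.compile(r"[A-Za-z0-9][A-Za-z0-9\-\+]*")


def tokenize_spans(text: str, offset: int = 0) -> list[tuple[int, int, str]]:
    """Tokenize ``text`` into (start, end, token) triples.

    ``offset`` shifts the reported spans, so sentence-local tokenization
    can report abstract-level offsets.
    """
    return [(m.start() + offset, m.end() + offset, m.group(0)) for m in _TOKEN.finditer(text)]


_IRREGULAR_LEMMAS = {
    "is": "be", "are": "be", "was": "be", "were": "be", "been": "be", "being": "be",
    "has": "have", "had": "have", "having": "have",
    "does": "do", "did": "do", "done": "do",
    "cells": "cell", "mice": "mouse", "media": "medium", "data": "datum",
    "analyses": "analysis", "hypotheses": "hypothesis",
}

_KEEP_S = ("ss", "us", "is")  # express, thymus, analysis: final s is not plural


def lemmatize(token: str) -> str:
    """Rule-based English lemma: lowercase, strip plural/verb suffixes.

    Intentionally light-weight — it only needs to collapse inflectional
    variants of context words so that "secretes"/"secreted"/"secreting"
    share one feature. Unknown forms pass through lowercased.
    """
    w = token.lower()
    if w in _IRREGULAR_LEMMAS:
        return _IRREGULAR_LEMMAS[w]
    if len(w) <= 3 or not w.isalpha():
        return w
    if w.endswith("ies") and len(w) > 4:
        return w[:-3] + "y"
    if w.endswith("sses"):
        return w[:-2]
    if w.endswith("es") and len(w) > 4 and w[-3] in "sxzh":
        return w[:-2]
    if w.endswith("s") and not w.endswith(_KEEP_S):
        return w[:-1]
    if w.endswith("ing") and len(w) > 5:
        stem = w[:-3]
        if len(stem) > 2 and stem[-1] == stem[-2]:  # stopping -> stop
            stem = stem[:-1]
        return stem + "e" if _needs_e(stem) else stem
    if w.endswith("ed") and len(w) > 4:
        stem = w[:-2]
        if len(stem) > 2 and stem[-1] == stem[-2]:
            stem = stem[:-1]
        return stem + "e" if _needs_e(stem) else stem
    return w


def _needs_e(stem: str) -> bool:
    # induc -> induce, activat -> activate, measur -> measure
    return stem.endswith(("at", "uc", "ur", "as", "iv", "ag", "iz", "ys"))


def extract_context(
    inst: Instance,
    doc: Document,
    window: int = 3,
    sentence_mentions: Sequence[EntityMention] | None = None,
) -> list[str]:
    """Lemma tokens from a ±``window`` context around each entity of the pair.

    The windows of the two entities are merged positionally: each token
    position inside either window contributes exactly once, even when the
    windows overlap. Token positions covered by any entity mention of the
    sentence (the pair's own or a third entity's) yield the entity-type
    placeholder instead of the surface lemma. Windows truncate at sentence
    boundaries.
    """
    sentence = doc.sentences[inst.sentence_index]
    tokens = tokenize_spans(sentence.text, offset=sentence.start)
    mentions = list(sentence_mentions) if sentence_mentions is not None else [
        inst.cell_mention,
        inst.cytokine_mention,
    ]
    mentions = [m for m in mentions if m.sentence_index == inst.sentence_index]

    def mention_of(tok_start: int, tok_end: int) -> EntityMention | None:
        for m in mentions:
            if tok_start < m.end and m.start < tok_end:  # token touches the mention
                return m
        return None

    def window_positions(m: EntityMention) -> set[int]:
        inside = [i for i, (s, e, _) in enumerate(tokens) if s < m.end and m.start < e]
        if inside:
            first, last = inside[0], inside[-1]
        else:  # mention aligned to no token (punctuation-only edge); anchor by offset
            first = next((i for i, (s, _, _) in enumerate(tokens) if s >= m.end), len(tokens))
            last = first - 1
        left = range(max(0, first - window), first)
        right = range(last + 1, min(len(tokens), last + 1 + window))
        return set(left) | set(right)

    positions = sorted(
        window_positions(inst.cell_mention) | window_positions(inst.cytokine_mention)
    )
    out: list[str] = []
    for i in positions:
        s, e, tok = tokens[i]
        m = mention_of(s, e)
        if m is not None:
            out.append(CELL_PLACEHOLDER if m.entity_type == "cell" else CYTOKINE_PLACEHOLDER)
        else:
            out.append(lemmatize(tok))
    return out


# --------------------------------------------------------------------------
# vocabulary / tf-idf
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class Vocabulary:
    """Frozen term list with idf weights.

    ``terms`` are lexicographically sorted; ``idf[i]`` belongs to
    ``terms[i]``; ``df[i]`` is the raw document frequency observed at fit
    time over ``n_docs_fit`` documents.
    """

    terms: tuple[str, ...]
    idf: tuple[float, ...]
    df: tuple[int, ...]
    min_df: float
    n_docs_fit: int

    def __post_init__(self) -> None:
        if len(set(self.terms)) != len(self.terms):
            raise ValueError("duplicate terms in vocabulary")
        if any(w <= 0 for w in self.idf):
            raise ValueError("idf weights must be positive")

    def __len__(self) -> int:
        return len(self.terms)

    @property
    def index(self) -> dict[str, int]:
        return {t: i for i, t in enumerate(self.terms)}

    def save(self, path: str | Path) -> None:
        with open(path, "w", encoding="utf-8", newline="") as fh:
            writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
            writer.writerow(["term", "df", "idf"])
            for t, d, w in zip(self.terms, self.df, self.idf):
                writer.writerow([t, d, repr(w)])

    @classmethod
    def load(cls, path: str | Path, min_df: float = 0.0, n_docs_fit: int = 0) -> "Vocabulary":
        terms, dfs, idfs = [], [], []
        with open(path, encoding="utf-8") as fh:
            reader = csv.reader(fh, delimiter="\t")
            next(reader)  # header
            for row in reader:
                terms.append(row[0])
                dfs.append(int(row[1]))
                idfs.append(float(row[2]))
        return cls(tuple(terms), tuple(idfs), tuple(dfs), min_df, n_docs_fit)


def fit_vocabulary(
    token_lists: Sequence[Sequence[str]],
    doc_ids: Sequence[str],
    min_df: float = 0.01,
) -> Vocabulary:
    """Fit a vocabulary from per-instance token lists.

    Document frequency counts distinct documents (``doc_ids``, parallel to
    ``token_lists``) containing the term; terms with df < min_df × n_docs
    are pruned. idf(t) = ln(n_docs / df(t)) + 1.
    """
    if not token_lists:
        raise ValueError("no token lists to fit on")
    if len(token_lists) != len(doc_ids):
        raise ValueError("token_lists and doc_ids must be parallel")
    docs_of_term: dict[str, set[str]] = {}
    for tokens, doc in zip(token_lists, doc_ids):
        for t in tokens:
            docs_of_term.setdefault(t, set()).add(doc)
    n_docs = len(set(doc_ids))
    threshold = min_df * n_docs
    kept = sorted(t for t, docs in docs_of_term.items() if len(docs) >= threshold)
    df = tuple(len(docs_of_term[t]) for t in kept)
    idf = tuple(math.log(n_docs / d) + 1.0 for d in df)
    return Vocabulary(tuple(kept), idf, df, min_df, n_docs)


def vectorize(tokens: Iterable[str], vocab: Vocabulary) -> np.ndarray:
    """tf-idf vector: weight(t) = count(t) × idf(t), L2-normalized.

    Out-of-vocabulary tokens are ignored; an all-OOV instance maps to the
    zero vector.
    """
    index = vocab.index
    vec = np.zeros(len(vocab))
    for t in tokens:
        i = index.get(t)
        if i is not None:
            vec[i] += vocab.idf[i]
    norm = np.linalg.norm(vec)
    if norm > 0:
        vec /= norm
    return vec


def vectorize_many(token_lists: Sequence[Sequence[str]], vocab: Vocabulary) -> sp.csr_matrix:
    """Sparse matrix of tf-idf vectors, one row per token list."""
    index = vocab.index
    idf = np.asarray(vocab.idf)
    rows, cols, vals = [], [], []
    for r, tokens in enumerate(token_lists):
        counts: dict[int, int] = {}
        for t in tokens:
            i = index.get(t)
            if i is not None:
                counts[i] = counts.get(i, 0) + 1
        if not counts:
            continue
        w = np.array([c * idf[i] for i, c in counts.items()])
        w /= np.linalg.norm(w)
        for (i, _), v in zip(counts.items(), w):
            rows.append(r)
            cols.append(i)
            vals.append(v)
    return sp.csr_matrix((vals, (rows, cols)), shape=(len(token_lists), len(vocab)))
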