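"""Cross-validation and threshold-based evaluation of pair scoring.

Documents (not pairs) are partitioned into k folds so that no abstract
contributes evidence to both the training and the test side of a fold. Each
fold fits its own vocabulary and sMIL model on the training documents only;
test bags are built from test documents only and scored with the frozen
model. Scores are pooled across folds into precision-recall curves for the
two rankings under study — classifier confidence and raw pair frequency —
summarized by average precision (step-interpolated area under the PR
curve).
"""

from __future__ import annotations

import logging
import random
from dataclasses import dataclass, field
from typing import Sequence

from .classifier import SmilModel, confidence as bag_confidence, train_smil
from .corpus import Document
from .features import extract_context, fit_vocabulary, vectorize_many
from .ner import EntityMention
from .pairs import Bag, ReferenceDB, build_bags, generate_instances, label_bags, pair_frequency

logger = logging.getLogger(__name__)

__all__ = [
    "PRPoint",
    "CVResult",
    "pr_curve",
    "auc_pr",
    "best_f_threshold",
    "cross_validate",
]


@dataclass(frozen=True)
class PRPoint:
    threshold: float
    precision: float
    recall: float
    f1: float


@dataclass
class ScoredPair:
    pair_key: tuple[str, str]
    confidence: float
    frequency: float
    label: bool  # distant-supervision truth (pair in reference DB)
    fold: int


@dataclass
class CVResult:
    fold_of: dict[str, int]  # pmid -> fold index
    scored: list[ScoredPair]
    curve_confidence: list[PRPoint]
    curve_frequency: list[PRPoint]
    auc_confidence: float
    auc_frequency: float
    models: list[SmilModel] = field(default_factory=list)


# --------------------------------------------------------------------------
# threshold metrics
# --------------------------------------------------------------------------


def pr_curve(scores: Sequence[tuple[float, bool]]) -> list[PRPoint]:
    """One PR point per distinct score used as threshold (>= rule).

    Points are ordered by decreasing threshold, i.e. non-decreasing
    predicted-positive count; recall is non-increasing in the threshold.
    Raises when the labels contain no positive (recall undefined).
    """
    if not scores:
        raise ValueError("empty score list")
    n_pos = sum(1 for _, t in scores if t)
    if n_pos == 0:
        raise ValueError("no positive labels: recall undefined")
    ordered = sorted(scores, key=lambda st: -st[0])
    points: list[PRPoint] = []
    tp = fp = 0
    i = 0
    n = len(ordered)
    while i < n:
        t = ordered[i][0]
        while i < n and ordered[i][0] == t:  # group ties: threshold = this score
            tp += 1 if ordered[i][1] else 0
            fp += 0 if ordered[i][1] else 1
            i += 1
        precision = tp / (tp + fp)
        recall = tp / n_pos
        f1 = 2 * precision * recall / (precision + recall) if precision + recall > 0 else 0.0
        points.append(PRPoint(t, precision, recall, f1))
    return points


def auc_pr(curve: Sequence[PRPoint]) -> float:
    """Average precision: step-wise integral of precision over recall."""
    if not curve:
        raise ValueError("empty PR curve")
    area = 0.0
    prev_recall = 0.0
    for p in sorted(curve, key=lambda q: q.recall):
        area += (p.recall - prev_recall) * p.precision
        prev_recall = p.recall
    return float(min(max(area, 0.0), 1.0))


def best_f_threshold(curve: Sequence[PRPoint]) -> PRPoint:
    """The point maximizing F1; ties broken toward the higher threshold."""
    if not curve:
        raise ValueError("empty PR curve")
    return max(curve, key=lambda p: (p.f1, p.threshold))


# --------------------------------------------------------------------------
# cross-validation
# --------------------------------------------------------------------------


def _split_folds(pmids: Sequence[str], k: int, seed: int) -> dict[str, int]:
    order = sorted(pmids)
    rng = random.Random(seed)
    rng.shuffle(order)
    return {pmid: i % k for i, pmid in enumerate(order)}


def _bag_tokens(
    bags: Sequence[Bag],
    doc_by_pmid: dict[str, Document],
    mentions_by_sentence: dict[tuple[str, int], list[EntityMention]],
    window: int,
) -> list[list[list[str]]]:
    """Per-bag list of per-instance context token lists."""
    out = []
    for bag in bags:
        out.append(
            [
                extract_context(
                    inst,
                    doc_by_pmid[inst.doc],
                    window=window,
                    sentence_mentions=mentions_by_sentence.get((inst.doc, inst.sentence_index), []),
                )
                for inst in bag.instances
            ]
        )
    return out


def cross_validate(
    docs: Sequence[Document],
    mentions: Sequence[EntityMention],
    db: ReferenceDB,
    k: int = 5,
    seed: int = 0,
    C: float = 1.0,
    min_df: float = 0.01,
    window: int = 3,
    max_resplits: int = 10,
    keep_models: bool = False,
) -> CVResult:
    """Document-level k-fold cross-validation of the full scoring pipeline.

    ``docs`` must be segmented and ``mentions`` overlap-resolved. A split in
    which some training side lacks a positive or negative bag is discarded
    with a warning and re-drawn from the next seed.
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    if len(docs) < k:
        raise ValueError("need at least k documents")
    doc_by_pmid = {d.pmid: d for d in docs}
    mentions_by_doc: dict[str, list[EntityMention]] = {}
    mentions_by_sentence: dict[tuple[str, int], list[EntityMention]] = {}
    for m in mentions:
        mentions_by_doc.setdefault(m.doc, []).append(m)
        mentions_by_sentence.setdefault((m.doc, m.sentence_index), []).append(m)

    instances_by_doc = {
        pmid: generate_instances(doc_by_pmid[pmid], ms) for pmid, ms in mentions_by_doc.items()
    }

    fold_of: dict[str, int] = {}
    for attempt in range(max_resplits):
        fold_of = _split_folds([d.pmid for d in docs], k, seed + attempt)
        ok = True
        for fold in range(k):
            train_insts = [
                i
                for pmid, insts in instances_by_doc.items()
                if fold_of[pmid] != fold
                for i in insts
            ]
            labels = {b.pair_key: b.label for b in label_bags(build_bags(train_insts), db)}
            if "positive" not in labels.values() or "negative" not in labels.values():
                logger.warning(
                    "fold %d of split seed %d lacks a class; re-seeding split", fold, seed + attempt
                )
                ok = False
                break
        if ok:
            break
    else:
        raise ValueError("could not find a fold split with both classes in every training side")

    scored: list[ScoredPair] = []
    models: list[SmilModel] = []
    for fold in range(k):
        train_pmids = [p for p, f in fold_of.items() if f != fold]
        test_pmids = [p for p, f in fold_of.items() if f == fold]
        train_insts = [i for p in train_pmids for i in instances_by_doc.get(p, [])]
        test_insts = [i for p in test_pmids for i in instances_by_doc.get(p, [])]
        train_bags = label_bags(build_bags(train_insts), db)
        test_bags = label_bags(build_bags(test_insts), db)
        if not test_bags:
            continue

        train_tokens = _bag_tokens(train_bags, doc_by_pmid, mentions_by_sentence, window)
        flat_tokens = [toks for bag_toks in train_tokens for toks in bag_toks]
        flat_docs = [inst.doc for bag in train_bags for inst in bag.instances]
        vocab = fit_vocabulary(flat_tokens, flat_docs, min_df=min_df)

        train_matrices = [vectorize_many(toks, vocab) for toks in train_tokens]
        model = train_smil(
            train_matrices, [b.label for b in train_bags], C=C, vocab=vocab
        )
        if keep_models:
            models.append(model)

        test_tokens = _bag_tokens(test_bags, doc_by_pmid, mentions_by_sentence, window)
        n_test_docs = len(test_pmids)
        for bag, toks in zip(test_bags, test_tokens):
            mat = vectorize_many(toks, vocab)
            scored.append(
                ScoredPair(
                    pair_key=bag.pair_key,
                    confidence=bag_confidence(model, mat),
                    frequency=pair_frequency(bag, n_test_docs),
                    label=bag.label == "positive",
                    fold=fold,
                )
            )

    conf_curve = pr_curve([(s.confidence, s.label) for s in scored])
    freq_curve = pr_curve([(s.frequency, s.label) for s in scored])
    return CVResult(
        fold_of=fold_of,
        scored=scored,
        curve_confidence=conf_curve,
        curve_frequency=freq_curve,
        auc_confidence=auc_pr(conf_curve),
        auc_frequency=auc_pr(freq_curve),
        models=models,
    )
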