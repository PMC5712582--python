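"""End-to-end pipeline: annotate -> pair -> train/score -> graph -> export.

A single declarative :class:`PipelineConfig` wires every stage; unknown
keys are rejected. Each run writes a manifest recording parameter values,
the seed, input checksums and output checksums, so identical configurations
can be verified to produce identical artifacts.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from pathlib import Path

from pydantic import BaseModel, ConfigDict

from . import __version__
from .classifier import confidence as bag_confidence, train_smil
from .corpus import load_corpus, segment_sentences
from .evaluation import best_f_threshold, cross_validate
from .features import extract_context, fit_vocabulary, vectorize_many
from .graph import build_graph, export_graph, graph_stats
from .lexicon import (
    expand_plurals,
    filter_common_words,
    load_common_words,
    load_lexicon,
)
from .ner import EntityMention, annotate, resolve_overlaps
from .pairs import build_bags, generate_instances, label_bags, load_reference_db, pair_frequency

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "run_pipeline"]


class PipelineConfig(BaseModel):
    """Declarative configuration; defaults follow the method's stated
    settings (context window 3, min document frequency 1%, 5 folds)."""

    model_config = ConfigDict(extra="forbid")

    corpus: Path
    cells: Path
    cytokines: Path
    reference_db: Path
    out_dir: Path

    window: int = 3
    min_df: float = 0.01
    C: float = 1.0
    threshold: float = 0.5
    k: int = 5
    seed: int = 0
    expand_cell_plurals: bool = True
    filter_cytokine_common_words: bool = True
    common_words_path: Path | None = None
    export_formats: tuple[str, ...] = ("graphml", "edge-tsv", "evidence-tsv")
    run_cv: bool = False

    def validate_paths(self) -> None:
        for name in ("corpus", "cells", "cytokines", "reference_db"):
            p = getattr(self, name)
            if not Path(p).exists():
                raise FileNotFoundError(f"{name} path does not exist: {p}")


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def run_pipeline(cfg: PipelineConfig) -> Path:
    """Execute the full extraction pipeline and return the output directory.

    Stages: load + segment corpus; build lexicons (plural-expanded cells,
    common-word-filtered cytokines); dictionary NER with overlap
    resolution; sentence-level pairing into labeled bags; tf-idf features;
    sMIL training with confidence calibration; graph construction at the
    configured confidence threshold; exports plus a JSON manifest.
    """
    cfg.validate_paths()
    out_dir = Path(cfg.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    t0 = time.time()
    stage = "load"
    try:
        docs = [segment_sentences(d) for d in load_corpus(cfg.corpus)]
        cell_lex = load_lexicon(cfg.cells, "cell")
        cyt_lex = load_lexicon(cfg.cytokines, "cytokine")
        if cfg.expand_cell_plurals:
            cell_lex = expand_plurals(cell_lex)
        if cfg.filter_cytokine_common_words:
            cyt_lex = filter_common_words(cyt_lex, load_common_words(cfg.common_words_path))
        db = load_reference_db(cfg.reference_db)

        stage = "annotate"
        mentions: list[EntityMention] = []
        for doc in docs:
            found = annotate(doc, cell_lex) + annotate(doc, cyt_lex)
            mentions.extend(resolve_overlaps(found))
        mentions_by_sentence: dict[tuple[str, int], list[EntityMention]] = {}
        for m in mentions:
            mentions_by_sentence.setdefault((m.doc, m.sentence_index), []).append(m)

        stage = "pairs"
        doc_by_pmid = {d.pmid: d for d in docs}
        mentions_by_doc: dict[str, list[EntityMention]] = {}
        for m in mentions:
            mentions_by_doc.setdefault(m.doc, []).append(m)
        instances = [
            i
            for pmid, ms in sorted(mentions_by_doc.items())
            for i in generate_instances(doc_by_pmid[pmid], ms)
        ]
        bags = label_bags(build_bags(instances), db)
        logger.info(
            "%d instances in %d bags (%d positive)",
            len(instances),
            len(bags),
            sum(b.label == "positive" for b in bags),
        )

        stage = "train"
        bag_tokens = [
            [
                extract_context(
                    inst,
                    doc_by_pmid[inst.doc],
                    window=cfg.window,
                    sentence_mentions=mentions_by_sentence.get((inst.doc, inst.sentence_index), []),
                )
                for inst in bag.instances
            ]
            for bag in bags
        ]
        flat_tokens = [t for bt in bag_tokens for t in bt]
        flat_docs = [i.doc for b in bags for i in b.instances]
        vocab = fit_vocabulary(flat_tokens, flat_docs, min_df=cfg.min_df)
        matrices = [vectorize_many(bt, vocab) for bt in bag_tokens]
        model = train_smil(matrices, [b.label for b in bags], C=cfg.C, vocab=vocab)
        model.save(out_dir / "model.json")

        stage = "score"
        scored = [
            (bag, bag_confidence(model, mat), pair_frequency(bag, len(docs)))
            for bag, mat in zip(bags, matrices)
        ]
        with open(out_dir / "scores.tsv", "w", encoding="utf-8") as fh:
            fh.write("cell\tcytokine\tconfidence\tfrequency\tds_label\n")
            for bag, conf, freq in sorted(scored, key=lambda s: s[0].pair_key):
                fh.write(
                    f"{bag.pair_key[0]}\t{bag.pair_key[1]}\t{conf:.6f}\t{freq:.6f}\t{bag.label}\n"
                )

        stage = "graph"
        kg = build_graph(scored, cfg.threshold, doc_by_pmid)
        written = export_graph(kg, out_dir, formats=cfg.export_formats)
        stats = graph_stats(kg) if len(kg) else {"n_edges": 0}
        (out_dir / "graph_stats.json").write_text(
            json.dumps(stats, indent=1, default=str), encoding="utf-8"
        )

        cv_summary = None
        if cfg.run_cv:
            stage = "cross-validate"
            cv = cross_validate(
                docs, mentions, db, k=cfg.k, seed=cfg.seed, C=cfg.C,
                min_df=cfg.min_df, window=cfg.window,
            )
            best = best_f_threshold(cv.curve_confidence)
            cv_summary = {
                "auc_confidence": cv.auc_confidence,
                "auc_frequency": cv.auc_frequency,
                "best_f": {
                    "threshold": best.threshold,
                    "precision": best.precision,
                    "recall": best.recall,
                    "f1": best.f1,
                },
            }
            (out_dir / "cv_summary.json").write_text(
                json.dumps(cv_summary, indent=1), encoding="utf-8"
            )

        stage = "manifest"
        manifest = {
            "package_version": __version__,
            "parameters": json.loads(cfg.model_dump_json()),
            "inputs": {
                name: _sha256(Path(getattr(cfg, name)))
                for name in ("corpus", "cells", "cytokines", "reference_db")
            },
            "outputs": {
                str(p.name): _sha256(p) for p in sorted(written.values())
            },
            "n_documents": len(docs),
            "n_mentions": len(mentions),
            "n_instances": len(instances),
            "n_bags": len(bags),
            "n_edges": len(kg),
            "elapsed_seconds": round(time.time() - t0, 3),
        }
        (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=1), encoding="utf-8")
    except Exception:
        (out_dir / "failed").write_text(f"stage: {stage}\n", encoding="utf-8")
        logger.exception("pipeline failed at stage %r", stage)
        raise
    return out_dir
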