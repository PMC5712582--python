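# cellkine

Mine cell–cytokine relations from biomedical abstracts and assemble them
into an evidence-backed knowledge graph.

Immunology literature states thousands of relations of the form "dendritic
cells secrete IL-12" that no curated database fully covers. `cellkine` is
for computational biologists and text-mining practitioners who want to
build or refresh such a relation inventory from abstracts without manually
annotating a single sentence. The pipeline is:

1. **Dictionary NER** — exact, case-insensitive, token-boundary-aligned
   matching of cell and cytokine lexicons (built from an OBO ontology and a
   synonym registry), with plural expansion and common-English-word
   filtering, returning character-offset mentions.
2. **Pairing** — every sentence-level co-occurrence of a (cell, cytokine)
   pair becomes an *instance*; all instances of one pair form a *bag*.
3. **Distant supervision** — a bag is labeled positive iff its pair exists
   in a reference relation database; no sentence-level labels are needed.
4. **Classification** — a sparse multi-instance SVM (sMIL) over tf-idf
   features of ±3-token lemma windows around each entity, with entity
   mentions masked by type placeholders.
5. **Graph** — pairs scoring above a confidence threshold become edges of
   an undirected bipartite graph, each carrying its supporting
   (pmid, sentence) evidence, a calibrated confidence, and a pair-frequency
   score, with export to GraphML/TSV and curation tooling (edge sampling,
   accuracy, Fleiss' κ).

## The sMIL program

Under the multi-instance assumption, every instance of a negative bag is
negative, while a positive bag only guarantees *some* positive instance.
sMIL therefore expands negative bags instance-by-instance and represents
each positive bag B by its averaged feature vector φ̄(B):

```
minimize    ½‖w‖² + C Σ ξ
subject to  w·x  + b ≤ −1 + ξ_x          for every instance x of a negative bag
            w·φ̄(B) + b ≥ (2−|B|)/|B| − ξ_B   for every positive bag B
            ξ ≥ 0
```

A singleton positive bag gets the ordinary margin 1; larger bags get a
relaxed margin approaching −1, encoding that large bags are expected to be
mostly negative inside. The quadratic program is solved exactly in the dual
by a deterministic SMO solver (per-example target margins generalize the
standard SVM dual); a confidence in [0, 1] is obtained by Platt-style
logistic calibration of the signed hyperplane distance, fitted on training
bags. The competing baseline score is the *pair frequency*: the fraction of
corpus abstracts containing a sentence-level co-occurrence of the pair.

## Worked example

No download is needed: the `cellkine.synthetic` module generates seeded
corpora with planted relations, noisy reference databases and full ground
truth. The `examples/` directory has one short script per capability.

```bash
python examples/01_dictionary_ner.py
```

```
[4, 19)  surface='dendritic cells'  canonical='dendritic cell'
-> one cell mention; the span maps the plural surface form to its concept
```

The matcher finds the plural surface form at 0-based half-open character
offsets [4, 19) and normalizes it to the singular lexicon concept.

```bash
python examples/03_cross_validation.py
```

```
AUC-PR  confidence ranking: 0.635
AUC-PR  frequency ranking:  0.491
best F1 0.682 at threshold 0.080 (P 0.876, R 0.558)
recall against planted ground truth at that threshold: 0.92
```

On the default synthetic corpus (500 abstracts, 50 planted relations, a
reference DB missing 20% of them), document-level 5-fold cross-validation
shows the classifier confidence ranking pairs better than raw co-occurrence
frequency (average precision 0.635 vs 0.491), and the best-F operating
point recovers 92% of the planted relations — including most of the ones
the reference database itself was missing.

## Command line

```bash
cellkine simulate --out-dir bundle --seed 42          # synthetic corpus bundle
cellkine annotate --corpus bundle/corpus.jsonl \
    --cells bundle/cells.tsv --cytokines bundle/cytokines.tsv \
    --out annotations.tsv
cellkine run --config pipeline.yaml                   # full pipeline -> graph
cellkine eval --corpus ... --db ... --k 5 --seed 42 --out evaldir/
cellkine curate sample --graphml run/graph.graphml --out assignment.tsv
```

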