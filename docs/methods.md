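# Methods

## Problem setting

Given a corpus of abstracts, a cell lexicon, a cytokine lexicon and a
reference database of known cell–cytokine relations, the package extracts
candidate relations stated in single sentences and scores each candidate
pair. The output is an undirected bipartite graph whose edges carry
calibrated confidences and sentence-level evidence. Training labels come
entirely from distant supervision: a pair is labeled positive when it has
an entry in the reference database, so no manually annotated sentences are
required. The cost of that convenience is label noise in both directions —
a database entry does not make every co-occurrence sentence relational, and
a missing entry does not make a pair false — which is exactly what the
multi-instance formulation and the evaluation design address.

## Dictionary NER

Matching is exact, case-insensitive, and token-boundary aligned: a match
may not be flanked by letters or digits, so the synonym `IL6` never fires
inside `IL6R`, while hyphens count as boundaries (`anti-IL-6` contains
`IL-6`). This is the strictest reproducible reading of exact dictionary
matching; it trades recall on orthographic variants for zero ambiguity.
Offsets are 0-based half-open on the raw (NFC-normalized) abstract string.
Overlapping candidate mentions are resolved longest-span-first (ties:
earlier start, then cell before cytokine), so "natural killer cell"
suppresses the embedded cytokine synonym "killer". Two lexicon curation
passes precede matching:

- **Plural expansion** adds a plural variant of every synonym mapping to
  the same canonical concept. The pluralizer is rule-based (`-is→-es`,
  `-us→-i`, consonant+`y`→`-ies`, sibilant→`-es`, else `+s`, applied to the
  final word) and treats already-plural-looking words as fixed points,
  making expansion idempotent.
- **Common-word filtering** removes single-token synonyms that are ordinary
  English words ("light", "killer"), using a bundled list of ~900
  high-frequency words (configurable). Multi-word synonyms are never
  filtered, and canonical names are kept even when common, since removing
  them would orphan the concept.

NER evaluation is at document level — (pmid, type, canonical) triples —
because reference inventories of this kind list entities per relation, not
per offset.

## Features

Each instance is represented by the lemmas of at most `window` (default 3)
tokens before and after each of the pair's two mentions, inside the
sentence. The two windows are merged positionally: a token position covered
by both windows contributes once. Tokens covered by *any* entity mention in
the sentence contribute a `CELL`/`CYTOKINE` placeholder instead of their
lemma, one per covered token position, so the classifier cannot memorize
entity identities. The lemmatizer is a light rule-based English stemmer
(plural and `-ed/-ing/-es` suffixes with an e-restoration heuristic and a
small irregular table); it is consistent within inflection families like
induce/induces/induced/inducing but, like any dictionary-free stemmer, does
not guarantee a linguistically canonical lemma for every verb. Term
weighting is tf-idf with `idf(t) = ln(n_docs/df(t)) + 1` and L2
normalization; document frequency is counted over documents (not
instances), and terms below `min_df` (default 1% of documents) are pruned.
The vocabulary and idf weights are frozen at fit time; test-fold data is
transformed with the training-fold weights.

## The sMIL classifier

Bags are corpus-level: one bag per distinct (cell, cytokine) pair. Negative
bags are expanded to per-instance constraints (margin 1 on the negative
side); each positive bag B contributes one constraint on its averaged
vector with target margin `(2−|B|)/|B|`. The resulting soft-margin program
(`½‖w‖² + C·Σξ`, default `C = 1`) is a standard SVM generalized to
per-example target margins, which may be zero or negative. It is solved in
the dual by sequential minimal optimization with maximal-violating-pair
selection, a precomputed Gram matrix, and a KKT-violation stopping
tolerance (default 1e-8; tests use down to 1e-12). The solver is fully
deterministic — no random initialization — and the dual optimum is verified
against a generic NLP solver on random small programs in the test suite.

Numerical notes:

- With all-singleton positive bags the program *is* the standard SVM;
  weights and bias agree with an independent SVM implementation to ~1e-6.
- Exact inverse scaling of `w` under feature scaling holds only when no
  slack is active at the optimum; with active slack, scaling changes the
  regularization/cost balance of the program itself.
- The bias is recovered from free support vectors (mean of their KKT
  values), falling back to the midpoint of the KKT interval.

Confidence is `σ(a·s + c)` of the raw bag score `s = w·φ̄(B) + b`, with
`(a, c)` fitted by Platt-style penalized maximum likelihood on the training
bags' own scores (`a` constrained positive, targets smoothed with Platt's
pseudo-counts so separable data yields a finite map). The mapping is
monotone, so rankings are unchanged; the [0, 1] scale exists to make
thresholds comparable across runs. The baseline score is the pair
frequency: supporting abstracts divided by corpus size.

## Evaluation

Cross-validation splits *documents* (default k = 5) by seeded shuffle, so
no abstract contributes evidence to both sides of a fold; vocabulary,
model and calibration are fitted per fold on training documents only, and
test bags are built from test documents only. Scores are pooled across
folds (per-fold averaging is possible from the per-fold records, but the
pooled curve is the default summary). Precision–recall curves place one
point per distinct score threshold (predict positive iff score ≥ t); the
area is the step-interpolated average-precision convention, verified
against an independent implementation. Best-F threshold selection breaks
ties toward the higher threshold. A split in which some training side
lacks a class is discarded with a warning and redrawn from the next seed.

## Knowledge graph

Edges are bags with confidence at or above the threshold; each edge stores
every distinct supporting (pmid, sentence). Diameter and center are
computed on the largest connected component, because literature-derived
graphs are routinely disconnected. Cross-graph novelty comparison assigns
each edge to exactly one of four categories (shared; both endpoints known
but unconnected; one endpoint new; both endpoints new) by exact canonical
string matching — near-miss synonyms across graphs are logged, never
auto-merged. Cytokine receptors remain cytokine-type nodes. The
confidence–evidence association is summarized by the Pearson correlation
between per-edge confidence and per-edge sentence count.

## Curation

A curation round samples `n_total` edges uniformly without replacement
(default 60), assigns `n_shared` (15) to all `n_curators` (3), and splits
the rest evenly, giving each curator 30 edges in the default design.
Agreement on the shared subset is Fleiss' κ with the standard per-item
agreement and pooled chance-agreement formulas (undefined when every
rating falls in one category). Graph accuracy is the accepted fraction of
distinct edges, with shared edges decided by majority verdict and ties
counted as reject. Rejection causes are recorded as free-text categories;
κ is computed on the accept/reject binary.

## Synthetic data generator

The generator is first-class, tested code that emulates the study design
at desk scale: invented entities with synonym variants (exercising
normalization and plural expansion), planted true relations with a skewed
usage distribution, and three sentence types — relational templates that
state a relation ("X secretes Y …"), noise templates that merely co-occur
a pair ("… X counts and Y titers were tabulated"), and filler. Default
conditions (20 cells × 20 cytokines, 50 relations, 500 abstracts of ~6
sentences, seed 42): 15% of sentences are relational and 45% are noise
co-occurrences drawn mostly from a 150-pair decoy pool, so that — as in
real abstracts — only a minority of sentences state a relation and most
co-occurring pairs are unrelated. The reference database withholds 20% of
the true relations (no false positives), emulating a silver standard's
false-negative rate; withheld relations are taken from the rarely-stated
tail, since automatically built databases miss sparsely reported relations
first. Under these conditions the distant-supervision classifier must
overcome contradictory training labels: withheld relations produce
relational sentences constrained to the negative side. When false
negatives are instead made frequent *and* relationally dense, the sMIL
program's trivial solution (w = 0) becomes optimal and no context signal
can be learned — the generator's defaults deliberately stay in the regime
the method is designed for.

Relational and noise templates use mostly disjoint context vocabulary, so
a linear classifier can in principle separate them; `template_overlap`
(default 0.1) appends cross-class clauses to a fraction of sentences to
keep the task from being trivially separable. Every planted relation is
guaranteed at least one relational sentence. Identical configurations
produce byte-identical corpora.

What passing on this generator does and does not show: it validates the
pipeline's mechanics (offsets, pairing, labeling, optimization, ranking,
graph assembly) and the qualitative claim that context-based confidence
out-ranks co-occurrence frequency under reference-database false
negatives. It does not demonstrate performance on real prose — real
abstracts have unbounded vocabulary, syntactic variety, negation and
hypothetical phrasing, none of which templated sentences reproduce.

## Problem sizes and runtime choices

Default test and example runs use 60–500 synthetic abstracts, giving
roughly 1 000–2 500 pair instances and dual problems of about 500–1 500
variables — sizes where the dense-Gram SMO solver converges in seconds.
The end-to-end cross-validation check runs in a few seconds on one CPU;
the whole suite in well under a minute.

## Known limitations

- Exact matching misses orthographic variants and abbreviations not in the
  lexicon; no fuzzy or context-dependent disambiguation is attempted.
- Relation direction and sentiment (up/down-regulation) are not extracted;
  edges are undirected.
- Instance-level labels are not recovered: an edge's evidence lists every
  co-occurrence sentence, not the specific sentence(s) stating the
  relation.
- The confidence scale, while calibrated to [0, 1], is fitted on
  distant-supervision labels and inherits their noise.
- `fetch_pubmed` is a thin cached convenience and is not exercised against
  the live service in tests.
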