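"""Dictionary NER on a single sentence: exact matching with plural expansion.

Builds a one-entry cell lexicon, expands plurals, and annotates the classic
example sentence. The printed offsets are 0-based half-open character
positions into the sentence: [4, 19) covers exactly "dendritic cells",
normalized back to the singular ontology concept.
"""

from cellkine.corpus import Document, segment_sentences
from cellkine.lexicon import Lexicon, expand_plurals
from cellkine.ner import annotate, resolve_overlaps

lex = expand_plurals(Lexicon("cell", {"dendritic cell": "dendritic cell"}))
doc = segment_sentences(Document("ex1", "", "The dendritic cells were safely tolerated."))

for m in resolve_overlaps(annotate(doc, lex)):
    print(f"[{m.start}, {m.end})  surface={m.surface!r}  canonical={m.canonical!r}")
print("-> one cell mention; the span maps the plural surface form to its concept")
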