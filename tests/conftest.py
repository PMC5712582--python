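import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "deterministic",
    derandomize=True,
    database=None,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("deterministic")

from cellkine.corpus import segment_sentences
from cellkine.lexicon import Lexicon, expand_plurals
from cellkine.ner import annotate, resolve_overlaps
from cellkine.synthetic import SynthConfig, generate


@pytest.fixture(scope="session")
def small_bundle():
    """A 120-document synthetic corpus, annotated and overlap-resolved."""
    cfg = SynthConfig(n_docs=120, seed=7)
    cell_lex, cyt_lex, docs, db, truth = generate(cfg)
    docs = [segment_sentences(d) for d in docs]
    cell_lex = expand_plurals(cell_lex)
    mentions = []
    for d in docs:
        mentions.extend(resolve_overlaps(annotate(d, cell_lex) + annotate(d, cyt_lex)))
    return {
        "cfg": cfg,
        "cell_lex": cell_lex,
        "cyt_lex": cyt_lex,
        "docs": docs,
        "db": db,
        "truth": truth,
        "mentions": mentions,
    }


@pytest.fixture()
def toy_cell_lexicon():
    return expand_plurals(
        Lexicon(
            "cell",
            {
                "dendritic cell": "dendritic cell",
                "natural killer cell": "natural killer cell",
                "t cell": "T cell",
            },
        )
    )


@pytest.fixture()
def toy_cytokine_lexicon():
    return Lexicon(
        "cytokine",
        {
            "il-6": "IL6",
            "il6": "IL6",
            "interleukin-6": "IL6",
            "killer": "KILR",
            "tnf": "TNF",
        },
    )
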