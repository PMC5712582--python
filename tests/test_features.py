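"""Context windows, lemmatization, vocabulary fitting, tf-idf vectors."""

import math

import numpy as np
import pytest

from cellkine.corpus import Document, segment_sentences
from cellkine.features import (
    Vocabulary,
    extract_context,
    fit_vocabulary,
    lemmatize,
    vectorize,
    vectorize_many,
)
from cellkine.lexicon import Lexicon
from cellkine.ner import annotate, resolve_overlaps
from cellkine.pairs import generate_instances

CELLS = Lexicon("cell", {"t cell": "T cell", "b cell": "B cell"})
CYTS = Lexicon("cytokine", {"il6": "IL6", "tnf": "TNF"})


def _instance(text, pmid="d1"):
    doc = segment_sentences(Document(pmid, "", text))
    mentions = resolve_overlaps(annotate(doc, CELLS) + annotate(doc, CYTS))
    instances = generate_instances(doc, mentions)
    return doc, mentions, instances


class TestLemmatizer:
    @pytest.mark.parametrize(
        "token,lemma",
        [
            ("secretes", "secrete"),
            ("induces", "induce"),
            ("induced", "induce"),
            ("inducing", "induce"),
            ("cells", "cell"),
            ("was", "be"),
            ("stimulated", "stimulate"),
            ("levels", "level"),
            ("analysis", "analysis"),
            ("Activated", "activate"),
        ],
    )
    def test_inflection_collapse(self, token, lemma):
        assert lemmatize(token) == lemma

    def test_verb_family_consistency(self):
        for a, b in [("upregulates", "upregulated"), ("induces", "inducing")]:
            assert lemmatize(a) == lemmatize(b)

    def test_unknown_tokens_pass_through_lowercased(self):
        assert lemmatize("XYZ12") == "xyz12"


class TestExtractContext:
    def test_entity_at_sentence_start_has_no_left_context(self):
        doc, mentions, instances = _instance("T cell secretes IL6 rapidly today.")
        tokens = extract_context(instances[0], doc, sentence_mentions=mentions)
        # no token precedes the cell; the two-token cell mention contributes
        # one CELL placeholder per covered position inside the cytokine window
        assert tokens.count("CELL") == 2
        assert tokens.count("CYTOKINE") == 1
        assert "secrete" in tokens and "rapidly" in tokens and "today" in tokens

    def test_third_entity_masked_by_type(self):
        doc, mentions, instances = _instance("T cell and B cell secretes IL6 today.")
        inst = next(i for i in instances if i.pair_key == ("T cell", "IL6"))
        tokens = extract_context(inst, doc, sentence_mentions=mentions)
        # the B-cell tokens inside the window appear as CELL placeholders,
        # never as their surface lemmas
        assert "b" not in tokens
        assert tokens.count("CELL") >= 1

    def test_overlapping_windows_count_positions_once(self):
        doc, mentions, instances = _instance("T cell secretes IL6.")
        tokens = extract_context(instances[0], doc, sentence_mentions=mentions)
        # positional oracle: the sentence has tokens [T, cell, secreted, IL6];
        # windows cover {secreted, IL6} (right of cell) and {T, cell, secreted}
        # (left of cytokine); the union of positions is {0,1,2,3} minus the
        # pair's own token positions handled as placeholders
        assert tokens == ["CELL", "CELL", "secrete", "CYTOKINE"]

    def test_window_truncated_at_sentence_boundary(self):
        doc, mentions, instances = _instance(
            "Background sentence first. T cell secretes IL6. Another sentence follows."
        )
        tokens = extract_context(instances[0], doc, sentence_mentions=mentions)
        assert "background" not in tokens and "another" not in tokens

    def test_window_size_limits_context(self):
        doc, mentions, instances = _instance(
            "Alpha beta gamma delta epsilon T cell secretes IL6."
        )
        tokens = extract_context(instances[0], doc, window=3, sentence_mentions=mentions)
        assert "gamma" in tokens and "delta" in tokens and "epsilon" in tokens
        assert "alpha" not in tokens and "beta" not in tokens


class TestVocabulary:
    def test_ubiquitous_token_has_unit_idf(self):
        vocab = fit_vocabulary([["a"], ["a"], ["a"]], ["d1", "d2", "d3"], min_df=0.0)
        assert vocab.idf[vocab.index["a"]] == pytest.approx(1.0)

    def test_rare_token_pruned_at_one_percent(self):
        token_lists = [["common"] for _ in range(200)]
        token_lists[0] = ["common", "rare"]
        doc_ids = [f"d{i}" for i in range(200)]
        vocab = fit_vocabulary(token_lists, doc_ids, min_df=0.01)
        assert "rare" not in vocab.terms  # 1/200 < 1%
        assert "common" in vocab.terms

    def test_zero_threshold_keeps_everything(self):
        vocab = fit_vocabulary([["a", "b"], ["c"]], ["d1", "d2"], min_df=0.0)
        assert set(vocab.terms) == {"a", "b", "c"}

    def test_df_counts_documents_not_instances(self):
        vocab = fit_vocabulary([["x"], ["x"], ["y"]], ["d1", "d1", "d2"], min_df=0.0)
        assert vocab.df[vocab.index["x"]] == 1

    def test_instance_order_does_not_change_terms(self):
        lists = [["b", "a"], ["c"], ["a"]]
        ids = ["d1", "d2", "d3"]
        v1 = fit_vocabulary(lists, ids, min_df=0.0)
        v2 = fit_vocabulary(list(reversed(lists)), list(reversed(ids)), min_df=0.0)
        assert v1.terms == v2.terms
        assert v1.idf == v2.idf

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            fit_vocabulary([], [], min_df=0.0)

    def test_save_load_round_trip(self, tmp_path):
        vocab = fit_vocabulary([["a", "b"], ["b"]], ["d1", "d2"], min_df=0.0)
        path = tmp_path / "vocab.tsv"
        vocab.save(path)
        again = Vocabulary.load(path)
        assert again.terms == vocab.terms
        assert np.allclose(again.idf, vocab.idf)


class TestVectorize:
    VOCAB = Vocabulary(
        terms=("alpha", "beta", "gamma"),
        idf=(1.0, 2.0, 3.0),
        df=(4, 2, 1),
        min_df=0.0,
        n_docs_fit=4,
    )

    def test_all_oov_gives_zero_vector(self):
        assert np.all(vectorize(["nothing", "here"], self.VOCAB) == 0)

    def test_single_token_gives_unit_vector(self):
        vec = vectorize(["beta"], self.VOCAB)
        assert np.linalg.norm(vec) == pytest.approx(1.0)
        assert vec[self.VOCAB.index["beta"]] == pytest.approx(1.0)

    def test_hand_computed_tfidf(self):
        # counts: alpha x2, gamma x1 -> raw weights (2*1, 0, 1*3) = (2, 0, 3)
        vec = vectorize(["alpha", "gamma", "alpha"], self.VOCAB)
        norm = math.sqrt(2**2 + 3**2)
        assert vec == pytest.approx(np.array([2 / norm, 0.0, 3 / norm]), abs=1e-12)

    def test_norm_is_zero_or_one(self, small_bundle):
        vocab = fit_vocabulary([["a", "b"], ["b", "c"]], ["d1", "d2"], min_df=0.0)
        for tokens in (["a"], ["a", "b", "b"], ["zz"], []):
            n = np.linalg.norm(vectorize(tokens, vocab))
            assert n == pytest.approx(0.0) or n == pytest.approx(1.0)

    def test_vectorize_many_matches_vectorize(self):
        lists = [["alpha", "beta"], ["gamma"], ["oov"]]
        mat = vectorize_many(lists, self.VOCAB)
        for r, tokens in enumerate(lists):
            assert np.allclose(np.asarray(mat[r].todense()).ravel(), vectorize(tokens, self.VOCAB))

    def test_frozen_vocabulary_ignores_new_tokens(self):
        vec = vectorize(["alpha", "delta"], self.VOCAB)
        assert len(vec) == 3  # "delta" did not grow the vocabulary
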