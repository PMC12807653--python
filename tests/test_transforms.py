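import unicodedata

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from transqc import transforms
from transqc.transforms import (
    CHAR_TRANSFORMS,
    ConfigurationError,
    TransformationSet,
    apply_char_transform,
    enumerate_transformation_sets,
    load_stopword_file,
    normalize_pair,
    remove_stopwords,
    stem,
    tokenize,
)

# text strategy: Latin letters with Spanish diacritics, digits, spaces, punctuation
TEXT = st.text(
    alphabet="abcdefghijklmnopqrstuvwxyzABCDEFGHIJKLMNOPQRSTUVWXYZáéíóúüñÁÉÍÑ0123456789 ,.;:-",
    max_size=40,
)


class TestApplyCharTransform:
    def test_diacritic_example(self):
        assert apply_char_transform("Schönlein", "diacritic") == "Schonlein"

    def test_diacritic_spanish_phrase(self):
        assert (
            apply_char_transform("Hemorrágica brasileña", "diacritic")
            == "Hemorragica brasilena"
        )

    def test_numeral_example(self):
        assert apply_char_transform("type V", "numeral") == "type 5"

    def test_numeral_preserves_embedded_letters(self):
        # "mix" is only a roman numeral when uppercased; untouched otherwise
        assert apply_char_transform("mix", "numeral") == "mix"

    def test_numeral_case_insensitive_when_cofolded(self):
        assert apply_char_transform("type v", "numeral", case_cofolded=True) == "type 5"
        assert apply_char_transform("type v", "numeral", case_cofolded=False) == "type v"

    def test_space_removal_example(self):
        assert apply_char_transform("PKD YS1", "space_removal") == "PKDYS1"

    def test_space_removal_tabs_and_newlines(self):
        assert apply_char_transform("a\tb\nc", "space_removal") == "abc"

    def test_punct_removal_example(self):
        assert apply_char_transform("46,XX sex reversal 5", "punct_removal") == (
            "46XX sex reversal 5"
        )

    def test_case_idempotent_on_lowercase(self):
        assert apply_char_transform("syndrome", "case") == "syndrome"

    def test_case_example(self):
        assert apply_char_transform("Syndrome", "case") == "syndrome"

    def test_unknown_transform_rejected(self):
        with pytest.raises(ConfigurationError):
            apply_char_transform("x", "reverse")

    @pytest.mark.parametrize("transform_id", CHAR_TRANSFORMS)
    @given(text=TEXT)
    @settings(max_examples=50, deadline=None)
    def test_idempotence(self, transform_id, text):
        text = unicodedata.normalize("NFC", text)
        once = apply_char_transform(text, transform_id)
        assert apply_char_transform(once, transform_id) == once

    @given(text=TEXT)
    @settings(max_examples=50, deadline=None)
    def test_diacritic_output_ascii_for_latin_input(self, text):
        out = apply_char_transform(unicodedata.normalize("NFC", text), "diacritic")
        assert all(ord(c) < 128 for c in out)


class TestTokenize:
    def test_punct_split_example(self):
        assert tokenize("46,XX sex reversal 5", punct_split=True) == (
            "46", "XX", "sex", "reversal", "5",
        )

    def test_empty(self):
        assert tokenize("", punct_split=True) == ()
        assert tokenize("", punct_split=False) == ()

    def test_whitespace_split(self):
        # five maximal runs of non-separator characters
        assert tokenize("fiebre del río de Ross") == (
            "fiebre", "del", "río", "de", "Ross",
        )

    def test_punctuation_kept_without_punct_split(self):
        assert tokenize("46,XX sex") == ("46,XX", "sex")


class TestStem:
    def test_english_plural(self):
        assert stem("ears", "en") == "ear"

    def test_spanish_infinitive(self):
        assert stem("inhalar", "es") == "inhal"

    def test_spanish_noun(self):
        assert stem("inhalación", "es") == "inhal"

    def test_unsupported_language(self):
        with pytest.raises(ConfigurationError):
            stem("word", "fr")

    @given(token=st.text(alphabet="abcdefghijklmnopqrstuvwxyzáéíóúñ", min_size=1, max_size=15))
    @settings(max_examples=50, deadline=None)
    @pytest.mark.parametrize("language", ["en", "es"])
    def test_deterministic(self, token, language):
        assert stem(token, language) == stem(token, language)


class TestRemoveStopwords:
    def test_spanish_example(self):
        assert remove_stopwords(["de", "la", "fiebre"], "es") == ("fiebre",)

    def test_english_all_removed(self):
        assert remove_stopwords(["to", "of", "in"], "en") == ()

    def test_empty(self):
        assert remove_stopwords([], "en") == ()

    def test_missing_list(self):
        with pytest.raises(ConfigurationError):
            remove_stopwords(["le"], "fr")

    def test_case_insensitive_membership(self):
        assert remove_stopwords(["De", "fiebre"], "es") == ("fiebre",)

    @given(tokens=st.lists(st.text(alphabet="abcdeoyl", min_size=1, max_size=5), max_size=10))
    @settings(max_examples=50, deadline=None)
    def test_subsequence_property(self, tokens):
        survivors = remove_stopwords(tokens, "es")
        it = iter(tokens)
        assert all(any(s == t for t in it) for s in survivors)  # ordered subsequence


class TestTransformationSet:
    def test_word_transforms_require_tokenization(self):
        with pytest.raises(ConfigurationError):
            TransformationSet(word_transforms=frozenset({"stemming"}), tokenized=False)

    def test_space_removal_forbidden_when_tokenized(self):
        with pytest.raises(ConfigurationError):
            TransformationSet(
                char_transforms=frozenset({"space_removal"}), tokenized=True
            )

    def test_unknown_identifier(self):
        with pytest.raises(ConfigurationError):
            TransformationSet(char_transforms=frozenset({"lowercase"}))

    def test_enumeration_size_and_admissibility(self):
        sets = enumerate_transformation_sets()
        assert len(sets) == 160
        assert len(set(sets)) == 160
        for ts in sets:
            if ts.word_transforms:
                assert ts.tokenized
            if ts.tokenized:
                assert "space_removal" not in ts.char_transforms


class TestNormalizePair:
    def test_case_only(self):
        pair = normalize_pair(
            "Ross River fever",
            "ross river fever",
            TransformationSet(char_transforms=frozenset({"case"})),
            "en",
        )
        assert pair.side_a == pair.side_b == "ross river fever"

    def test_identity(self):
        pair = normalize_pair("fiebre", "fiebre", TransformationSet(), "es")
        assert pair.side_a == pair.side_b == "fiebre"

    def test_case_stopword_tokenized_retains_contraction(self):
        # "de" is a listed stopword; the contraction "del" is not (kept as
        # content-bearing by the shipped list)
        ts = TransformationSet(
            char_transforms=frozenset({"case"}),
            word_transforms=frozenset({"stopword_removal"}),
            tokenized=True,
        )
        pair = normalize_pair("fiebre del río de Ross", "Fiebre del río Ross", ts, "es")
        assert pair.side_a == pair.side_b == ("fiebre", "del", "río", "ross")

    @given(a=TEXT, b=TEXT)
    @settings(max_examples=50, deadline=None)
    def test_swap_symmetry(self, a, b):
        ts = TransformationSet(
            char_transforms=frozenset({"case", "diacritic"}),
            word_transforms=frozenset({"stopword_removal"}),
            tokenized=True,
        )
        fwd = normalize_pair(a, b, ts, "es")
        rev = normalize_pair(b, a, ts, "es")
        assert fwd.side_a == rev.side_b and fwd.side_b == rev.side_a


def test_load_stopword_file(tmp_path):
    p = tmp_path / "sw.txt"
    p.write_text("# comment\nde\nY\n\nla\n", encoding="utf-8")
    assert load_stopword_file(str(p)) == frozenset({"de", "y", "la"})


def test_compose_normalizes_decomposed_input():
    decomposed = "rió"  # o + combining acute
    assert transforms.compose(decomposed) == "rió"
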