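import dataclasses
import random

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import oracle
from transqc.scoring import (
    DEFAULT_CONFIG,
    IncompleteUnitError,
    ScoreConfig,
    TranslationUnit,
    best_match,
    classify,
    percent_word_match,
    read_units,
    score_match,
    score_translation_unit,
    write_scored,
    write_units,
)
from transqc.transforms import TransformationSet

TOKENS = st.lists(st.text(alphabet="abcdeáé", min_size=1, max_size=4), max_size=6)

SHORT_TEXT = st.text(
    alphabet="abcdefghijklmnñopqrstuvwxyzABCDEFáéíó 0123456789,.-", max_size=25
)


class TestPercentWordMatch:
    def test_reorder_full_match(self):
        assert percent_word_match(
            ["breast", "lobular", "carcinoma"], ["lobular", "breast", "carcinoma"]
        ) == 1.0

    def test_extra_word_half_match(self):
        assert percent_word_match(["daltonismo"], ["daltonismo", "rojo"]) == 0.5

    def test_multiset_duplicates(self):
        # brute force: multiset intersection {a} has size 1, max length 2
        assert percent_word_match(["a", "a"], ["a"]) == 0.5

    def test_both_empty(self):
        assert percent_word_match([], []) == 1.0

    def test_one_empty(self):
        assert percent_word_match([], ["x"]) == 0.0

    @given(a=TOKENS, b=TOKENS)
    @settings(max_examples=100, deadline=None)
    def test_symmetric_and_matches_oracle(self, a, b):
        assert percent_word_match(a, b) == percent_word_match(b, a)
        assert percent_word_match(a, b) == pytest.approx(oracle.word_match(a, b))


class TestScoreMatch:
    def test_spanish_worked_example(self):
        assert score_match(1, True, 1, 1) == pytest.approx(0.78)

    def test_english_worked_example(self):
        assert score_match(1, False, 0, 1) == pytest.approx(0.98)

    def test_perfect(self):
        assert score_match(1, False, 0, 0) == 1.0

    def test_scaled_penalties(self):
        # 0.5 * (1 - 0.15 - 3*0.05 - 5*0.02) = 0.30
        assert score_match(0.5, True, 3, 5) == pytest.approx(0.30)

    def test_monotone_penalty(self):
        base = score_match(0.8, True, 1, 1)
        assert score_match(0.8, True, 2, 1) == pytest.approx(base - 0.8 * 0.05)
        assert score_match(0.8, True, 1, 2) == pytest.approx(base - 0.8 * 0.02)


class TestScoreConfig:
    def test_negative_weight_rejected(self):
        with pytest.raises(ValueError):
            ScoreConfig(C_wt=-0.01)

    @pytest.mark.parametrize("cutoff", [0.0, 1.0, 1.2])
    def test_cutoff_bounds(self, cutoff):
        with pytest.raises(ValueError):
            ScoreConfig(cutoff=cutoff)

    def test_total_penalty_must_stay_below_one(self):
        with pytest.raises(ValueError):
            ScoreConfig(t_penalty=0.6, W_wt=0.1, C_wt=0.02)


class TestBestMatch:
    def test_english_pair(self):
        r = best_match("Ross River fever", "ross river fever", "en")
        assert r.score == pytest.approx(0.98)
        assert r.C_n == 1 and r.W_n == 0 and not r.tokenized
        assert r.applied.char_transforms == frozenset({"case"})

    def test_spanish_pair(self):
        r = best_match("fiebre del río de Ross", "Fiebre del río Ross", "es")
        assert r.score == pytest.approx(0.78)
        assert r.tokenized and r.W_pct == 1.0
        assert r.applied.word_transforms == frozenset({"stopword_removal"})
        assert r.applied.char_transforms == frozenset({"case"})

    def test_identity(self):
        r = best_match("laringe", "laringe", "es")
        assert r.score == 1.0
        assert r.applied == TransformationSet()

    def test_empty_vs_empty(self):
        assert best_match("", "", "en").score == 1.0

    def test_empty_vs_nonempty(self):
        assert best_match("", "fever", "en").score == 0.0

    def test_single_perturbation_case_law(self):
        r = best_match("Night Fever", "night fever", "en")
        assert r.score == pytest.approx(1 - DEFAULT_CONFIG.C_wt)

    def test_single_perturbation_stopword_law(self):
        r = best_match("night of fever", "night fever", "en")
        assert r.score == pytest.approx(
            1 - DEFAULT_CONFIG.t_penalty - DEFAULT_CONFIG.W_wt
        )

    def test_engineered_two_word_transform_pair(self):
        # requires tokenization + stopword removal + stemming: 1-0.15-0.10
        r = best_match("fevers of night", "fever night", "en")
        assert r.score == pytest.approx(0.75)

    @given(a=SHORT_TEXT, b=SHORT_TEXT)
    @settings(max_examples=60, deadline=None)
    def test_symmetry_bounds_property(self, a, b):
        fwd = best_match(a, b, "es")
        rev = best_match(b, a, "es")
        assert fwd.score == pytest.approx(rev.score)
        assert 0.0 <= fwd.score <= fwd.W_pct <= 1.0


def _random_pair(rng: random.Random) -> tuple[str, str]:
    vocab = ["fiebre", "Río", "tipo", "de", "la", "noche", "aguda", "dolor", "II", "3"]
    n = rng.randint(0, 5)
    a = [rng.choice(vocab) for _ in range(n)]
    b = list(a)
    if b and rng.random() < 0.6:
        rng.shuffle(b)
    if rng.random() < 0.4:
        b.append(rng.choice(vocab))
    mk = lambda toks: " ".join(toks)
    sa, sb = mk(a), mk(b)
    if rng.random() < 0.4:
        sb = sb.lower()
    if rng.random() < 0.3:
        sa = sa.replace("i", "í", 1)
    if rng.random() < 0.3:
        sb = sb.replace("e", "e,", 1)
    return sa, sb


def test_oracle_equivalence_random_pairs():
    """The search must equal a naive independent enumeration on 200 pairs."""
    rng = random.Random(42)
    for _ in range(200):
        a, b = _random_pair(rng)
        assert best_match(a, b, "es").score == pytest.approx(
            oracle.best_score(a, b, "es")
        ), (a, b)


class TestClassify:
    def test_passed(self):
        assert classify(0.88) == "passed"

    def test_exact(self):
        assert classify(1.0) == "exact"

    def test_at_cutoff_is_pending(self):
        assert classify(0.75) == "pending"

    def test_below_cutoff(self):
        assert classify(0.2) == "pending"

    def test_custom_cutoff(self):
        assert classify(0.7, ScoreConfig(cutoff=0.65)) == "passed"


class TestScoreTranslationUnit:
    def test_worked_example(self, worked_unit):
        ct = score_translation_unit(worked_unit)
        assert ct.en_result.score == pytest.approx(0.98)
        assert ct.es_result.score == pytest.approx(0.78)
        assert ct.final_score == pytest.approx(0.88)
        assert ct.category == "passed"

    def test_exact_unit(self):
        unit = TranslationUnit(
            "DOID:1", "label", "en", "night fever", "es",
            "fiebre nocturna", "fiebre nocturna", "night fever",
        )
        ct = score_translation_unit(unit)
        assert ct.final_score == 1.0
        assert ct.category == "exact"

    def test_engineered_pending_at_cutoff(self):
        # each pair needs tokenization + two word transforms: 0.75 per pair,
        # final 0.75 <= cutoff -> pending ("at or below" rule)
        unit = TranslationUnit(
            "DOID:2", "label", "en", "fevers of night", "es",
            "fiebres de noche", "fiebre noche", "fever night",
        )
        ct = score_translation_unit(unit)
        assert ct.final_score == pytest.approx(0.75)
        assert ct.category == "pending"

    @pytest.mark.parametrize(
        "missing",
        ["source_text", "professional_text", "machine_forward_text", "machine_back_text"],
    )
    def test_missing_text_names_field(self, worked_unit, missing):
        broken = dataclasses.replace(worked_unit, **{missing: ""})
        with pytest.raises(IncompleteUnitError, match=missing):
            score_translation_unit(broken)


def test_unit_tsv_round_trip(tmp_path, worked_unit):
    path = str(tmp_path / "units.tsv")
    write_units([worked_unit], path)
    assert read_units(path) == [worked_unit]


def test_scored_tsv_columns(tmp_path, worked_unit):
    ct = score_translation_unit(worked_unit)
    path = str(tmp_path / "scored.tsv")
    write_scored([(worked_unit, ct)], path)
    lines = open(path, encoding="utf-8").read().splitlines()
    header = lines[0].split("\t")
    row = dict(zip(header, lines[1].split("\t")))
    assert row["final_score"] == "0.88"
    assert row["category"] == "passed"
    assert "case" in row["en_transforms"]
    assert "stopword_removal" in row["es_transforms"]
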