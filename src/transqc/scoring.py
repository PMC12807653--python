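"""Penalized similarity scoring for bilingual translation pairs.

Every admissible transformation combination is applied to a language pair;
each combination yields a fraction of matching words ``W_pct`` and a score

    score = W_pct - W_pct * (t*[tokenized] + W_n*W_wt + C_n*C_wt)

where ``W_n``/``C_n`` count the word/character transform *types* applied and
``t`` is a flat penalty for moving from whole-string to word-level
comparison.  The best (maximum-score) combination is kept per pair; a
translation unit is scored on two pairs — source text vs machine
backtranslation, and professional vs machine forward translation — and the
two best scores are averaged and classified against a cutoff.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Sequence

from . import _tsv, transforms
from .transforms import (
    DEFAULT_STOPWORDS,
    IDENTITY,
    TransformationSet,
    enumerate_transformation_sets,
    normalize_pair,
)

CATEGORY_EXACT = "exact"
CATEGORY_PASSED = "passed"
CATEGORY_PENDING = "pending"


class IncompleteUnitError(ValueError):
    """A translation unit is missing one of its four required texts."""


@dataclass(frozen=True)
class ScoreConfig:
    """Penalty weights, classification cutoff, and language resources."""

    C_wt: float = 0.02
    W_wt: float = 0.05
    t_penalty: float = 0.15
    cutoff: float = 0.75
    stopwords: dict[str, frozenset[str]] = field(
        default_factory=lambda: dict(DEFAULT_STOPWORDS)
    )
    enabled_transforms: frozenset[str] = frozenset(
        transforms.CHAR_TRANSFORMS + transforms.WORD_TRANSFORMS
    )

    def __post_init__(self) -> None:
        if min(self.C_wt, self.W_wt, self.t_penalty) < 0:
            raise ValueError("penalty weights must be non-negative")
        if not 0 < self.cutoff < 1:
            raise ValueError("cutoff must lie strictly between 0 and 1")
        max_penalty = (
            self.t_penalty
            + len(transforms.WORD_TRANSFORMS) * self.W_wt
            + len(transforms.CHAR_TRANSFORMS) * self.C_wt
        )
        if max_penalty >= 1:
            raise ValueError(
                "maximum total penalty must stay below 1 "
                f"(got {max_penalty:.3f}); scores would not remain non-negative"
            )


DEFAULT_CONFIG = ScoreConfig()


@dataclass(frozen=True)
class TranslationUnit:
    """One ontology text element with its four texts."""

    subject_id: str
    predicate_id: str
    source_lang: str
    source_text: str
    translation_lang: str
    professional_text: str
    machine_forward_text: str
    machine_back_text: str


@dataclass(frozen=True)
class MatchResult:
    """Outcome of the best-transformation search on one text pair."""

    W_pct: float
    tokenized: bool
    W_n: int
    C_n: int
    score: float
    applied: TransformationSet


@dataclass(frozen=True)
class ClassifiedTranslation:
    subject_id: str
    predicate_id: str
    en_result: MatchResult
    es_result: MatchResult
    final_score: float
    category: str


def percent_word_match(tokens_a: Sequence[str], tokens_b: Sequence[str]) -> float:
    """Order-insensitive multiset word overlap over the larger token count.

    Two empty sequences match perfectly (1.0); the measure is symmetric.
    """
    if not tokens_a and not tokens_b:
        return 1.0
    counts_a, counts_b = Counter(tokens_a), Counter(tokens_b)
    overlap = sum((counts_a & counts_b).values())
    return overlap / max(len(tokens_a), len(tokens_b))


def score_match(
    W_pct: float,
    tokenized: bool,
    W_n: int,
    C_n: int,
    config: ScoreConfig = DEFAULT_CONFIG,
) -> float:
    """Evaluate the penalized score equation for one transformed comparison."""
    penalty = (
        (config.t_penalty if tokenized else 0.0)
        + W_n * config.W_wt
        + C_n * config.C_wt
    )
    return W_pct - W_pct * penalty


def _evaluate(
    text_a: str,
    text_b: str,
    ts: TransformationSet,
    language: str,
    config: ScoreConfig,
) -> MatchResult:
    pair = normalize_pair(text_a, text_b, ts, language, config.stopwords)
    if ts.tokenized:
        w_pct = percent_word_match(pair.side_a, pair.side_b)  # type: ignore[arg-type]
    else:
        w_pct = 1.0 if pair.side_a == pair.side_b else 0.0
    score = score_match(w_pct, ts.tokenized, ts.n_word, ts.n_char, config)
    return MatchResult(
        W_pct=w_pct,
        tokenized=ts.tokenized,
        W_n=ts.n_word,
        C_n=ts.n_char,
        score=score,
        applied=ts,
    )


def _preference_key(r: MatchResult) -> tuple:
    # Maximize score; break ties toward fewer total transforms, then fewer
    # word transforms, then lexicographically earliest identifier tuple.
    total = r.C_n + r.W_n + (1 if r.tokenized else 0)
    return (-r.score, total, r.W_n, r.applied.identifiers())


def best_match(
    text_a: str,
    text_b: str,
    language: str,
    config: ScoreConfig = DEFAULT_CONFIG,
) -> MatchResult:
    """Exhaustively search transformation combinations; return the best result."""
    results = [
        _evaluate(text_a, text_b, ts, language, config)
        for ts in enumerate_transformation_sets(config.enabled_transforms)
    ]
    return min(results, key=_preference_key)


def classify(final_score: float, config: ScoreConfig = DEFAULT_CONFIG) -> str:
    """exact iff the score is 1; passed above the cutoff; pending at or below."""
    if final_score >= 1.0:
        return CATEGORY_EXACT
    if final_score > config.cutoff:
        return CATEGORY_PASSED
    return CATEGORY_PENDING


def score_translation_unit(
    unit: TranslationUnit, config: ScoreConfig = DEFAULT_CONFIG
) -> ClassifiedTranslation:
    """Score both language pairs of a unit, average, and classify.

    The source-language pair compares the original text with the machine
    backtranslation; the target-language pair compares the professional and
    machine forward translations.
    """
    for field_name in (
        "source_text",
        "professional_text",
        "machine_forward_text",
        "machine_back_text",
    ):
        if getattr(unit, field_name) is None or getattr(unit, field_name) == "":
            raise IncompleteUnitError(
                f"unit {unit.subject_id}/{unit.predicate_id}: missing {field_name}"
            )
    en_result = best_match(
        unit.source_text, unit.machine_back_text, unit.source_lang, config
    )
    es_result = best_match(
        unit.professional_text, unit.machine_forward_text, unit.translation_lang, config
    )
    final_score = (en_result.score + es_result.score) / 2.0
    return ClassifiedTranslation(
        subject_id=unit.subject_id,
        predicate_id=unit.predicate_id,
        en_result=en_result,
        es_result=es_result,
        final_score=final_score,
        category=classify(final_score, config),
    )


def score_units(
    units: Iterable[TranslationUnit], config: ScoreConfig = DEFAULT_CONFIG
) -> list[ClassifiedTranslation]:
    return [score_translation_unit(u, config) for u in units]


# --- unit table I/O --------------------------------------------------------

UNIT_COLUMNS = (
    "subject_id",
    "predicate_id",
    "source_lang",
    "source_text",
    "translation_lang",
    "professional_text",
    "machine_forward_text",
    "machine_back_text",
)

SCORED_COLUMNS = UNIT_COLUMNS + (
    "en_score",
    "es_score",
    "final_score",
    "category",
    "en_transforms",
    "es_transforms",
)


def _unit_row(u: TranslationUnit) -> list[str]:
    return [getattr(u, c) for c in UNIT_COLUMNS]


def read_units(path: str) -> list[TranslationUnit]:
    _, rows = _tsv.read_rows(path, required_columns=UNIT_COLUMNS)
    return [TranslationUnit(**{c: row[c] for c in UNIT_COLUMNS}) for row in rows]


def write_units(units: Iterable[TranslationUnit], path: str) -> None:
    _tsv.write_rows(path, UNIT_COLUMNS, [_unit_row(u) for u in units])


def write_scored(
    pairs: Iterable[tuple[TranslationUnit, ClassifiedTranslation]], path: str
) -> None:
    """Write the scored table: unit columns plus scores, category and the
    semicolon-joined transform identifiers of each best match."""
    rows = []
    for unit, ct in pairs:
        rows.append(
            _unit_row(unit)
            + [
                f"{ct.en_result.score:.2f}",
                f"{ct.es_result.score:.2f}",
                f"{ct.final_score:.2f}",
                ct.category,
                ";".join(ct.en_result.applied.identifiers()),
                ";".join(ct.es_result.applied.identifiers()),
            ]
        )
    _tsv.write_rows(path, SCORED_COLUMNS, rows)
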