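"""Text transformations used for bilingual pair comparison.

Two families of transformations are supported:

* character-level: case folding, roman/arabic numeral standardization,
  diacritic stripping, whitespace removal and punctuation removal;
* word-level (require tokenization): stemming, stopword removal, and
  punctuation word-splitting.

A :class:`TransformationSet` names a combination of these; applying it to
both members of a text pair yields a :class:`NormalizedPair`.  Application
order is canonical and fixed: tokenization first (when enabled), then
character transforms per token in the order case -> diacritic -> numeral ->
punct_removal -> space_removal, then stopword removal, then stemming.
"""

from __future__ import annotations

import re
import unicodedata
from dataclasses import dataclass, field
from typing import Iterable, Sequence

from ._snowball import EnglishStemmer, SpanishStemmer

CHAR_TRANSFORMS = ("case", "numeral", "diacritic", "space_removal", "punct_removal")
WORD_TRANSFORMS = ("stemming", "stopword_removal", "punct_split")

# Character transform application order within a token / whole string.
_CHAR_ORDER = ("case", "diacritic", "numeral", "punct_removal", "space_removal")

#: Built-in stopword lists. The published examples name only a few words per
#: language; these lists extend them with the high-frequency function words of
#: each language. "del"/"al" (Spanish contractions) are deliberately kept OUT
#: of the default list so that they survive as content-bearing tokens; both
#: lists are replaceable through ScoreConfig / stopword files.
DEFAULT_STOPWORDS: dict[str, frozenset[str]] = {
    "en": frozenset(
        {"to", "in", "of", "the", "a", "an", "and", "or", "for", "with", "by"}
    ),
    "es": frozenset(
        {"de", "y", "la", "el", "los", "las", "un", "una", "en", "o", "con", "por", "para"}
    ),
}

_PUNCT_RE = re.compile(r"[^\w\s]|_", re.UNICODE)
_WS_RE = re.compile(r"\s+")
_ROMAN_RE = re.compile(
    r"^M{0,3}(CM|CD|D?C{0,3})(XC|XL|L?X{0,3})(IX|IV|V?I{0,3})$"
)
_ROMAN_VALUES = {"I": 1, "V": 5, "X": 10, "L": 50, "C": 100, "D": 500, "M": 1000}

_STEMMERS = {"en": EnglishStemmer, "es": SpanishStemmer}


class ConfigurationError(ValueError):
    """Unknown transform identifier, language, or missing language resource."""


@dataclass(frozen=True)
class TransformationSet:
    """A combination of transformations applied identically to both texts."""

    char_transforms: frozenset[str] = frozenset()
    word_transforms: frozenset[str] = frozenset()
    tokenized: bool = False

    def __post_init__(self) -> None:
        unknown = set(self.char_transforms) - set(CHAR_TRANSFORMS)
        if unknown:
            raise ConfigurationError(f"unknown character transform(s): {sorted(unknown)}")
        unknown = set(self.word_transforms) - set(WORD_TRANSFORMS)
        if unknown:
            raise ConfigurationError(f"unknown word transform(s): {sorted(unknown)}")
        if self.word_transforms and not self.tokenized:
            raise ConfigurationError("word transforms require tokenized=True")
        if self.tokenized and "space_removal" in self.char_transforms:
            raise ConfigurationError("space_removal is incompatible with tokenization")

    @property
    def n_char(self) -> int:
        return len(self.char_transforms)

    @property
    def n_word(self) -> int:
        return len(self.word_transforms)

    def identifiers(self) -> tuple[str, ...]:
        """Stable, sorted identifier tuple (tokenization included) for provenance."""
        ids = sorted(self.char_transforms) + sorted(self.word_transforms)
        if self.tokenized:
            ids.append("tokenization")
        return tuple(sorted(ids))


#: The empty set: raw comparison of whole strings.
IDENTITY = TransformationSet()


@dataclass(frozen=True)
class NormalizedPair:
    """Both sides of a text pair after applying the same TransformationSet."""

    side_a: str | tuple[str, ...]
    side_b: str | tuple[str, ...]
    language: str
    applied: TransformationSet


def compose(text: str) -> str:
    """Canonical Unicode composition (NFC), applied to all text on ingest."""
    return unicodedata.normalize("NFC", text)


def _strip_diacritics(text: str) -> str:
    decomposed = unicodedata.normalize("NFD", text)
    return unicodedata.normalize(
        "NFC", "".join(c for c in decomposed if not unicodedata.combining(c))
    )


def _roman_to_int(token: str) -> int:
    total = 0
    prev = 0
    for ch in reversed(token):
        value = _ROMAN_VALUES[ch]
        total += value if value >= prev else -value
        prev = max(prev, value)
    return total


def _standardize_numeral_token(token: str, case_insensitive: bool) -> str:
    candidate = token.upper() if case_insensitive else token
    if candidate and _ROMAN_RE.match(candidate):
        return str(_roman_to_int(candidate))
    return token


def _apply_numeral(text: str, case_insensitive: bool) -> str:
    # Only whole runs of letters bounded by non-letters are eligible, so words
    # like "mix" embedded in larger tokens are never touched accidentally;
    # the run itself must be a valid canonical roman numeral.
    def repl(m: re.Match[str]) -> str:
        return _standardize_numeral_token(m.group(0), case_insensitive)

    return re.sub(r"[A-Za-z]+", repl, text)


def apply_char_transform(text: str, transform_id: str, *, case_cofolded: bool = False) -> str:
    """Apply one character-level transform to ``text``.

    ``case_cofolded`` signals that case standardization is co-applied in the
    same TransformationSet; numeral standardization then matches roman
    numerals case-insensitively.
    """
    if transform_id == "case":
        return text.lower()
    if transform_id == "diacritic":
        return _strip_diacritics(text)
    if transform_id == "numeral":
        return _apply_numeral(text, case_insensitive=case_cofolded)
    if transform_id == "space_removal":
        return _WS_RE.sub("", text)
    if transform_id == "punct_removal":
        return _PUNCT_RE.sub("", text)
    raise ConfigurationError(f"unknown character transform: {transform_id!r}")


def tokenize(text: str, punct_split: bool = False) -> tuple[str, ...]:
    """Split into maximal runs of non-separator characters.

    Separators are whitespace; punctuation also separates when ``punct_split``
    is true, e.g. ``"46,XX sex reversal 5"`` -> ``46 / XX / sex / reversal / 5``.
    """
    if punct_split:
        parts = re.split(r"[\s]+|" + _PUNCT_RE.pattern, text)
    else:
        parts = _WS_RE.split(text)
    return tuple(p for p in parts if p)


def stem(token: str, language: str) -> str:
    """Stem one token with the Snowball algorithm for ``language`` (en/es)."""
    try:
        stemmer_cls = _STEMMERS[language]
    except KeyError:
        raise ConfigurationError(f"no stemmer configured for language {language!r}") from None
    return stemmer_cls().stemWord(token)


class _StemmerCache:
    """Reusable stemmer instances plus a token->stem memo per language.

    The exhaustive search re-stems the same short tokens across many
    transformation combinations; memoization keeps that linear in distinct
    tokens. The memo is capped to bound memory on adversarial input streams.
    """

    _MAX_MEMO = 200_000

    def __init__(self) -> None:
        self._instances: dict[str, EnglishStemmer | SpanishStemmer] = {}
        self._memo: dict[tuple[str, str], str] = {}

    def stem(self, token: str, language: str) -> str:
        key = (language, token)
        cached = self._memo.get(key)
        if cached is not None:
            return cached
        inst = self._instances.get(language)
        if inst is None:
            try:
                inst = _STEMMERS[language]()
            except KeyError:
                raise ConfigurationError(
                    f"no stemmer configured for language {language!r}"
                ) from None
            self._instances[language] = inst
        stemmed = inst.stemWord(token)
        if len(self._memo) >= self._MAX_MEMO:
            self._memo.clear()
        self._memo[key] = stemmed
        return stemmed


_stemmer_cache = _StemmerCache()


def remove_stopwords(
    tokens: Iterable[str],
    language: str,
    stopwords: dict[str, frozenset[str]] | None = None,
) -> tuple[str, ...]:
    """Drop listed stopwords, preserving the order of surviving tokens.

    Matching is case-insensitive against the configured list so that stopword
    removal composes with or without case standardization.
    """
    lists = stopwords if stopwords is not None else DEFAULT_STOPWORDS
    try:
        listed = lists[language]
    except KeyError:
        raise ConfigurationError(f"no stopword list for language {language!r}") from None
    return tuple(t for t in tokens if t.lower() not in listed)


def load_stopword_file(path: str) -> frozenset[str]:
    """Read a stopword file: UTF-8, one token per line, '#' lines ignored."""
    words: set[str] = set()
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            line = line.strip()
            if line and not line.startswith("#"):
                words.add(line.lower())
    return frozenset(words)


def _apply_char_transforms(text: str, ts: TransformationSet) -> str:
    case_cofolded = "case" in ts.char_transforms
    for tid in _CHAR_ORDER:
        if tid in ts.char_transforms:
            text = apply_char_transform(text, tid, case_cofolded=case_cofolded)
    return text


def _normalize_one(
    text: str,
    ts: TransformationSet,
    language: str,
    stopwords: dict[str, frozenset[str]] | None,
) -> str | tuple[str, ...]:
    text = compose(text)
    if not ts.tokenized:
        return _apply_char_transforms(text, ts)
    tokens: Sequence[str] = tokenize(text, punct_split="punct_split" in ts.word_transforms)
    tokens = [_apply_char_transforms(t, ts) for t in tokens]
    tokens = [t for t in tokens if t]  # punct_removal may empty a token
    if "stopword_removal" in ts.word_transforms:
        tokens = remove_stopwords(tokens, language, stopwords)
    if "stemming" in ts.word_transforms:
        tokens = [_stemmer_cache.stem(t, language) for t in tokens]
    return tuple(tokens)


def normalize_pair(
    text_a: str,
    text_b: str,
    ts: TransformationSet,
    language: str = "en",
    stopwords: dict[str, frozenset[str]] | None = None,
) -> NormalizedPair:
    """Apply ``ts`` identically to both texts of a language pair."""
    return NormalizedPair(
        side_a=_normalize_one(text_a, ts, language, stopwords),
        side_b=_normalize_one(text_b, ts, language, stopwords),
        language=language,
        applied=ts,
    )


def enumerate_transformation_sets(
    enabled: Iterable[str] | None = None,
) -> list[TransformationSet]:
    """Every admissible TransformationSet over the enabled transform identifiers.

    Untokenized sets draw character transforms only; tokenized sets add word
    transforms but exclude space_removal (tokenization already erases
    separators). With everything enabled this yields 160 combinations.
    """
    enabled_set = set(enabled) if enabled is not None else set(CHAR_TRANSFORMS + WORD_TRANSFORMS)
    chars = [t for t in CHAR_TRANSFORMS if t in enabled_set]
    words = [t for t in WORD_TRANSFORMS if t in enabled_set]

    def subsets(items: list[str]) -> list[frozenset[str]]:
        out = [frozenset()]
        for item in items:
            out += [s | {item} for s in out]
        return out

    sets: list[TransformationSet] = []
    for cs in subsets(chars):
        sets.append(TransformationSet(char_transforms=cs))
    tok_chars = [t for t in chars if t != "space_removal"]
    for cs in subsets(tok_chars):
        for ws in subsets(words):
            sets.append(
                TransformationSet(char_transforms=cs, word_transforms=ws, tokenized=True)
            )
    return sets
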