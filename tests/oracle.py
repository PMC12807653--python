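"""Independent brute-force reference for the transformation-search score.

This module deliberately re-implements normalization and scoring with
different mechanics (greedy roman-numeral table, explicit punctuation set,
two-pointer multiset overlap, itertools powersets) so the package's search
can be checked against an implementation that shares no code path with it
beyond the published Snowball stemming algorithm.

Only used by tests.
"""

from __future__ import annotations

import itertools
import re
import unicodedata

from transqc._snowball import EnglishStemmer, SpanishStemmer

EN_STOP = {"to", "in", "of", "the", "a", "an", "and", "or", "for", "with", "by"}
ES_STOP = {"de", "y", "la", "el", "los", "las", "un", "una", "en", "o", "con", "por", "para"}

# Punctuation alphabet used by the oracle-equivalence pair generator; the
# oracle only needs to agree with the implementation on this set.
PUNCT_CHARS = set(",.;:()-'!?")

_ROMAN_PARTS = [
    (1000, "M"), (900, "CM"), (500, "D"), (400, "CD"),
    (100, "C"), (90, "XC"), (50, "L"), (40, "XL"),
    (10, "X"), (9, "IX"), (5, "V"), (4, "IV"), (1, "I"),
]


def _int_to_roman(n: int) -> str:
    out = []
    for value, sym in _ROMAN_PARTS:
        while n >= value:
            out.append(sym)
            n -= value
    return "".join(out)


ROMAN_TO_INT = {_int_to_roman(n): n for n in range(1, 4000)}


def strip_marks(s: str) -> str:
    return unicodedata.normalize(
        "NFC",
        "".join(c for c in unicodedata.normalize("NFD", s) if unicodedata.category(c) != "Mn"),
    )


def numeral(s: str, case_insensitive: bool) -> str:
    def rep(m: re.Match[str]) -> str:
        word = m.group(0)
        key = word.upper() if case_insensitive else word
        return str(ROMAN_TO_INT[key]) if key in ROMAN_TO_INT else word

    return re.sub(r"[A-Za-z]+", rep, s)


def drop_punct(s: str) -> str:
    return "".join(c for c in s if c not in PUNCT_CHARS)


def char_apply(s: str, combo: set[str]) -> str:
    if "case" in combo:
        s = s.lower()
    if "diacritic" in combo:
        s = strip_marks(s)
    if "numeral" in combo:
        s = numeral(s, case_insensitive="case" in combo)
    if "punct_removal" in combo:
        s = drop_punct(s)
    if "space_removal" in combo:
        s = "".join(c for c in s if not c.isspace())
    return s


def word_match(a: list[str], b: list[str]) -> float:
    if not a and not b:
        return 1.0
    sa, sb = sorted(a), sorted(b)
    i = j = overlap = 0
    while i < len(sa) and j < len(sb):
        if sa[i] == sb[j]:
            overlap += 1
            i += 1
            j += 1
        elif sa[i] < sb[j]:
            i += 1
        else:
            j += 1
    return overlap / max(len(a), len(b))


_stemmers = {"en": EnglishStemmer(), "es": SpanishStemmer()}


def _powerset(items):
    for r in range(len(items) + 1):
        yield from (set(c) for c in itertools.combinations(items, r))


def best_score(
    text_a: str,
    text_b: str,
    language: str,
    c_wt: float = 0.02,
    w_wt: float = 0.05,
    t: float = 0.15,
) -> float:
    """Maximum penalized score over all admissible transformation combos."""
    text_a = unicodedata.normalize("NFC", text_a)
    text_b = unicodedata.normalize("NFC", text_b)
    stop = EN_STOP if language == "en" else ES_STOP
    stemmer = _stemmers[language]
    best = 0.0

    for chars in _powerset(["case", "numeral", "diacritic", "space_removal", "punct_removal"]):
        w_pct = 1.0 if char_apply(text_a, chars) == char_apply(text_b, chars) else 0.0
        best = max(best, w_pct - w_pct * len(chars) * c_wt)

    for chars in _powerset(["case", "numeral", "diacritic", "punct_removal"]):
        for words in _powerset(["stemming", "stopword_removal", "punct_split"]):
            sides = []
            for text in (text_a, text_b):
                if "punct_split" in words:
                    spaced = "".join(" " if c in PUNCT_CHARS else c for c in text)
                else:
                    spaced = text
                tokens = [char_apply(tok, chars) for tok in spaced.split()]
                tokens = [tok for tok in tokens if tok]
                if "stopword_removal" in words:
                    tokens = [tok for tok in tokens if tok.lower() not in stop]
                if "stemming" in words:
                    tokens = [stemmer.stemWord(tok) for tok in tokens]
                sides.append(tokens)
            w_pct = word_match(sides[0], sides[1])
            penalty = t + len(words) * w_wt + len(chars) * c_wt
            best = max(best, w_pct - w_pct * penalty)
    return best
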