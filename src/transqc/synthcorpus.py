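"""Synthetic bilingual translation units with controlled perturbations.

Generates disease-like term pairs from a tiny built-in bijective
English/Spanish lexicon, then perturbs them with the error classes the
scorer is designed to absorb (case, diacritics, stopwords, word order,
numeral style, punctuation, whitespace) plus meaning-changing word
substitutions that it is designed to flag.  Backtranslation is modeled as a
deterministic token-level back-mapping through the lexicon, so the whole
pipeline is exercisable offline with known ground truth.

The lexicon is deliberately small and word-for-word; linguistic realism is
a non-goal — the corpus exists to exercise the score's algebra and the
pipeline's plumbing.
"""

from __future__ import annotations

import random
import unicodedata
from dataclasses import dataclass, replace

from .scoring import TranslationUnit
from .transforms import DEFAULT_STOPWORDS

# --- built-in bijective lexicon (en -> es); values are unique -------------

LEXICON_EN_ES: dict[str, str] = {
    # anatomy
    "kidney": "riñón",
    "liver": "hígado",
    "heart": "corazón",
    "lung": "pulmón",
    "brain": "cerebro",
    "bone": "hueso",
    "skin": "piel",
    "blood": "sangre",
    "muscle": "músculo",
    "nerve": "nervio",
    "eye": "ojo",
    "ear": "oreja",
    "stomach": "estómago",
    "colon": "colon",
    "spleen": "bazo",
    "thyroid": "tiroides",
    "pancreas": "páncreas",
    "bladder": "vejiga",
    "joint": "articulación",
    "artery": "arteria",
    "vein": "vena",
    "tendon": "tendón",
    "retina": "retina",
    "cornea": "córnea",
    "larynx": "laringe",
    # disorders
    "fibrosis": "fibrosis",
    "carcinoma": "carcinoma",
    "syndrome": "síndrome",
    "disease": "enfermedad",
    "fever": "fiebre",
    "atrophy": "atrofia",
    "dystrophy": "distrofia",
    "deficiency": "deficiencia",
    "infection": "infección",
    "inflammation": "inflamación",
    "sclerosis": "esclerosis",
    "stenosis": "estenosis",
    "necrosis": "necrosis",
    "lymphoma": "linfoma",
    "sarcoma": "sarcoma",
    "anemia": "anemia",
    "edema": "edema",
    "lesion": "lesión",
    "tumor": "tumor",
    "cyst": "quiste",
    "ulcer": "úlcera",
    "palsy": "parálisis",
    "rupture": "ruptura",
    "obstruction": "obstrucción",
    "malformation": "malformación",
    # modifiers
    "chronic": "crónica",
    "acute": "aguda",
    "congenital": "congénita",
    "hereditary": "hereditaria",
    "juvenile": "juvenil",
    "adult": "adulta",
    "severe": "grave",
    "benign": "benigna",
    "malignant": "maligna",
    "primary": "primaria",
    "secondary": "secundaria",
    "recessive": "recesiva",
    "dominant": "dominante",
    "familial": "familiar",
    "idiopathic": "idiopática",
    "infantile": "infantil",
    "progressive": "progresiva",
    "recurrent": "recurrente",
    "systemic": "sistémica",
    "autoimmune": "autoinmune",
    # structural words
    "type": "tipo",
    "syndrome-like": "sindrómica",
    # function words (needed so inserted stopwords back-map to stopwords)
    "of": "de",
    "the": "el",
    "and": "y",
    "in": "en",
    "with": "con",
    "for": "para",
    "by": "por",
    "or": "o",
    "a": "una",
    "to": "al",
}

LEXICON_ES_EN: dict[str, str] = {v: k for k, v in LEXICON_EN_ES.items()}
assert len(LEXICON_ES_EN) == len(LEXICON_EN_ES), "lexicon must be bijective"

_ANATOMY_WORDS = list(LEXICON_EN_ES)[:25]
_DISORDER_WORDS = list(LEXICON_EN_ES)[25:50]
_MODIFIER_WORDS = list(LEXICON_EN_ES)[50:70]

_STOPWORD_POOL = {
    "en": ("of", "the", "in", "with", "and"),
    "es": ("de", "el", "en", "con", "y"),
}

_ROMAN = ["I", "II", "III", "IV", "V", "VI", "VII", "VIII", "IX", "X"]

PERTURBATION_CLASSES = (
    "case_flip",
    "diacritic",
    "stopword",
    "reorder",
    "numeral_style",
    "punctuation",
    "whitespace",
    "substitution",
)


@dataclass(frozen=True)
class PerturbationProfile:
    """Independent application probability for each perturbation class."""

    case_flip: float = 0.0
    diacritic: float = 0.0
    stopword: float = 0.0
    reorder: float = 0.0
    numeral_style: float = 0.0
    punctuation: float = 0.0
    whitespace: float = 0.0
    substitution: float = 0.0

    def __post_init__(self) -> None:
        for name in PERTURBATION_CLASSES:
            p = getattr(self, name)
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"probability {name} must be in [0,1], got {p}")

    def without_substitution(self) -> "PerturbationProfile":
        return replace(self, substitution=0.0)


#: Default profiles used by the CLI and acceptance runs: faithful units carry
#: only scorer-recoverable noise; unfaithful units additionally always carry a
#: meaning-changing substitution.
FAITHFUL_PROFILE = PerturbationProfile(
    case_flip=0.3,
    diacritic=0.3,
    stopword=0.3,
    reorder=0.3,
    numeral_style=0.3,
    punctuation=0.3,
    whitespace=0.15,
    substitution=0.0,
)
UNFAITHFUL_PROFILE = replace(FAITHFUL_PROFILE, substitution=1.0)


@dataclass(frozen=True)
class SyntheticUnit:
    unit: TranslationUnit
    label: str  # faithful | unfaithful
    perturbation_log: tuple[str, ...]


def generate_term(rng: random.Random) -> tuple[str, str]:
    """Draw a bilingual (English source, Spanish reference) term pair.

    Grammar: [modifier] anatomy disorder ["type" N]; the Spanish reference is
    the word-by-word lexicon image, so back-mapping recovers the source.
    """
    tokens = []
    if rng.random() < 0.5:
        tokens.append(rng.choice(_MODIFIER_WORDS))
    tokens.append(rng.choice(_ANATOMY_WORDS))
    tokens.append(rng.choice(_DISORDER_WORDS))
    if rng.random() < 0.4:
        tokens += ["type", str(rng.randint(1, 10))]
    source = " ".join(tokens)
    reference = " ".join(LEXICON_EN_ES.get(t, t) for t in tokens)
    return source, reference


def _lookup_key(token: str) -> str:
    """Surface-noise-insensitive lexicon key: lower-cased, diacritic- and
    punctuation-stripped, mimicking a translation service's robustness."""
    decomposed = unicodedata.normalize("NFD", token.lower())
    return "".join(c for c in decomposed if c.isalnum())


_LOOKUP_ES_EN: dict[str, str] = {_lookup_key(k): v for k, v in LEXICON_ES_EN.items()}
assert len(_LOOKUP_ES_EN) == len(LEXICON_ES_EN), "normalized es keys must stay unique"


def back_map(text_es: str) -> str:
    """Deterministic token-level backtranslation through the lexicon.

    Lookup ignores case, diacritics and attached punctuation (a translation
    service is robust to such noise); matched tokens come back as clean
    English words, unmatched tokens pass through unchanged.
    """
    return " ".join(
        _LOOKUP_ES_EN.get(_lookup_key(t), t) for t in text_es.split(" ") if t != ""
    )


_DIACRITIC_MAP = {"a": "á", "e": "é", "i": "í", "o": "ó", "u": "ú", "n": "ñ"}
_STRIP_MAP = {v: k for k, v in _DIACRITIC_MAP.items()}


def _flip_case(token: str) -> str:
    return token.lower() if token[0].isupper() else token.capitalize()


def perturb(
    text: str,
    profile: PerturbationProfile,
    rng: random.Random,
    language: str = "es",
) -> tuple[str, tuple[str, ...]]:
    """Apply each perturbation class independently with its probability.

    Returns the perturbed text and the log of classes actually applied (a
    class that fires but finds no applicable site is not logged).
    """
    tokens = [t for t in text.split(" ") if t]
    log: list[str] = []

    if tokens and rng.random() < profile.substitution:
        sites = [i for i, t in enumerate(tokens) if t in (LEXICON_ES_EN if language == "es" else LEXICON_EN_ES)]
        if sites:
            i = rng.choice(sites)
            pool = list(LEXICON_ES_EN if language == "es" else LEXICON_EN_ES)
            # a substitute must carry meaning: never a stopword the scorer
            # could legitimately strip away
            removable = DEFAULT_STOPWORDS.get(language, frozenset())
            choices = [
                w
                for w in pool
                if w != tokens[i]
                and w.lower() not in removable
                and w not in _STOPWORD_POOL[language]
            ]
            tokens[i] = rng.choice(choices)
            log.append("substitution")

    if tokens and rng.random() < profile.case_flip:
        i = rng.randrange(len(tokens))
        tokens[i] = _flip_case(tokens[i])
        log.append("case_flip")

    if tokens and rng.random() < profile.diacritic:
        marked = [
            (i, j)
            for i, t in enumerate(tokens)
            for j, ch in enumerate(t)
            if ch in _STRIP_MAP
        ]
        if marked:  # strip one existing mark
            i, j = rng.choice(marked)
            t = tokens[i]
            tokens[i] = t[:j] + _STRIP_MAP[t[j]] + t[j + 1 :]
            log.append("diacritic")
        else:  # or add one
            plain = [
                (i, j)
                for i, t in enumerate(tokens)
                for j, ch in enumerate(t)
                if ch in _DIACRITIC_MAP
            ]
            if plain:
                i, j = rng.choice(plain)
                t = tokens[i]
                tokens[i] = t[:j] + _DIACRITIC_MAP[t[j]] + t[j + 1 :]
                log.append("diacritic")

    if rng.random() < profile.stopword:
        present = [i for i, t in enumerate(tokens) if t.lower() in _STOPWORD_POOL[language]]
        if present and rng.random() < 0.5:
            del tokens[rng.choice(present)]
        else:
            tokens.insert(rng.randint(0, len(tokens)), rng.choice(_STOPWORD_POOL[language]))
        log.append("stopword")

    if len(tokens) >= 2 and rng.random() < profile.reorder:
        i = rng.randrange(len(tokens) - 1)
        if tokens[i] != tokens[i + 1]:
            tokens[i], tokens[i + 1] = tokens[i + 1], tokens[i]
            log.append("reorder")

    if rng.random() < profile.numeral_style:
        arabics = [i for i, t in enumerate(tokens) if t.isdigit() and 1 <= int(t) <= 10]
        if arabics:
            i = rng.choice(arabics)
            tokens[i] = _ROMAN[int(tokens[i]) - 1]
            log.append("numeral_style")

    if tokens and rng.random() < profile.punctuation:
        punctuated = [i for i, t in enumerate(tokens) if t.endswith((",", "."))]
        if punctuated:
            i = rng.choice(punctuated)
            tokens[i] = tokens[i].rstrip(",.")
        else:
            i = rng.randrange(len(tokens))
            tokens[i] = tokens[i] + ","
        log.append("punctuation")

    out = " ".join(tokens)
    if tokens and rng.random() < profile.whitespace:
        # separator-only change: double one inter-token space (token-neutral)
        seps = out.count(" ")
        if seps:
            k = rng.randrange(seps)
            pos = -1
            for _ in range(k + 1):
                pos = out.index(" ", pos + 1)
            out = out[:pos] + "  " + out[pos + 1 :]
            log.append("whitespace")

    return out, tuple(log)


_PREDICATE_CYCLE = ("label", "exact_synonym", "definition")


def generate_corpus(
    n: int,
    profile_faithful: PerturbationProfile = FAITHFUL_PROFILE,
    profile_unfaithful: PerturbationProfile = UNFAITHFUL_PROFILE,
    mix: float = 0.5,
    seed: int = 0,
) -> list[SyntheticUnit]:
    """Generate ``n`` labeled units; ``mix`` is the faithful fraction.

    Allocation is deterministic: the first ``round(n*mix)`` units use the
    faithful profile.  Each unit draws from its own counter-derived RNG
    substream, so units are independent of generation order.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if not 0.0 <= mix <= 1.0:
        raise ValueError("mix must be in [0,1]")
    n_faithful = round(n * mix)
    units: list[SyntheticUnit] = []
    for i in range(n):
        # counter-derived substream: unit i is independent of generation order
        rng = random.Random(seed * 1_000_003 + i)
        faithful = i < n_faithful
        profile = profile_faithful if faithful else profile_unfaithful
        source, reference = generate_term(rng)
        professional, log_prof = perturb(reference, profile, rng, "es")
        forward, log_fwd = perturb(reference, profile_faithful.without_substitution(), rng, "es")
        back_raw = back_map(professional)
        back, log_back = perturb(
            back_raw, profile_faithful.without_substitution(), rng, "en"
        )
        full_log = log_prof + log_fwd + log_back
        unit = TranslationUnit(
            subject_id=f"SYNTH:{i:07d}",
            predicate_id=_PREDICATE_CYCLE[i % len(_PREDICATE_CYCLE)],
            source_lang="en",
            source_text=source,
            translation_lang="es",
            professional_text=professional,
            machine_forward_text=forward,
            machine_back_text=back,
        )
        label = "unfaithful" if "substitution" in full_log else "faithful"
        units.append(SyntheticUnit(unit=unit, label=label, perturbation_log=full_log))
    return units


def as_labeled(units):
    """View a synthetic corpus as labeled calibration data.

    Faithful units are what a human reviewer would accept; unfaithful ones
    (meaning-changing substitution present) would be rejected.
    """
    from .calibrate import LabeledUnit

    return [
        LabeledUnit(unit=su.unit, verdict="accept" if su.label == "faithful" else "reject")
        for su in units
    ]
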