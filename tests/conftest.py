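import pytest

from transqc import synthcorpus
from transqc.scoring import TranslationUnit, score_units


@pytest.fixture(scope="session")
def worked_unit() -> TranslationUnit:
    """The arbovirus-fever unit used throughout the docs: a professional
    Spanish translation paired with machine forward and back translations."""
    return TranslationUnit(
        subject_id="DOID:0050518",
        predicate_id="label",
        source_lang="en",
        source_text="Ross River fever",
        translation_lang="es",
        professional_text="fiebre del río de Ross",
        machine_forward_text="Fiebre del río Ross",
        machine_back_text="ross river fever",
    )


@pytest.fixture(scope="session")
def corpus500():
    """Default-profile synthetic corpus, shared across tests (generation is
    cheap but scoring is not; see scored500)."""
    return synthcorpus.generate_corpus(500, mix=0.5, seed=7)


@pytest.fixture(scope="session")
def scored500(corpus500):
    return score_units([su.unit for su in corpus500])
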