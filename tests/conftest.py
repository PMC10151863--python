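import pytest

from consultcoder.corpus_io import LabeledCorpus, LabelSet, Transcript, Turn
from consultcoder.synthetic_data import (
    GeneratorConfig,
    LexiconSpec,
    generate_corpus,
    generate_lexicons,
)


@pytest.fixture
def tiny_transcript() -> Transcript:
    return Transcript("t1", (
        Turn("clinician", "hello what brings you in"),
        Turn("patient", "my knee hurts when i walk"),
        Turn("clinician", "how long has the knee been painful"),
    ))


@pytest.fixture
def tiny_corpus(tiny_transcript) -> LabeledCorpus:
    t2 = Transcript("t2", (
        Turn("clinician", "any cough or fever"),
        Turn("patient", "a dry cough for two weeks"),
    ))
    t3 = Transcript("t3", (Turn("patient", "just a rash on my arm"),))
    return LabeledCorpus(
        transcripts=[tiny_transcript, t2, t3],
        labels={
            "t1": LabelSet("t1", frozenset({"L"})),
            "t2": LabelSet("t2", frozenset({"R"})),
            "t3": LabelSet("t3", frozenset({"S"})),
        },
    )


@pytest.fixture(scope="session")
def small_lexicons():
    """Separable 4-chapter lexicons shared across pipeline tests."""
    return generate_lexicons(
        LexiconSpec(inventory=("D", "L", "R", "S"), keywords_per_class=8,
                    n_filler_words=60, overlap=0.0),
        seed=7,
    )


@pytest.fixture(scope="session")
def small_corpus(small_lexicons) -> LabeledCorpus:
    config = GeneratorConfig(
        n_transcripts=120,
        inventory=("D", "L", "R", "S"),
        class_weights={"D": 1, "L": 1, "R": 1, "S": 1},
        label_count_dist={1: 1.0},
    )
    return generate_corpus(config, small_lexicons, seed=7)
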