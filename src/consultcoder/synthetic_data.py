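"""Synthetic GP-patient dialogue corpora with controllable class signal.

Real consultation corpora with chapter-coded transcripts are access
restricted, so every pipeline stage is exercised against generated data that
emulates their structure: speaker-turn transcripts whose label-count
distribution and per-chapter label marginals default to the printed summary
statistics of the reference consultation dataset, and whose clinical signal
is a per-speaker keyword-emission process over per-chapter lexicons.

Lexicons are pronounceable pseudo-words (never real medical terms, so they
cannot collide with shipped stopword lists).  A cross-class overlap rate
controls task difficulty: a fraction of each chapter's keywords is drawn
from one block shared by *all* chapters, so any pair of chapters shares
exactly ``round(overlap * k)`` keywords and classification degrades smoothly
as overlap grows.  Filler text deliberately includes common English
stopwords so stopword removal has a measurable effect.

The same lexicons also materialise as synthetic code-description entries and
synthetic health topics (with a topic->chapter map), so distant supervision
can be tested end to end.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
from sklearn.feature_extraction.text import ENGLISH_STOP_WORDS

from consultcoder.corpus_io import (
    DEFAULT_INVENTORY,
    CodeDescriptionEntry,
    HealthTopic,
    LabeledCorpus,
    LabelSet,
    TopicCodeMap,
    Transcript,
    Turn,
)

__all__ = [
    "LexiconSpec",
    "SyntheticLexicons",
    "GeneratorConfig",
    "TABLE1_CLASS_WEIGHTS",
    "TABLE1_LABEL_COUNT_DIST",
    "generate_lexicons",
    "generate_corpus",
    "make_ablation_corpus",
]

#: Per-chapter transcript counts of the reference dataset (marginal weights).
TABLE1_CLASS_WEIGHTS: dict[str, int] = {
    "A": 14, "B": 8, "D": 44, "F": 5, "H": 11, "K": 32, "L": 65, "N": 20,
    "P": 50, "R": 37, "S": 32, "T": 24, "U": 18, "W": 11, "X": 14, "Y": 7,
}

#: Printed codes-per-consultation counts (the "4+" row generates 4 labels).
TABLE1_LABEL_COUNT_DIST: dict[int, int] = {0: 2, 1: 128, 2: 62, 3: 40, 4: 8}


@dataclass(frozen=True)
class LexiconSpec:
    """Shape of the synthetic per-chapter lexicons.

    ``overlap`` in [0, 1): the fraction of each chapter's ``keywords_per_class``
    keywords taken from a block shared by all chapters.
    """

    inventory: tuple[str, ...] = DEFAULT_INVENTORY
    keywords_per_class: int = 12
    n_filler_words: int = 150
    overlap: float = 0.0

    def __post_init__(self) -> None:
        object.__setattr__(self, "inventory", tuple(sorted(self.inventory)))
        if not 0 <= self.overlap < 1:
            raise ValueError("overlap rate must be in [0, 1)")
        if self.keywords_per_class < 1:
            raise ValueError("keywords_per_class must be >= 1")


# pronounceable pseudo-word machinery: CV syllables, deterministic order
_CONSONANTS = "bdfgklmnprstvz"
_VOWELS = "aeiou"


def _pseudo_word_pool(rng: np.random.Generator, n: int) -> list[str]:
    """n unique pronounceable pseudo-words (2-3 CV syllables), seeded."""
    syllables = [c + v for c in _CONSONANTS for v in _VOWELS]
    pool: list[str] = []
    seen: set[str] = set(ENGLISH_STOP_WORDS)  # never collide with stopwords
    attempts = 0
    while len(pool) < n:
        attempts += 1
        if attempts > 100 * n + 1000:
            raise ValueError(f"cannot generate {n} unique pseudo-words")
        k = int(rng.integers(2, 4))
        word = "".join(rng.choice(syllables) for _ in range(k))
        if word not in seen:
            seen.add(word)
            pool.append(word)
    return pool


@dataclass(frozen=True)
class SyntheticLexicons:
    """Per-chapter keyword lists plus their distant-supervision materialisations."""

    spec: LexiconSpec
    keywords: dict[str, tuple[str, ...]]          # letter -> keywords
    filler: tuple[str, ...]                       # shared non-signal vocabulary
    code_entries: tuple[CodeDescriptionEntry, ...]
    topics: tuple[HealthTopic, ...]
    topic_map: TopicCodeMap = field(default_factory=dict)

    def keyword_union(self, letters: Sequence[str]) -> tuple[str, ...]:
        out: list[str] = []
        for c in sorted(letters):
            out.extend(self.keywords[c])
        return tuple(dict.fromkeys(out))  # dedupe, order preserved


def generate_lexicons(spec: LexiconSpec, seed: int = 0) -> SyntheticLexicons:
    """Sample per-chapter keyword lexicons, filler vocabulary and their
    code-description / health-topic materialisations.

    Shared-block scheme: ``m = round(overlap * k)`` keywords are identical in
    every chapter's list; the remaining ``k - m`` are unique per chapter, so
    every chapter pair shares exactly m keywords.
    """
    rng = np.random.default_rng(seed)
    k = spec.keywords_per_class
    m = round(spec.overlap * k)
    n_unique = (k - m) * len(spec.inventory)
    need = m + n_unique + spec.n_filler_words
    pool = _pseudo_word_pool(rng, need)

    shared = pool[:m]
    cursor = m
    keywords: dict[str, tuple[str, ...]] = {}
    for letter in spec.inventory:
        own = pool[cursor:cursor + (k - m)]
        cursor += k - m
        keywords[letter] = tuple(own + shared)
    pseudo_filler = pool[cursor:cursor + spec.n_filler_words]
    filler = tuple(sorted(set(pseudo_filler) | set(ENGLISH_STOP_WORDS)))

    entries: list[CodeDescriptionEntry] = []
    for letter in spec.inventory:
        words = keywords[letter]
        for i in range(0, len(words), 3):
            entries.append(CodeDescriptionEntry(
                low_level_code=f"{letter}{i // 3 + 1:02d}",
                chapter=letter,
                description=" ".join(words[i:i + 3]),
            ))

    topics: list[HealthTopic] = []
    topic_map: TopicCodeMap = {}
    for letter in spec.inventory:
        words = keywords[letter]
        half = max(1, len(words) // 2)
        topic_id = f"topic_{letter.lower()}"
        topics.append(HealthTopic(topic_id, {
            "Definition": "A condition involving " + " and ".join(words[:half]) + ".",
            "Presentation": "Patients typically report "
                            + ", ".join(words[half:]) + ".",
        }))
        topic_map[topic_id] = frozenset({letter})

    return SyntheticLexicons(
        spec=spec, keywords=keywords, filler=filler,
        code_entries=tuple(entries), topics=tuple(topics), topic_map=topic_map,
    )


@dataclass(frozen=True)
class GeneratorConfig:
    """Study conditions for synthetic corpus generation.

    Defaults mirror the reference consultation dataset's printed summary:
    label marginals proportional to the per-chapter transcript counts and the
    codes-per-consultation distribution renormalized over 1..4+ (zero-label
    consultations excluded so every transcript is usable for multiclass
    training; ``include_zero_labels`` restores them).  Keyword emission
    probabilities are per speaker: each content token is a keyword of one of
    the transcript's chapters with the speaker's emission probability, else a
    filler word.
    """

    n_transcripts: int = 239
    inventory: tuple[str, ...] = DEFAULT_INVENTORY
    class_weights: Mapping[str, float] | None = None     # default: reference counts
    label_count_dist: Mapping[int, float] | None = None  # default: printed rows 1..4+
    include_zero_labels: bool = False
    turns_range: tuple[int, int] = (8, 24)
    tokens_per_turn_range: tuple[int, int] = (6, 18)
    p_clinician: float = 0.12
    p_patient: float = 0.12
    id_prefix: str = "syn"

    def __post_init__(self) -> None:
        object.__setattr__(self, "inventory", tuple(sorted(self.inventory)))
        for p in (self.p_clinician, self.p_patient):
            if not 0 <= p <= 1:
                raise ValueError("emission probabilities must be in [0, 1]")
        if self.n_transcripts < 1:
            raise ValueError("n_transcripts must be >= 1")
        if self.turns_range[0] < 1 or self.turns_range[0] > self.turns_range[1]:
            raise ValueError("invalid turns_range")
        if (self.tokens_per_turn_range[0] < 1
                or self.tokens_per_turn_range[0] > self.tokens_per_turn_range[1]):
            raise ValueError("invalid tokens_per_turn_range")

    def resolved_class_weights(self) -> np.ndarray:
        if self.class_weights is not None:
            w = np.array([float(self.class_weights[c]) for c in self.inventory])
        else:
            w = np.array([float(TABLE1_CLASS_WEIGHTS.get(c, 1.0))
                          for c in self.inventory])
        if (w < 0).any() or w.sum() <= 0:
            raise ValueError("class weights must be non-negative and not all zero")
        return w / w.sum()

    def resolved_label_count_dist(self) -> tuple[np.ndarray, np.ndarray]:
        if self.label_count_dist is not None:
            items = sorted((int(k), float(v))
                           for k, v in self.label_count_dist.items())
        else:
            items = sorted(TABLE1_LABEL_COUNT_DIST.items())
            if not self.include_zero_labels:
                items = [(c, v) for c, v in items if c > 0]
        counts = np.array([c for c, _ in items])
        probs = np.array([v for _, v in items], dtype=float)
        if (probs < 0).any() or probs.sum() <= 0:
            raise ValueError("label-count distribution must be non-negative")
        if counts.max() > len(self.inventory):
            raise ValueError("label count exceeds inventory size")
        return counts, probs / probs.sum()


def _generate(config: GeneratorConfig, lexicons: SyntheticLexicons,
              patient_only_classes: frozenset[str], seed: int) -> LabeledCorpus:
    missing = set(config.inventory) - set(lexicons.keywords)
    if missing:
        raise ValueError(f"lexicons do not cover chapter(s) {sorted(missing)}")
    bad = patient_only_classes - set(config.inventory)
    if bad:
        raise ValueError(f"patient-only classes outside inventory: {sorted(bad)}")

    rng = np.random.default_rng(seed)
    class_probs = config.resolved_class_weights()
    counts, count_probs = config.resolved_label_count_dist()
    inventory = np.array(config.inventory)
    filler = np.array(lexicons.filler)

    transcripts: list[Transcript] = []
    labels: dict[str, LabelSet] = {}
    width = len(str(config.n_transcripts))
    for i in range(config.n_transcripts):
        tid = f"{config.id_prefix}{i + 1:0{width}d}"
        n_labels = int(rng.choice(counts, p=count_probs))
        if n_labels > 0:
            chosen = rng.choice(inventory, size=n_labels, replace=False,
                                p=class_probs)
            label_set = frozenset(str(c) for c in chosen)
        else:
            label_set = frozenset()
        clin_pool = np.array(
            lexicons.keyword_union(sorted(label_set - patient_only_classes)))
        pat_pool = np.array(lexicons.keyword_union(sorted(label_set)))

        n_turns = int(rng.integers(config.turns_range[0],
                                   config.turns_range[1] + 1))
        turns: list[Turn] = []
        for turn_idx in range(n_turns):
            speaker = "clinician" if turn_idx % 2 == 0 else "patient"
            p_emit = config.p_clinician if speaker == "clinician" else config.p_patient
            pool = clin_pool if speaker == "clinician" else pat_pool
            n_tokens = int(rng.integers(config.tokens_per_turn_range[0],
                                        config.tokens_per_turn_range[1] + 1))
            words: list[str] = []
            for _ in range(n_tokens):
                if len(pool) and rng.random() < p_emit:
                    words.append(str(rng.choice(pool)))
                else:
                    words.append(str(rng.choice(filler)))
            turns.append(Turn(speaker, " ".join(words)))
        transcripts.append(Transcript(tid, tuple(turns)))
        labels[tid] = LabelSet(tid, label_set)
    return LabeledCorpus(transcripts, labels, config.inventory)


def generate_corpus(config: GeneratorConfig, lexicons: SyntheticLexicons,
                    seed: int = 0) -> LabeledCorpus:
    """Generate a labelled speaker-turn corpus under the configured conditions."""
    return _generate(config, lexicons, frozenset(), seed)


def make_ablation_corpus(
    config: GeneratorConfig,
    lexicons: SyntheticLexicons,
    patient_only_classes: Sequence[str],
    seed: int = 0,
) -> LabeledCorpus:
    """Generate a corpus in which the listed chapters' keywords appear only in
    patient turns, so clinician-only text is uninformative for them.

    With an empty ``patient_only_classes`` this is identical to
    :func:`generate_corpus` at the same seed.
    """
    return _generate(config, lexicons, frozenset(patient_only_classes), seed)
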