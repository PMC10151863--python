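"""Tokenization, stopword removal and top-5000 unigram+bigram featurization.

Transcript text is lower-cased and tokenized into maximal runs of letters
(internal apostrophes kept, digits and punctuation dropped).  Stopwords come
in three tiers — general English, medical and custom — removable in any
combination; removal happens *before* bigram formation by default, so the
removal can create new word adjacencies.  Documents are encoded as count
vectors over the most frequent unigrams and bigrams of a training corpus
(default vocabulary cap 5000).
"""

from __future__ import annotations

import csv
import re
from collections import Counter
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from sklearn.feature_extraction.text import ENGLISH_STOP_WORDS

from consultcoder.corpus_io import Transcript

__all__ = [
    "TokenSequence",
    "StopwordInventory",
    "Vocabulary",
    "extract_text",
    "tokenize",
    "remove_stopwords",
    "build_vocabulary",
    "vectorize",
    "ngrams_of",
]

TokenSequence = list[str]

_TOKEN_RE = re.compile(r"[a-z]+(?:'[a-z]+)*")

_LIST_NAMES = ("english", "medical", "custom")


def extract_text(transcript: Transcript, speaker_mode: str = "both") -> str:
    """Concatenate turn texts in order, optionally keeping clinician turns only.

    ``speaker_mode`` is ``"both"`` (all turns) or ``"clinician_only"`` (the
    GP's half of the conversation).  Speaker tags are never included; a
    transcript with no selected turns yields an empty string.
    """
    if speaker_mode not in ("both", "clinician_only"):
        raise ValueError(f"unknown speaker_mode {speaker_mode!r}")
    if speaker_mode == "both":
        texts = [t.text for t in transcript.turns]
    else:
        texts = [t.text for t in transcript.turns if t.speaker == "clinician"]
    return " ".join(t for t in texts if t)


def tokenize(text: str) -> TokenSequence:
    """Lower-case and split into letter runs; apostrophes inside words survive."""
    return _TOKEN_RE.findall(text.lower())


def _read_wordlist(path: str | Path) -> frozenset[str]:
    words: set[str] = set()
    for line in Path(path).read_text(encoding="utf-8").splitlines():
        word = line.split("#", 1)[0].strip().lower()
        if word:
            words.add(word)
    return frozenset(words)


def _packaged_wordlist(name: str) -> frozenset[str]:
    ref = resources.files("consultcoder.data") / f"stopwords_{name}.txt"
    words = {
        line.split("#", 1)[0].strip().lower()
        for line in ref.read_text(encoding="utf-8").splitlines()
    }
    return frozenset(w for w in words if w)


@dataclass(frozen=True)
class StopwordInventory:
    """Three named stopword tiers: general ``english``, ``medical``, ``custom``."""

    english: frozenset[str]
    medical: frozenset[str]
    custom: frozenset[str]

    @classmethod
    def default(cls) -> "StopwordInventory":
        """English = the standard scikit-learn 318-word list; medical and
        custom = packaged editable placeholder lists (the tier mechanism, not
        the exact membership, is the contract)."""
        return cls(
            english=frozenset(ENGLISH_STOP_WORDS),
            medical=_packaged_wordlist("medical"),
            custom=_packaged_wordlist("custom"),
        )

    @classmethod
    def from_files(cls, english: str | Path, medical: str | Path,
                   custom: str | Path) -> "StopwordInventory":
        """Load all three tiers from one-word-per-line files ('#' comments)."""
        return cls(
            english=_read_wordlist(english),
            medical=_read_wordlist(medical),
            custom=_read_wordlist(custom),
        )

    def sizes(self) -> dict[str, int]:
        return {name: len(getattr(self, name)) for name in _LIST_NAMES}

    def union(self, active_lists: Iterable[str]) -> frozenset[str]:
        active = list(active_lists)
        unknown = set(active) - set(_LIST_NAMES)
        if unknown:
            raise ValueError(f"unknown stopword list(s): {sorted(unknown)}")
        out: frozenset[str] = frozenset()
        for name in active:
            out |= getattr(self, name)
        return out


def remove_stopwords(tokens: TokenSequence, inventory: StopwordInventory,
                     active_lists: Iterable[str] = ()) -> TokenSequence:
    """Drop tokens in the union of the active tiers, preserving order."""
    stop = inventory.union(active_lists)
    if not stop:
        return list(tokens)
    return [t for t in tokens if t not in stop]


def ngrams_of(tokens: Sequence[str]) -> list[str]:
    """All unigrams plus adjacent bigrams (space-joined) of a token sequence."""
    grams = list(tokens)
    grams.extend(f"{a} {b}" for a, b in zip(tokens, tokens[1:]))
    return grams


@dataclass(frozen=True)
class Vocabulary:
    """A frozen, frequency-ranked unigram+bigram vocabulary.

    Entries are ordered by descending training-corpus frequency, ties broken
    lexicographically; at most ``max_features`` entries are kept.
    """

    ngrams: tuple[str, ...]
    frequencies: tuple[int, ...]
    max_features: int

    _index: dict[str, int] = field(init=False, repr=False, compare=False)

    def __post_init__(self) -> None:
        object.__setattr__(self, "_index",
                           {g: i for i, g in enumerate(self.ngrams)})

    def __len__(self) -> int:
        return len(self.ngrams)

    def __contains__(self, gram: str) -> bool:
        return gram in self._index

    def index(self, gram: str) -> int:
        return self._index[gram]

    def to_csv(self, path: str | Path) -> None:
        with open(path, "w", newline="", encoding="utf-8") as fh:
            writer = csv.writer(fh)
            writer.writerow(["ngram", "frequency", "index"])
            for i, (g, f) in enumerate(zip(self.ngrams, self.frequencies)):
                writer.writerow([g, f, i])

    @classmethod
    def from_csv(cls, path: str | Path, max_features: int | None = None) -> "Vocabulary":
        grams: list[str] = []
        freqs: list[int] = []
        with open(path, newline="", encoding="utf-8") as fh:
            for row in csv.DictReader(fh):
                grams.append(row["ngram"])
                freqs.append(int(row["frequency"]))
        return cls(tuple(grams), tuple(freqs),
                   max_features if max_features is not None else len(grams))


def build_vocabulary(documents: Sequence[TokenSequence],
                     max_features: int = 5000) -> Vocabulary:
    """Rank all unigrams and adjacent bigrams by corpus frequency, keep the top.

    Stopword removal (if any) must already have been applied to ``documents``
    so bigrams reflect post-removal adjacency.
    """
    if not documents:
        raise ValueError("cannot build a vocabulary from an empty corpus")
    if max_features < 1:
        raise ValueError("max_features must be >= 1")
    counts: Counter[str] = Counter()
    for doc in documents:
        counts.update(ngrams_of(doc))
    ranked = sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))[:max_features]
    return Vocabulary(
        ngrams=tuple(g for g, _ in ranked),
        frequencies=tuple(c for _, c in ranked),
        max_features=max_features,
    )


def vectorize(tokens: TokenSequence, vocab: Vocabulary) -> np.ndarray:
    """Count vocabulary n-grams in a document; OOV n-grams are ignored."""
    vec = np.zeros(len(vocab), dtype=np.int64)
    for gram in ngrams_of(tokens):
        idx = vocab._index.get(gram)
        if idx is not None:
            vec[idx] += 1
    return vec


def vectorize_corpus(token_docs: Sequence[TokenSequence],
                     vocab: Vocabulary) -> np.ndarray:
    """Stack per-document count vectors into an (n_docs, n_features) matrix."""
    if not token_docs:
        return np.zeros((0, len(vocab)), dtype=np.int64)
    return np.vstack([vectorize(doc, vocab) for doc in token_docs])
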