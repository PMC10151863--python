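"""Sentence-respecting chunking and prompt-based few-shot classification.

Transformer encoders cap input length (512 tokens for BERT-family models),
so long transcripts and health topics are broken into chunks of complete
sentences under a token budget.  Training chunks inherit the parent
document's labels; at prediction time the document label is the union of
per-chunk predictions.

Two few-shot strategies score chunks against a one-blank prompt such as
``"this is a problem of ___"``:

* NSP — next-sentence-prediction-style pair scoring of (chunk, filled
  prompt), one score per chapter, thresholded (multilabel);
* MLM — fill-in-the-blank scoring of the verbalized chapter names, argmax
  per chunk (multiclass).

A ``conventional`` fine-tuned classification head is modelled by any backend
implementing ``fit``/``predict_label``.  All logic is exercised by the
deterministic :class:`KeywordStubBackend`; a transformer backend can be
registered under a name without changing any call site.
"""

from __future__ import annotations

import json
import re
import warnings
from dataclasses import dataclass, field
from importlib import resources
from typing import Callable, Iterable, Mapping, Protocol, Sequence, runtime_checkable

from consultcoder.classifiers import PredictionSet

__all__ = [
    "Chunk",
    "PromptTemplate",
    "Verbalizer",
    "ScoringBackend",
    "KeywordStubBackend",
    "BACKENDS",
    "register_backend",
    "split_sentences",
    "chunk_document",
    "inherit_labels",
    "union_predictions",
    "nsp_classify",
    "mlm_classify",
    "conventional_classify",
    "default_verbalizer",
]


@dataclass(frozen=True)
class Chunk:
    """A contiguous run of complete sentences from one parent document."""

    parent_id: str
    index: int
    text: str
    token_count: int


@dataclass(frozen=True)
class PromptTemplate:
    """A prompt with exactly one blank slot, e.g. ``this is a problem of ___``."""

    template: str = "this is a problem of ___"
    slot: str = "___"

    def __post_init__(self) -> None:
        if self.template.count(self.slot) != 1:
            raise ValueError(
                f"template must contain exactly one {self.slot!r} slot"
            )

    def fill(self, word: str) -> str:
        return self.template.replace(self.slot, word)


@dataclass(frozen=True)
class Verbalizer:
    """Chapter letter -> single-token class name used inside prompts."""

    names: Mapping[str, str]

    def __post_init__(self) -> None:
        object.__setattr__(self, "names", dict(self.names))
        values = list(self.names.values())
        if len(set(values)) != len(values):
            raise ValueError("verbalizer class names must be unique")
        for letter, name in self.names.items():
            if " " in name:
                raise ValueError(
                    f"verbalizer name for {letter!r} must be a single token, got {name!r}"
                )

    def name(self, letter: str) -> str:
        try:
            return self.names[letter]
        except KeyError:
            raise KeyError(f"verbalizer has no name for chapter {letter!r}") from None

    def letter(self, name: str) -> str:
        for letter, n in self.names.items():
            if n == name:
                return letter
        raise KeyError(f"verbalizer has no chapter for name {name!r}")

    def check_covers(self, inventory: Iterable[str]) -> None:
        missing = [c for c in inventory if c not in self.names]
        if missing:
            raise KeyError(f"verbalizer missing entries for {missing}")


def default_verbalizer() -> Verbalizer:
    """The packaged single-word chapter names (e.g. L -> musculoskeletal)."""
    ref = resources.files("consultcoder.data") / "verbalizer_default.json"
    return Verbalizer(json.loads(ref.read_text(encoding="utf-8")))


@runtime_checkable
class ScoringBackend(Protocol):
    """Contract a scoring backend must satisfy.

    ``pair_score(a, b)`` returns a coherence score in [0, 1] for the pair.
    ``fill_scores(text_with_blank, candidates)`` returns a probability per
    candidate token (summing to at most 1).  Backends supporting conventional
    fine-tuning additionally expose ``fit(texts, labels)`` and
    ``predict_label(text)``.  All methods must be deterministic for a fixed
    backend state.
    """

    def pair_score(self, text_a: str, text_b: str) -> float: ...

    def fill_scores(self, text_with_blank: str,
                    candidates: Sequence[str]) -> dict[str, float]: ...


def _whitespace_tokens(text: str) -> list[str]:
    return text.split()


_ABBREVIATIONS = {
    "dr", "mr", "mrs", "ms", "prof", "st", "e.g", "i.e", "eg", "ie", "etc",
    "vs", "no", "approx",
}

_SENT_BOUNDARY = re.compile(r"([.!?]+)(\s+|$)")


def split_sentences(text: str) -> list[str]:
    """Rule-based sentence split on terminal punctuation with an abbreviation
    guard (``Dr.``, ``e.g.`` and similar do not end a sentence)."""
    sentences: list[str] = []
    start = 0
    for m in _SENT_BOUNDARY.finditer(text):
        candidate = text[start:m.end(1)].strip()
        if not candidate:
            start = m.end()
            continue
        last_word = candidate.rsplit(None, 1)[-1].rstrip(".!?").lower()
        if last_word in _ABBREVIATIONS and m.group(1) == ".":
            continue
        sentences.append(candidate)
        start = m.end()
    tail = text[start:].strip()
    if tail:
        sentences.append(tail)
    return sentences


def chunk_document(
    text: str,
    parent_id: str = "doc",
    *,
    budget: int = 512,
    tokenizer: Callable[[str], list[str]] = _whitespace_tokens,
) -> list[Chunk]:
    """Greedily pack whole sentences into chunks of at most ``budget`` tokens.

    A single sentence longer than the budget is hard-split at the budget with
    a warning.  Empty text yields no chunks.
    """
    if budget < 1:
        raise ValueError("token budget must be >= 1")
    pieces: list[list[str]] = []  # token lists of budget-conformant sentences
    for sent in split_sentences(text):
        tokens = tokenizer(sent)
        if len(tokens) <= budget:
            pieces.append(tokens)
        else:
            warnings.warn(
                f"{parent_id}: sentence of {len(tokens)} tokens exceeds the "
                f"budget of {budget}; hard-splitting", stacklevel=2
            )
            for i in range(0, len(tokens), budget):
                pieces.append(tokens[i:i + budget])
    chunks: list[Chunk] = []
    current: list[str] = []
    current_sents: list[str] = []

    def flush() -> None:
        nonlocal current, current_sents
        if current_sents:
            text_out = " ".join(current_sents)
            chunks.append(Chunk(parent_id, len(chunks), text_out, len(current)))
        current, current_sents = [], []

    for tokens in pieces:
        if current and len(current) + len(tokens) > budget:
            flush()
        current.extend(tokens)
        current_sents.append(" ".join(tokens))
    flush()
    return chunks


def inherit_labels(chunks: Sequence[Chunk],
                   parent_labels: Iterable[str]) -> list[frozenset[str]]:
    """Every training chunk receives its parent document's full label set."""
    labels = frozenset(parent_labels)
    return [labels for _ in chunks]


def union_predictions(per_chunk: Iterable[Iterable[str]]) -> frozenset[str]:
    """Document prediction = set union of the per-chunk predictions."""
    out: frozenset[str] = frozenset()
    for labels in per_chunk:
        out |= frozenset(labels)
    return out


def nsp_classify(
    chunks: Sequence[Chunk],
    inventory: Sequence[str],
    verbalizer: Verbalizer,
    template: PromptTemplate,
    backend: ScoringBackend,
    threshold: float = 0.5,
) -> frozenset[str]:
    """Multilabel prompt classification via pair scoring.

    Per chunk and chapter, score = ``pair_score(chunk, prompt with the
    chapter's name)``; the chunk's labels are the chapters scoring above the
    threshold, and the document label is the union over chunks.
    """
    verbalizer.check_covers(inventory)
    per_chunk: list[set[str]] = []
    for chunk in chunks:
        labels = {
            c for c in inventory
            if backend.pair_score(chunk.text, template.fill(verbalizer.name(c)))
            > threshold
        }
        per_chunk.append(labels)
    return union_predictions(per_chunk)


def mlm_classify(
    chunks: Sequence[Chunk],
    inventory: Sequence[str],
    verbalizer: Verbalizer,
    template: PromptTemplate,
    backend: ScoringBackend,
) -> frozenset[str]:
    """Multiclass prompt classification via fill-in-the-blank scoring.

    Per chunk, the chapter whose verbalized name best completes the prompt
    (appended after the chunk) wins; score ties break to the alphabetically
    first chapter.  The document label is the union over chunks, so chunks
    that disagree can yield more than one chapter.
    """
    verbalizer.check_covers(inventory)
    inventory = sorted(inventory)
    candidates = [verbalizer.name(c) for c in inventory]
    per_chunk: list[set[str]] = []
    for chunk in chunks:
        scores = backend.fill_scores(
            f"{chunk.text} {template.template}", candidates
        )
        best = max(inventory,
                   key=lambda c: (scores.get(verbalizer.name(c), 0.0),))
        # max() keeps the first (alphabetically smallest) argmax on ties
        per_chunk.append({best})
    return union_predictions(per_chunk)


def conventional_classify(
    train_chunks: Sequence[Chunk],
    train_labels: Sequence[Iterable[str]],
    test_docs: Mapping[str, Sequence[Chunk]],
    backend,
) -> PredictionSet:
    """Fine-tuned-head classification through a backend with ``fit``.

    The backend is fitted on label-inherited training chunks (multiclass:
    each chunk's alphabetically first label); per test document the
    prediction is the union of per-chunk predicted labels.
    """
    if not hasattr(backend, "fit") or not hasattr(backend, "predict_label"):
        raise TypeError("backend does not support conventional fine-tuning "
                        "(needs fit/predict_label)")
    texts: list[str] = []
    labels: list[str] = []
    for chunk, label_set in zip(train_chunks, train_labels):
        ordered = sorted(frozenset(label_set))
        if not ordered:
            continue
        texts.append(chunk.text)
        labels.append(ordered[0])
    backend.fit(texts, labels)
    out: PredictionSet = {}
    for doc_id, chunks in test_docs.items():
        out[doc_id] = union_predictions(
            [{backend.predict_label(c.text)} for c in chunks]
        )
    return out


# ---------------------------------------------------------------------------
# deterministic stub backend


class KeywordStubBackend:
    """Deterministic keyword-lookup scorer standing in for a neural encoder.

    Built from a mapping class-name -> keyword set.  ``pair_score`` returns
    the fraction of the prompt's class keywords present in the text (0 when
    the class name is unknown); ``fill_scores`` distributes probability over
    candidate names proportionally to keyword overlap.  ``fit`` memorises
    training texts as extra keywords per label, making the conventional path
    testable without any model download.
    """

    def __init__(self, keywords: Mapping[str, Iterable[str]] | None = None):
        self.keywords: dict[str, set[str]] = {
            name: {w.lower() for w in words}
            for name, words in (keywords or {}).items()
        }
        self._fitted_labels: list[str] = []

    @staticmethod
    def _tokens(text: str) -> set[str]:
        return set(re.findall(r"[a-z']+", text.lower()))

    def _match(self, text_tokens: set[str], name: str) -> float:
        kws = self.keywords.get(name)
        if not kws:
            return 0.0
        return len(text_tokens & kws) / len(kws)

    def _name_in(self, text: str) -> str | None:
        toks = self._tokens(text)
        for name in sorted(self.keywords):
            if name in toks:
                return name
        return None

    def pair_score(self, text_a: str, text_b: str) -> float:
        name = self._name_in(text_b)
        if name is None:
            return 0.0
        return min(1.0, self._match(self._tokens(text_a), name))

    def fill_scores(self, text_with_blank: str,
                    candidates: Sequence[str]) -> dict[str, float]:
        toks = self._tokens(text_with_blank)
        raw = {name: self._match(toks, name) for name in candidates}
        total = sum(raw.values())
        if total <= 0:
            return {name: 0.0 for name in candidates}
        return {name: v / total for name, v in raw.items()}

    # conventional fine-tuning: memorise word -> label votes
    def fit(self, texts: Sequence[str], labels: Sequence[str]) -> None:
        self._word_votes: dict[str, dict[str, int]] = {}
        self._fitted_labels = sorted(set(labels))
        for text, label in zip(texts, labels):
            for w in self._tokens(text):
                votes = self._word_votes.setdefault(w, {})
                votes[label] = votes.get(label, 0) + 1

    def predict_label(self, text: str) -> str:
        if not self._fitted_labels:
            raise RuntimeError("backend not fitted")
        tally: dict[str, int] = {lbl: 0 for lbl in self._fitted_labels}
        for w in self._tokens(text):
            for lbl, n in self._word_votes.get(w, {}).items():
                tally[lbl] += n
        return max(self._fitted_labels, key=lambda lbl: (tally[lbl], ))


BACKENDS: dict[str, Callable[..., object]] = {"keyword_stub": KeywordStubBackend}


def register_backend(name: str, factory: Callable[..., object]) -> None:
    """Register a scoring-backend factory under a name (plug-in point for a
    transformer backend; none is required by the test suite)."""
    BACKENDS[name] = factory
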