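"""Distant supervision: per-chapter training documents from surrogate text.

Instead of labelled example consultations, a classifier can be trained on one
document per chapter built from (a) the keyword descriptions of the low-level
codes under that chapter, or (b) the prose of health topics hand-mapped to the
chapter.  Both sources can be combined (kept as separate documents per class
so class priors remain controllable), and a chapter can be dropped from an
inventory — e.g. the catch-all "general" chapter, whose breadth can confuse
classifiers.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Sequence

from consultcoder.corpus_io import (
    DEFAULT_SECTION_ALLOWLIST,
    CodeDescriptionEntry,
    HealthTopic,
    LabeledCorpus,
    LabelSet,
    TopicCodeMap,
)

__all__ = [
    "ClassDocument",
    "DistantCorpus",
    "build_icpc2_docs",
    "build_cks_docs",
    "combine_sources",
    "drop_class",
]

_SOURCES = ("icpc2", "cks", "combined")


@dataclass(frozen=True)
class ClassDocument:
    """One training document standing in for a chapter."""

    chapter: str
    source: str
    text: str

    def __post_init__(self) -> None:
        if self.source not in _SOURCES:
            raise ValueError(f"source must be one of {_SOURCES}")
        if not self.text:
            raise ValueError(f"class document for {self.chapter!r} is empty")


@dataclass(frozen=True)
class DistantCorpus:
    """Per-chapter surrogate training documents over an ordered inventory."""

    documents: tuple[ClassDocument, ...]
    inventory: tuple[str, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "documents", tuple(self.documents))
        object.__setattr__(self, "inventory", tuple(self.inventory))
        letters = {d.chapter for d in self.documents}
        missing = set(self.inventory) - letters
        if missing:
            raise ValueError(f"no document for inventory letter(s) {sorted(missing)}")
        extra = letters - set(self.inventory)
        if extra:
            raise ValueError(f"documents for letters outside inventory {sorted(extra)}")

    def texts_and_labels(self) -> tuple[list[str], list[str]]:
        return [d.text for d in self.documents], [d.chapter for d in self.documents]

    def to_directory(self, directory: str | Path) -> None:
        """Serialize as ``<letter>_<source>.txt`` files for inspection."""
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        counters: dict[tuple[str, str], int] = {}
        for d in self.documents:
            key = (d.chapter, d.source)
            n = counters.get(key, 0)
            counters[key] = n + 1
            suffix = "" if n == 0 else f"_{n}"
            (directory / f"{d.chapter}_{d.source}{suffix}.txt").write_text(
                d.text, encoding="utf-8"
            )


def build_icpc2_docs(entries: Sequence[CodeDescriptionEntry],
                     inventory: Sequence[str]) -> DistantCorpus:
    """One document per chapter: its low-level descriptions space-joined in order.

    Entries for letters outside the inventory are skipped with a warning; an
    inventory letter with no entry raises.
    """
    inventory = tuple(sorted(inventory))
    if not entries:
        raise ValueError("no code description entries supplied")
    texts: dict[str, list[str]] = {c: [] for c in inventory}
    for e in entries:
        if e.chapter not in texts:
            warnings.warn(f"entry {e.low_level_code!r}: chapter {e.chapter!r} "
                          "outside inventory, skipped", stacklevel=2)
            continue
        texts[e.chapter].append(e.description)
    missing = [c for c, parts in texts.items() if not parts]
    if missing:
        raise ValueError(f"no code descriptions for chapter(s) {missing}")
    docs = tuple(ClassDocument(c, "icpc2", " ".join(texts[c])) for c in inventory)
    return DistantCorpus(docs, inventory)


def build_cks_docs(
    topics: Sequence[HealthTopic],
    mapping: TopicCodeMap,
    *,
    inventory: Sequence[str],
    allowlist: Sequence[str] = DEFAULT_SECTION_ALLOWLIST,
) -> DistantCorpus:
    """One document per chapter: retained prose of every topic mapped to it.

    Topic order is the input order; each topic's sections follow the
    allow-list order.  A topic mapped to k chapters contributes its full
    retained text to all k documents.
    """
    inventory = tuple(sorted(inventory))
    texts: dict[str, list[str]] = {c: [] for c in inventory}
    for topic in topics:
        body = topic.text(allowlist)
        if not body:
            continue
        for letter in sorted(mapping.get(topic.topic_id, frozenset())):
            if letter in texts:
                texts[letter].append(body)
    missing = [c for c, parts in texts.items() if not parts]
    if missing:
        raise ValueError(f"no mapped topic text for chapter(s) {missing}")
    docs = tuple(ClassDocument(c, "cks", " ".join(texts[c])) for c in inventory)
    return DistantCorpus(docs, inventory)


def combine_sources(a: DistantCorpus, b: DistantCorpus) -> DistantCorpus:
    """Pool two distant corpora, keeping each class document separate.

    Documents are not concatenated: each class keeps one document per source,
    so a naive-Bayes prior can weight sources if desired (uniform by default).
    """
    if a.inventory != b.inventory:
        raise ValueError(
            f"inventory mismatch: {a.inventory} vs {b.inventory}"
        )
    docs = tuple(
        ClassDocument(d.chapter, "combined", d.text)
        for d in (*a.documents, *b.documents)
    )
    return DistantCorpus(docs, a.inventory)


def drop_class(corpus: DistantCorpus | LabeledCorpus, letter: str):
    """Remove one chapter from an inventory and from all labels/documents.

    For a labelled corpus, transcripts are kept; the letter simply vanishes
    from every label set (a transcript labelled only with it becomes
    unlabelled but still contributes negatives).
    """
    if letter not in corpus.inventory:
        raise ValueError(f"letter {letter!r} not in inventory {corpus.inventory}")
    new_inventory = tuple(c for c in corpus.inventory if c != letter)
    if isinstance(corpus, DistantCorpus):
        docs = tuple(d for d in corpus.documents if d.chapter != letter)
        return DistantCorpus(docs, new_inventory)
    labels = {
        tid: LabelSet(tid, ls.codes - {letter})
        for tid, ls in corpus.labels.items()
    }
    return LabeledCorpus(
        transcripts=list(corpus.transcripts),
        labels=labels,
        inventory=new_inventory,
    )
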