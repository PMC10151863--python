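"""Data model and I/O for transcripts, labels, code tables and health topics.

A consultation is an ordered sequence of speaker turns.  Transcripts live one
per UTF-8 text file, lines starting ``DOCTOR:`` / ``PATIENT:`` / ``OTHER:``
(case-insensitive); a turn continues over following lines until the next tag.
Chapter labels are single letters from a configurable inventory (default: the
16 ICPC-2 chapters observed in the reference consultation dataset, i.e. all
chapters except Z).  Labels travel in a CSV of ``transcript_id,codes`` with
semicolon-separated letters.
"""

from __future__ import annotations

import csv
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

__all__ = [
    "Turn",
    "Transcript",
    "ChapterCode",
    "LabelSet",
    "LabeledCorpus",
    "CodeDescriptionEntry",
    "HealthTopic",
    "TopicCodeMap",
    "DEFAULT_INVENTORY",
    "CHAPTER_TITLES",
    "read_transcripts",
    "write_transcripts",
    "read_labels",
    "write_labels",
    "read_code_table",
    "read_topics",
    "load_table1_fixture",
]

#: The 16 chapter letters of the reference consultation dataset (no Z).
DEFAULT_INVENTORY: tuple[str, ...] = tuple("ABDFHKLNPRSTUWXY")

#: Human-readable chapter titles for the default inventory.
CHAPTER_TITLES: dict[str, str] = {
    "A": "General",
    "B": "Blood, blood forming",
    "D": "Digestive",
    "F": "Eye",
    "H": "Ear",
    "K": "Circulatory",
    "L": "Musculoskeletal",
    "N": "Neurological",
    "P": "Psychological",
    "R": "Respiratory",
    "S": "Skin",
    "T": "Metabolic, endocrine, nutritional",
    "U": "Urinary",
    "W": "Pregnancy, family planning",
    "X": "Female genital",
    "Y": "Male genital",
}

_SPEAKER_TAGS = {"doctor": "clinician", "patient": "patient", "other": "other"}
_ROLES = ("clinician", "patient", "other")


class CorpusFormatError(ValueError):
    """A file did not conform to the expected dialect."""


@dataclass(frozen=True)
class Turn:
    """One speaker turn: who spoke (clinician / patient / other) and what."""

    speaker: str
    text: str

    def __post_init__(self) -> None:
        if self.speaker not in _ROLES:
            raise ValueError(f"speaker must be one of {_ROLES}, got {self.speaker!r}")
        if self.text is None:
            raise ValueError("turn text may be empty but not None")


@dataclass(frozen=True)
class Transcript:
    """An identified consultation: an ordered sequence of turns."""

    id: str
    turns: tuple[Turn, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "turns", tuple(self.turns))


@dataclass(frozen=True)
class ChapterCode:
    """A high-level chapter: a single letter plus its title."""

    letter: str
    title: str = ""

    def __post_init__(self) -> None:
        if len(self.letter) != 1 or not self.letter.isalpha():
            raise ValueError(f"chapter letter must be a single letter, got {self.letter!r}")


@dataclass(frozen=True)
class LabelSet:
    """The set of chapter letters assigned to one transcript (may be empty)."""

    transcript_id: str
    codes: frozenset[str]

    def __post_init__(self) -> None:
        object.__setattr__(self, "codes", frozenset(self.codes))


@dataclass
class LabeledCorpus:
    """Transcripts plus per-transcript chapter label sets and a class inventory."""

    transcripts: list[Transcript]
    labels: dict[str, LabelSet]
    inventory: tuple[str, ...] = DEFAULT_INVENTORY

    def __post_init__(self) -> None:
        self.inventory = tuple(sorted(self.inventory))
        ids = {t.id for t in self.transcripts}
        if len(ids) != len(self.transcripts):
            raise ValueError("duplicate transcript ids in corpus")
        for tid, ls in self.labels.items():
            if tid not in ids:
                raise ValueError(f"label for unknown transcript id {tid!r}")
            bad = set(ls.codes) - set(self.inventory)
            if bad:
                raise ValueError(f"labels for {tid!r} outside inventory: {sorted(bad)}")

    @property
    def ids(self) -> list[str]:
        return [t.id for t in self.transcripts]

    def label_set(self, transcript_id: str) -> frozenset[str]:
        ls = self.labels.get(transcript_id)
        return ls.codes if ls is not None else frozenset()

    def subset(self, ids: Iterable[str]) -> "LabeledCorpus":
        wanted = set(ids)
        return LabeledCorpus(
            transcripts=[t for t in self.transcripts if t.id in wanted],
            labels={k: v for k, v in self.labels.items() if k in wanted},
            inventory=self.inventory,
        )


@dataclass(frozen=True)
class CodeDescriptionEntry:
    """One low-level code row: code, chapter letter and keyword description."""

    low_level_code: str
    chapter: str
    description: str

    def __post_init__(self) -> None:
        if len(self.chapter) != 1:
            raise ValueError(f"chapter must be a single letter, got {self.chapter!r}")
        if not self.description:
            raise ValueError("description must be non-empty")


#: Health-topic sections whose prose is clinically descriptive enough to use
#: as distant-supervision text.
DEFAULT_SECTION_ALLOWLIST: tuple[str, ...] = (
    "Causes",
    "Definition",
    "Diagnosis",
    "Clinical features",
    "History",
    "Presentation",
    "Signs and symptoms",
    "When to suspect",
)


@dataclass(frozen=True)
class HealthTopic:
    """A scraped health topic: an id and named sections of prose."""

    topic_id: str
    sections: Mapping[str, str]

    def __post_init__(self) -> None:
        object.__setattr__(self, "sections", dict(self.sections))

    def filtered(self, allowlist: Sequence[str] = DEFAULT_SECTION_ALLOWLIST) -> "HealthTopic":
        """Drop sections not on the allow-list (order of the allow-list kept)."""
        kept = {name: self.sections[name] for name in allowlist if name in self.sections}
        return HealthTopic(self.topic_id, kept)

    def text(self, allowlist: Sequence[str] = DEFAULT_SECTION_ALLOWLIST) -> str:
        return " ".join(
            self.sections[name] for name in allowlist if name in self.sections
        ).strip()


TopicCodeMap = dict[str, frozenset[str]]


# ---------------------------------------------------------------------------
# transcripts


def _parse_transcript_text(text: str, transcript_id: str, *, strict: bool,
                           source: str) -> Transcript:
    turns: list[Turn] = []
    current_role: str | None = None
    current_lines: list[str] = []

    def flush() -> None:
        nonlocal current_role, current_lines
        if current_role is not None:
            turns.append(Turn(current_role, " ".join(current_lines).strip()))
        current_role, current_lines = None, []

    for lineno, line in enumerate(text.splitlines(), start=1):
        stripped = line.strip()
        head, sep, rest = stripped.partition(":")
        tag = head.strip().lower()
        if sep and tag in _SPEAKER_TAGS:
            flush()
            current_role = _SPEAKER_TAGS[tag]
            current_lines = [rest.strip()]
        elif sep and tag.isalpha() and tag == head.strip().lower() and head.strip().isupper():
            # an upper-case word followed by ':' looks like a speaker tag
            if strict:
                raise CorpusFormatError(
                    f"{source}, line {lineno}: unknown speaker tag {head.strip()!r}"
                )
            flush()
            current_role = "other"
            current_lines = [rest.strip()]
        else:
            if current_role is None:
                if stripped:
                    raise CorpusFormatError(
                        f"{source}, line {lineno}: text before any speaker tag"
                    )
            else:
                current_lines.append(stripped)
    flush()
    return Transcript(transcript_id, tuple(turns))


def read_transcripts(path: str | Path, *, strict: bool = False) -> list[Transcript]:
    """Read transcripts from a file or a directory of ``*.txt`` files.

    The file stem is the transcript id.  Speaker tags are parsed
    case-insensitively; unknown upper-case tags map to role ``other`` unless
    ``strict`` is set, in which case they raise :class:`CorpusFormatError`.
    """
    path = Path(path)
    files = sorted(path.glob("*.txt")) if path.is_dir() else [path]
    out: list[Transcript] = []
    seen: set[str] = set()
    for f in files:
        tid = f.stem
        if tid in seen:
            raise CorpusFormatError(f"duplicate transcript id {tid!r}")
        seen.add(tid)
        out.append(
            _parse_transcript_text(
                f.read_text(encoding="utf-8"), tid, strict=strict, source=str(f)
            )
        )
    return out


_ROLE_TAGS = {"clinician": "DOCTOR", "patient": "PATIENT", "other": "OTHER"}


def write_transcripts(transcripts: Iterable[Transcript], directory: str | Path) -> None:
    """Write one ``<id>.txt`` file per transcript in the speaker-turn dialect."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    for t in transcripts:
        lines = [f"{_ROLE_TAGS[turn.speaker]}: {turn.text}" for turn in t.turns]
        (directory / f"{t.id}.txt").write_text("\n".join(lines) + "\n", encoding="utf-8")


# ---------------------------------------------------------------------------
# labels


def read_labels(path: str | Path,
                inventory: Sequence[str] = DEFAULT_INVENTORY) -> dict[str, LabelSet]:
    """Read a ``transcript_id,codes`` CSV; codes are ``;``-separated letters.

    Letters are upper-cased, deduplicated and validated against the inventory.
    """
    inventory_set = set(inventory)
    out: dict[str, LabelSet] = {}
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None or "transcript_id" not in reader.fieldnames:
            raise CorpusFormatError(f"{path}: expected columns transcript_id,codes")
        for rowno, row in enumerate(reader, start=2):
            tid = row["transcript_id"].strip()
            raw = (row.get("codes") or "").strip()
            letters = {c.strip().upper() for c in raw.split(";") if c.strip()}
            bad = letters - inventory_set
            if bad:
                raise CorpusFormatError(
                    f"{path}, row {rowno} ({tid!r}): codes {sorted(bad)} not in inventory"
                )
            out[tid] = LabelSet(tid, frozenset(letters))
    return out


def write_labels(labels: Mapping[str, LabelSet], path: str | Path) -> None:
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(["transcript_id", "codes"])
        for tid in sorted(labels):
            writer.writerow([tid, ";".join(sorted(labels[tid].codes))])


# ---------------------------------------------------------------------------
# code table


def read_code_table(
    path: str | Path,
    *,
    code_column: str = "code",
    chapter_column: str = "chapter",
    description_column: str = "description",
) -> list[CodeDescriptionEntry]:
    """Read a low-level code description CSV.

    When the chapter column is absent or blank the chapter is inferred from
    the first letter of the low-level code.  Rows with a missing description
    are skipped with a warning.
    """
    out: list[CodeDescriptionEntry] = []
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        rows = list(reader)
    if not rows:
        warnings.warn(f"{path}: empty code table", stacklevel=2)
        return out
    for rowno, row in enumerate(rows, start=2):
        code = (row.get(code_column) or "").strip()
        desc = (row.get(description_column) or "").strip()
        if not desc:
            warnings.warn(f"{path}, row {rowno}: missing description, skipped",
                          stacklevel=2)
            continue
        chapter = (row.get(chapter_column) or "").strip().upper()
        if not chapter:
            if not code:
                warnings.warn(f"{path}, row {rowno}: no code or chapter, skipped",
                              stacklevel=2)
                continue
            chapter = code[0].upper()
        out.append(CodeDescriptionEntry(code, chapter, desc))
    return out


# ---------------------------------------------------------------------------
# health topics


def read_topics(
    path: str | Path,
    mapping_path: str | Path,
    *,
    inventory: Sequence[str] = DEFAULT_INVENTORY,
    allowlist: Sequence[str] = DEFAULT_SECTION_ALLOWLIST,
) -> tuple[list[HealthTopic], TopicCodeMap]:
    """Read health topics (JSON-lines) plus a topic->chapter mapping CSV.

    Each JSON line is ``{"topic_id": ..., "sections": {name: prose, ...}}``.
    Sections off the allow-list are dropped.  Topics with no mapped chapter
    are excluded with a warning; a mapping row naming an unknown topic raises.
    """
    topics: list[HealthTopic] = []
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            record = json.loads(line)
            topics.append(HealthTopic(record["topic_id"], record["sections"]))
    known = {t.topic_id for t in topics}

    inventory_set = set(inventory)
    mapping: TopicCodeMap = {}
    with open(mapping_path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        for rowno, row in enumerate(reader, start=2):
            tid = row["topic_id"].strip()
            if tid not in known:
                raise CorpusFormatError(
                    f"{mapping_path}, row {rowno}: mapping references unknown topic {tid!r}"
                )
            letters = {c.strip().upper() for c in row["codes"].split(";") if c.strip()}
            bad = letters - inventory_set
            if bad:
                raise CorpusFormatError(
                    f"{mapping_path}, row {rowno}: letters {sorted(bad)} not in inventory"
                )
            mapping[tid] = frozenset(letters) | mapping.get(tid, frozenset())

    filtered: list[HealthTopic] = []
    for t in topics:
        if not mapping.get(t.topic_id):
            warnings.warn(f"topic {t.topic_id!r} has no mapped chapter; excluded",
                          stacklevel=2)
            continue
        filtered.append(t.filtered(allowlist))
    mapping = {tid: letters for tid, letters in mapping.items()
               if any(t.topic_id == tid for t in filtered)}
    return filtered, mapping


# ---------------------------------------------------------------------------
# reference dataset summary fixture

# Printed summary of the reference consultation dataset: per-chapter transcript
# counts, the per-consultation code-count distribution, and consultation
# duration buckets.  NOTE: the printed code-count rows sum to 240 while the
# printed unique-consultation total is 239; both printed values are stored
# verbatim (see `load_table1_fixture` docstring).
_TABLE1 = {
    "per_chapter_counts": {
        "A": 14, "B": 8, "D": 44, "F": 5, "H": 11, "K": 32, "L": 65, "N": 20,
        "P": 50, "R": 37, "S": 32, "T": 24, "U": 18, "W": 11, "X": 14, "Y": 7,
    },
    "per_chapter_percent": {
        "A": 5.9, "B": 3.3, "D": 18.4, "F": 2.1, "H": 4.6, "K": 13.4, "L": 27.2,
        "N": 8.4, "P": 20.9, "R": 15.5, "S": 13.4, "T": 10.0, "U": 7.5,
        "W": 4.6, "X": 5.9, "Y": 2.9,
    },
    "total_code_labels": 392,
    "total_unique_consultations": 239,
    "code_count_distribution": {"0": 2, "1": 128, "2": 62, "3": 40, "4+": 8},
    "duration_minutes_distribution": {
        "<5": 13, "5-10": 79, "10-15": 82, "15-20": 52, "20-35": 13,
    },
}


@dataclass(frozen=True)
class Table1Fixture:
    """Printed dataset summary with derived consistency checks on demand."""

    per_chapter_counts: dict[str, int]
    per_chapter_percent: dict[str, float]
    total_code_labels: int
    total_unique_consultations: int
    code_count_distribution: dict[str, int]
    duration_minutes_distribution: dict[str, int]

    def chapter_count_sum(self) -> int:
        return sum(self.per_chapter_counts.values())

    def multi_label_consultations(self) -> int:
        """Consultations with two or more assigned codes."""
        return sum(v for k, v in self.code_count_distribution.items() if k not in ("0", "1"))

    def duration_sum(self) -> int:
        return sum(self.duration_minutes_distribution.values())

    def code_count_sum(self) -> int:
        """Sum of the printed code-count rows.

        This is 240, one more than the printed unique-consultation total of
        239 — an internal inconsistency of the printed table, preserved
        verbatim rather than corrected.
        """
        return sum(self.code_count_distribution.values())


def load_table1_fixture() -> Table1Fixture:
    """Return the packaged summary of the reference consultation dataset."""
    return Table1Fixture(**{k: dict(v) if isinstance(v, dict) else v
                            for k, v in _TABLE1.items()})
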