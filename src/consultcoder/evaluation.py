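"""Set-valued evaluation: macro P/R/F1, bootstrap inference, splits, baseline.

Gold labels and predictions are both sets of chapter letters per document.
Per chapter, a document contributes a true positive when the chapter is in
both sets, a false positive when predicted only, a false negative when gold
only; precision/recall use the zero-division -> 0 convention and the macro
average is the unweighted mean over the configured inventory.

Uncertainty uses the percentile document bootstrap; two systems are compared
with a one-sided paired bootstrap test on the macro-F1 difference (ties
counted as non-positive).  Splitting is stratified by each document's
alphabetically first gold chapter (documents with no label stratify under
``"none"``), matching the label-selection rule of multiclass training.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass
from pathlib import Path
from typing import Callable, Mapping, Sequence

import numpy as np

from consultcoder.classifiers import PredictionSet
from consultcoder.corpus_io import LabeledCorpus

__all__ = [
    "MetricsReport",
    "BootstrapCI",
    "SignificanceResult",
    "SplitSpec",
    "macro_prf",
    "bootstrap_ci",
    "paired_bootstrap",
    "stratified_split",
    "kfold",
    "random_baseline",
]

GoldLabels = Mapping[str, frozenset[str] | set[str]]


@dataclass(frozen=True)
class MetricsReport:
    """Per-chapter and macro precision/recall/F1 over predicted label sets."""

    inventory: tuple[str, ...]
    per_class: dict[str, tuple[float, float, float]]  # letter -> (P, R, F1)
    macro_precision: float
    macro_recall: float
    macro_f1: float

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps({
            "inventory": list(self.inventory),
            "per_class": {c: list(v) for c, v in self.per_class.items()},
            "macro": {
                "precision": self.macro_precision,
                "recall": self.macro_recall,
                "f1": self.macro_f1,
            },
        }, indent=2), encoding="utf-8")

    def to_csv(self, path: str | Path) -> None:
        with open(path, "w", newline="", encoding="utf-8") as fh:
            writer = csv.writer(fh)
            writer.writerow(["class", "precision", "recall", "f1"])
            for c in self.inventory:
                p, r, f = self.per_class[c]
                writer.writerow([c, p, r, f])
            writer.writerow(["macro", self.macro_precision,
                             self.macro_recall, self.macro_f1])


@dataclass(frozen=True)
class BootstrapCI:
    lower: float
    upper: float
    replicates: int
    seed: int

    def __post_init__(self) -> None:
        if self.lower > self.upper:
            raise ValueError("CI lower bound exceeds upper bound")


@dataclass(frozen=True)
class SignificanceResult:
    """One-sided paired bootstrap comparison of two systems' macro F1."""

    delta_f1: float
    p_value: float
    replicates: int
    seed: int


@dataclass(frozen=True)
class SplitSpec:
    train_ids: tuple[str, ...]
    test_ids: tuple[str, ...]
    test_fraction: float
    seed: int
    stratify_key: str = "first_alphabetical_code"


def _check_ids(gold: GoldLabels, pred: Mapping[str, object], what: str) -> None:
    if set(gold) != set(pred):
        only_gold = sorted(set(gold) - set(pred))[:5]
        only_pred = sorted(set(pred) - set(gold))[:5]
        raise ValueError(
            f"{what}: document ids differ (gold-only {only_gold}, "
            f"pred-only {only_pred})"
        )


def _f1(p: float, r: float) -> float:
    return 0.0 if p + r == 0 else 2 * p * r / (p + r)


def macro_prf(gold: GoldLabels, pred: PredictionSet,
              inventory: Sequence[str]) -> MetricsReport:
    """Macro-averaged precision/recall/F1 from per-chapter set membership."""
    _check_ids(gold, pred, "macro_prf")
    inventory = tuple(sorted(inventory))
    per_class: dict[str, tuple[float, float, float]] = {}
    for c in inventory:
        tp = fp = fn = 0
        for did in gold:
            in_gold = c in gold[did]
            in_pred = c in pred[did]
            tp += in_gold and in_pred
            fp += in_pred and not in_gold
            fn += in_gold and not in_pred
        p = tp / (tp + fp) if tp + fp else 0.0
        r = tp / (tp + fn) if tp + fn else 0.0
        per_class[c] = (p, r, _f1(p, r))
    n = len(inventory)
    return MetricsReport(
        inventory=inventory,
        per_class=per_class,
        macro_precision=sum(v[0] for v in per_class.values()) / n,
        macro_recall=sum(v[1] for v in per_class.values()) / n,
        macro_f1=sum(v[2] for v in per_class.values()) / n,
    )


def bootstrap_ci(
    gold: GoldLabels,
    pred: PredictionSet,
    inventory: Sequence[str],
    metric: Callable[[MetricsReport], float] = lambda r: r.macro_f1,
    B: int = 1000,
    level: float = 0.95,
    seed: int = 0,
) -> BootstrapCI:
    """Percentile bootstrap CI over resamples of document ids with replacement."""
    if B < 1:
        raise ValueError("B must be >= 1")
    if len(gold) < 2:
        raise ValueError("bootstrap needs at least 2 documents")
    _check_ids(gold, pred, "bootstrap_ci")
    ids = sorted(gold)
    rng = np.random.default_rng(seed)
    values = np.empty(B)
    for b in range(B):
        sample = rng.choice(len(ids), size=len(ids), replace=True)
        g = {f"r{i}": frozenset(gold[ids[j]]) for i, j in enumerate(sample)}
        p = {f"r{i}": pred[ids[j]] for i, j in enumerate(sample)}
        values[b] = metric(macro_prf(g, p, inventory))
    alpha = (1 - level) / 2
    lo, hi = np.quantile(values, [alpha, 1 - alpha])
    return BootstrapCI(float(lo), float(hi), B, seed)


def paired_bootstrap(
    gold: GoldLabels,
    pred_a: PredictionSet,
    pred_b: PredictionSet,
    inventory: Sequence[str],
    B: int = 1000,
    seed: int = 0,
) -> SignificanceResult:
    """One-sided paired bootstrap: does system A beat system B on macro F1?

    ``p`` = fraction of B paired resamples in which the F1 difference is
    <= 0 (ties counted against A).
    """
    if B < 1:
        raise ValueError("B must be >= 1")
    _check_ids(gold, pred_a, "paired_bootstrap (system A)")
    _check_ids(gold, pred_b, "paired_bootstrap (system B)")
    ids = sorted(gold)
    observed = (macro_prf(gold, pred_a, inventory).macro_f1
                - macro_prf(gold, pred_b, inventory).macro_f1)
    rng = np.random.default_rng(seed)
    n_nonpos = 0
    for _ in range(B):
        sample = rng.choice(len(ids), size=len(ids), replace=True)
        g = {f"r{i}": frozenset(gold[ids[j]]) for i, j in enumerate(sample)}
        pa = {f"r{i}": pred_a[ids[j]] for i, j in enumerate(sample)}
        pb = {f"r{i}": pred_b[ids[j]] for i, j in enumerate(sample)}
        delta = (macro_prf(g, pa, inventory).macro_f1
                 - macro_prf(g, pb, inventory).macro_f1)
        if delta <= 0:
            n_nonpos += 1
    return SignificanceResult(float(observed), n_nonpos / B, B, seed)


def _strata(corpus: LabeledCorpus) -> dict[str, list[str]]:
    strata: dict[str, list[str]] = {}
    for t in corpus.transcripts:
        codes = sorted(corpus.label_set(t.id))
        key = codes[0] if codes else "none"
        strata.setdefault(key, []).append(t.id)
    return strata


def stratified_split(corpus: LabeledCorpus, test_fraction: float = 0.2,
                     seed: int = 0) -> SplitSpec:
    """Stratified train/test split by first-alphabetical gold chapter.

    Test sizes per stratum use proportional allocation with largest-remainder
    rounding so the overall test size is ``round(n * test_fraction)``;
    documents within a stratum are shuffled with the seed.
    """
    if not corpus.transcripts:
        raise ValueError("cannot split an empty corpus")
    if not 0 < test_fraction < 1:
        raise ValueError("test_fraction must be in (0, 1)")
    rng = np.random.default_rng(seed)
    strata = _strata(corpus)
    n = len(corpus.transcripts)
    target_total = round(n * test_fraction)

    keys = sorted(strata)
    exact = {k: len(strata[k]) * test_fraction for k in keys}
    base = {k: int(np.floor(exact[k])) for k in keys}
    remainder = target_total - sum(base.values())
    # largest remainders first; ties by stratum key for determinism
    by_frac = sorted(keys, key=lambda k: (-(exact[k] - base[k]), k))
    for k in by_frac[:max(remainder, 0)]:
        base[k] += 1

    test_ids: list[str] = []
    train_ids: list[str] = []
    for k in keys:
        members = sorted(strata[k])
        order = rng.permutation(len(members))
        take = min(base[k], len(members))
        test_ids.extend(members[i] for i in order[:take])
        train_ids.extend(members[i] for i in order[take:])
    return SplitSpec(tuple(sorted(train_ids)), tuple(sorted(test_ids)),
                     test_fraction, seed)


def kfold(corpus: LabeledCorpus, k: int = 5,
          seed: int = 0) -> list[tuple[tuple[str, ...], tuple[str, ...]]]:
    """Stratified k-fold partition (same stratification key as the split).

    Returns ``[(train_ids, valid_ids), ...]``; every id validates exactly
    once and fold sizes differ by at most one.
    """
    n = len(corpus.transcripts)
    if k < 2:
        raise ValueError("k must be >= 2")
    if k > n:
        raise ValueError(f"k={k} exceeds corpus size {n}")
    rng = np.random.default_rng(seed)
    folds: list[list[str]] = [[] for _ in range(k)]
    # deal stratum members round-robin into folds, rotating the starting fold
    # so small strata do not all land in fold 0
    offset = 0
    for key in sorted(_strata(corpus)):
        members = sorted(_strata(corpus)[key])
        order = rng.permutation(len(members))
        for i, j in enumerate(order):
            folds[(offset + i) % k].append(members[j])
        offset += len(members)
    all_ids = {t.id for t in corpus.transcripts}
    out = []
    for fold in folds:
        valid = tuple(sorted(fold))
        train = tuple(sorted(all_ids - set(fold)))
        out.append((train, valid))
    return out


def random_baseline(ids: Sequence[str], inventory: Sequence[str],
                    q: float = 0.5, seed: int = 0) -> PredictionSet:
    """Assign each chapter to each document independently with probability q."""
    if not 0 <= q <= 1:
        raise ValueError("q must be in [0, 1]")
    rng = np.random.default_rng(seed)
    inventory = tuple(sorted(inventory))
    out: PredictionSet = {}
    for did in ids:
        draws = rng.random(len(inventory))
        out[did] = frozenset(c for c, u in zip(inventory, draws) if u < q)
    return out
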