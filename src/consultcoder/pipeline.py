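"""End-to-end experiment protocols: conventional, distant and ablation runs.

Three protocols cover the study designs for chapter coding:

* ``conventional`` — supervised learning on labelled transcripts: stratified
  80/20 split, fivefold cross-validation on the training split for
  hyperparameters, a final fit on the training split, metrics on train,
  validation and test;
* ``distant`` — train on per-chapter surrogate documents (code-description
  keywords and/or health-topic prose) and evaluate on the full labelled
  corpus, which is repurposed as a validation set since it played no part in
  training;
* ``ablation`` — the identical pipeline run twice, once on both speakers'
  text and once on the clinician's half only, compared with a one-sided
  paired bootstrap test on macro F1.

Every run is fully determined by an :class:`ExperimentManifest` (serialized
alongside results) and a seed.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import yaml

from consultcoder.classifiers import (
    PredictionSet,
    predict_centroid,
    predict_margin,
    predict_nb,
    train_centroid,
    train_margin,
    train_nb,
)
from consultcoder.corpus_io import LabeledCorpus
from consultcoder.distant_supervision import DistantCorpus, drop_class
from consultcoder.evaluation import (
    BootstrapCI,
    MetricsReport,
    SignificanceResult,
    bootstrap_ci,
    kfold,
    macro_prf,
    paired_bootstrap,
    stratified_split,
)
from consultcoder.preprocess import (
    StopwordInventory,
    Vocabulary,
    build_vocabulary,
    extract_text,
    remove_stopwords,
    tokenize,
    vectorize_corpus,
)

__all__ = [
    "ExperimentManifest",
    "ExperimentReport",
    "AblationReport",
    "run_conventional",
    "run_distant",
    "run_ablation",
]

logger = logging.getLogger("consultcoder")

_CLASSIFIERS = ("nb", "centroid", "svm")
_KINDS = ("conventional", "distant", "ablation")
_SUPERVISION = ("transcripts", "icpc2", "cks", "combined")


@dataclass(frozen=True)
class ExperimentManifest:
    """Everything that determines a run; serialized next to its results."""

    kind: str = "conventional"
    classifier: str = "nb"
    mode: str = "multiclass"
    supervision: str = "transcripts"
    stopword_lists: tuple[str, ...] = ("english", "medical", "custom")
    speaker_mode: str = "both"
    drop_class_a: bool = False
    max_features: int = 5000
    alpha: float = 1.0
    svm_grid_C: tuple[float, ...] = (0.1, 1.0, 10.0)
    svm_grid_gamma: tuple[float, ...] = (0.001, 0.01, 0.1)
    test_fraction: float = 0.2
    cv_folds: int = 5
    bootstrap_B: int = 1000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kind not in _KINDS:
            raise ValueError(f"kind must be one of {_KINDS}")
        if self.classifier not in _CLASSIFIERS:
            raise ValueError(f"classifier must be one of {_CLASSIFIERS}")
        if self.supervision not in _SUPERVISION:
            raise ValueError(f"supervision must be one of {_SUPERVISION}")

    def to_yaml(self, path: str | Path) -> None:
        payload = asdict(self)
        for key in ("stopword_lists", "svm_grid_C", "svm_grid_gamma"):
            payload[key] = list(payload[key])
        Path(path).write_text(yaml.safe_dump(payload, sort_keys=True),
                              encoding="utf-8")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "ExperimentManifest":
        payload = yaml.safe_load(Path(path).read_text(encoding="utf-8"))
        for key in ("stopword_lists", "svm_grid_C", "svm_grid_gamma"):
            if key in payload:
                payload[key] = tuple(payload[key])
        return cls(**payload)


@dataclass
class ExperimentReport:
    """Results of one protocol run."""

    manifest: ExperimentManifest
    validation: MetricsReport | None
    train: MetricsReport | None
    test: MetricsReport
    test_ci: BootstrapCI | None
    predictions: PredictionSet
    hyperparameters: dict = field(default_factory=dict)

    def save(self, directory: str | Path) -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        self.manifest.to_yaml(directory / "manifest.yaml")
        self.test.to_json(directory / "test_metrics.json")
        self.test.to_csv(directory / "test_metrics.csv")
        if self.train is not None:
            self.train.to_json(directory / "train_metrics.json")
        if self.validation is not None:
            self.validation.to_json(directory / "validation_metrics.json")
        (directory / "predictions.json").write_text(json.dumps(
            {tid: sorted(codes) for tid, codes in sorted(self.predictions.items())},
            indent=2), encoding="utf-8")
        extras = dict(self.hyperparameters)
        if self.test_ci is not None:
            extras["test_f1_ci"] = [self.test_ci.lower, self.test_ci.upper]
        (directory / "run_info.json").write_text(json.dumps(extras, indent=2),
                                                 encoding="utf-8")


@dataclass
class AblationReport:
    """Paired both-speakers vs clinician-only reports plus the significance test."""

    both: ExperimentReport
    clinician_only: ExperimentReport
    significance: SignificanceResult


def _featurize_corpus(
    corpus: LabeledCorpus,
    manifest: ExperimentManifest,
    stopwords: StopwordInventory,
) -> dict[str, list[str]]:
    """id -> post-stopword token sequence under the manifest's speaker mode."""
    out: dict[str, list[str]] = {}
    for t in corpus.transcripts:
        tokens = tokenize(extract_text(t, manifest.speaker_mode))
        out[t.id] = remove_stopwords(tokens, stopwords, manifest.stopword_lists)
    return out


def _train_and_predict(
    manifest: ExperimentManifest,
    train_vectors: np.ndarray,
    train_labels: Sequence,
    inventory: Sequence[str],
    eval_sets: Mapping[str, tuple[np.ndarray, Sequence[str]]],
    *,
    C: float = 1.0,
    gamma: float | str = "scale",
) -> dict[str, PredictionSet]:
    """Fit the manifest's classifier once; predict on each named eval set."""
    if manifest.classifier == "nb":
        model = train_nb(train_vectors, train_labels, inventory=inventory,
                         mode=manifest.mode, alpha=manifest.alpha)
        predict = lambda X, ids: predict_nb(model, X, ids)
    elif manifest.classifier == "centroid":
        model = train_centroid(train_vectors, train_labels, inventory=inventory)
        predict = lambda X, ids: predict_centroid(model, X, ids)
    else:
        model = train_margin(train_vectors, train_labels, inventory=inventory,
                             mode=manifest.mode, C=C, gamma=gamma)
        predict = lambda X, ids: predict_margin(model, X, ids)
    return {name: predict(X, ids) for name, (X, ids) in eval_sets.items()}


def _gold(corpus: LabeledCorpus, ids: Sequence[str]) -> dict[str, frozenset[str]]:
    return {tid: corpus.label_set(tid) for tid in ids}


def _select_svm_hyperparameters(
    manifest: ExperimentManifest,
    corpus_train: LabeledCorpus,
    token_docs: Mapping[str, list[str]],
) -> tuple[float, float | str, list[MetricsReport]]:
    """Grid search C x gamma by mean cross-validation macro F1.

    Ties break to the smallest C, then the smallest gamma.  Returns the
    winning pair and the per-fold reports of the winning configuration.
    """
    folds = kfold(corpus_train, k=manifest.cv_folds, seed=manifest.seed)
    best: tuple[float, float | str] | None = None
    best_score = -1.0
    best_reports: list[MetricsReport] = []
    for C in sorted(manifest.svm_grid_C):
        for gamma in sorted(manifest.svm_grid_gamma):
            reports = _cv_reports(manifest, corpus_train, token_docs, folds,
                                  C=C, gamma=gamma)
            score = float(np.mean([r.macro_f1 for r in reports]))
            logger.info("cv grid C=%g gamma=%s mean_macro_f1=%.4f", C, gamma, score)
            if score > best_score:
                best, best_score, best_reports = (C, gamma), score, reports
    assert best is not None
    return best[0], best[1], best_reports


def _cv_reports(
    manifest: ExperimentManifest,
    corpus_train: LabeledCorpus,
    token_docs: Mapping[str, list[str]],
    folds: Sequence[tuple[tuple[str, ...], tuple[str, ...]]],
    *,
    C: float = 1.0,
    gamma: float | str = "scale",
) -> list[MetricsReport]:
    reports = []
    for train_ids, valid_ids in folds:
        vocab = build_vocabulary([token_docs[i] for i in train_ids],
                                 manifest.max_features)
        Xtr = vectorize_corpus([token_docs[i] for i in train_ids], vocab)
        Xva = vectorize_corpus([token_docs[i] for i in valid_ids], vocab)
        ytr = [corpus_train.label_set(i) for i in train_ids]
        preds = _train_and_predict(
            manifest, Xtr, ytr, corpus_train.inventory,
            {"valid": (Xva, list(valid_ids))}, C=C, gamma=gamma,
        )["valid"]
        reports.append(macro_prf(_gold(corpus_train, valid_ids), preds,
                                 corpus_train.inventory))
    return reports


def _mean_report(reports: Sequence[MetricsReport]) -> MetricsReport:
    inventory = reports[0].inventory
    per_class = {
        c: tuple(float(np.mean([r.per_class[c][j] for r in reports]))
                 for j in range(3))
        for c in inventory
    }
    return MetricsReport(
        inventory=inventory,
        per_class=per_class,
        macro_precision=float(np.mean([r.macro_precision for r in reports])),
        macro_recall=float(np.mean([r.macro_recall for r in reports])),
        macro_f1=float(np.mean([r.macro_f1 for r in reports])),
    )


def run_conventional(
    corpus: LabeledCorpus,
    manifest: ExperimentManifest,
    stopwords: StopwordInventory | None = None,
) -> ExperimentReport:
    """Supervised protocol: 80/20 stratified split, fivefold CV, final fit.

    Reports validation (mean over CV folds), train and test metrics with a
    percentile bootstrap CI on the test macro F1.
    """
    stopwords = stopwords or StopwordInventory.default()
    if manifest.drop_class_a and "A" in corpus.inventory:
        corpus = drop_class(corpus, "A")
    token_docs = _featurize_corpus(corpus, manifest, stopwords)
    split = stratified_split(corpus, manifest.test_fraction, manifest.seed)
    corpus_train = corpus.subset(split.train_ids)
    logger.info("split: %d train / %d test", len(split.train_ids),
                len(split.test_ids))

    missing = [c for c in corpus.inventory
               if not any(c in corpus.label_set(i) for i in split.train_ids)]
    if missing:
        raise ValueError(
            f"class(es) {missing} absent from the training split; enlarge the "
            "corpus, lower test_fraction, or drop the class"
        )

    hyper: dict = {}
    if manifest.classifier == "svm":
        C, gamma, cv_reports = _select_svm_hyperparameters(
            manifest, corpus_train, token_docs)
        hyper = {"C": C, "gamma": gamma}
    else:
        C, gamma = 1.0, "scale"
        folds = kfold(corpus_train, k=manifest.cv_folds, seed=manifest.seed)
        cv_reports = _cv_reports(manifest, corpus_train, token_docs, folds)

    vocab = build_vocabulary([token_docs[i] for i in split.train_ids],
                             manifest.max_features)
    logger.info("vocabulary: %d n-grams", len(vocab))
    Xtr = vectorize_corpus([token_docs[i] for i in split.train_ids], vocab)
    Xte = vectorize_corpus([token_docs[i] for i in split.test_ids], vocab)
    ytr = [corpus.label_set(i) for i in split.train_ids]
    preds = _train_and_predict(
        manifest, Xtr, ytr, corpus.inventory,
        {"train": (Xtr, list(split.train_ids)),
         "test": (Xte, list(split.test_ids))},
        C=C, gamma=gamma,
    )
    train_report = macro_prf(_gold(corpus, split.train_ids), preds["train"],
                             corpus.inventory)
    test_report = macro_prf(_gold(corpus, split.test_ids), preds["test"],
                            corpus.inventory)
    ci = bootstrap_ci(_gold(corpus, split.test_ids), preds["test"],
                      corpus.inventory, B=manifest.bootstrap_B,
                      seed=manifest.seed)
    logger.info("test macro F1 = %.4f (CI %.4f-%.4f)", test_report.macro_f1,
                ci.lower, ci.upper)
    return ExperimentReport(
        manifest=manifest,
        validation=_mean_report(cv_reports),
        train=train_report,
        test=test_report,
        test_ci=ci,
        predictions=preds["test"],
        hyperparameters=hyper,
    )


def run_distant(
    distant_corpus: DistantCorpus,
    eval_corpus: LabeledCorpus,
    manifest: ExperimentManifest,
    stopwords: StopwordInventory | None = None,
) -> ExperimentReport:
    """Distant protocol: train on per-chapter surrogate documents, evaluate on
    the whole labelled corpus (repurposed as a validation set)."""
    stopwords = stopwords or StopwordInventory.default()
    if manifest.drop_class_a and "A" in distant_corpus.inventory:
        distant_corpus = drop_class(distant_corpus, "A")
    if manifest.drop_class_a and "A" in eval_corpus.inventory:
        eval_corpus = drop_class(eval_corpus, "A")
    if distant_corpus.inventory != eval_corpus.inventory:
        raise ValueError(
            f"inventory mismatch: distant {distant_corpus.inventory} vs "
            f"eval {eval_corpus.inventory}"
        )
    texts, letters = distant_corpus.texts_and_labels()
    train_docs = [
        remove_stopwords(tokenize(text), stopwords, manifest.stopword_lists)
        for text in texts
    ]
    vocab = build_vocabulary(train_docs, manifest.max_features)
    logger.info("distant vocabulary: %d n-grams from %d class documents",
                len(vocab), len(train_docs))
    Xtr = vectorize_corpus(train_docs, vocab)
    eval_tokens = _featurize_corpus(eval_corpus, manifest, stopwords)
    ids = eval_corpus.ids
    Xev = vectorize_corpus([eval_tokens[i] for i in ids], vocab)
    preds = _train_and_predict(
        manifest, Xtr, letters, distant_corpus.inventory,
        {"eval": (Xev, ids)},
    )["eval"]
    report = macro_prf(_gold(eval_corpus, ids), preds, eval_corpus.inventory)
    ci = bootstrap_ci(_gold(eval_corpus, ids), preds, eval_corpus.inventory,
                      B=manifest.bootstrap_B, seed=manifest.seed)
    logger.info("distant eval macro F1 = %.4f (CI %.4f-%.4f)", report.macro_f1,
                ci.lower, ci.upper)
    return ExperimentReport(
        manifest=manifest, validation=report, train=None, test=report,
        test_ci=ci, predictions=preds,
    )


def run_ablation(
    corpus: LabeledCorpus,
    manifest: ExperimentManifest,
    stopwords: StopwordInventory | None = None,
) -> AblationReport:
    """Speaker ablation: identical runs with both speakers vs clinician-only
    text, compared by a one-sided paired bootstrap on test macro F1."""
    if manifest.drop_class_a and "A" in corpus.inventory:
        corpus = drop_class(corpus, "A")
    both = run_conventional(
        corpus, replace(manifest, kind="ablation", speaker_mode="both"),
        stopwords)
    clin = run_conventional(
        corpus, replace(manifest, kind="ablation", speaker_mode="clinician_only"),
        stopwords)
    test_ids = sorted(both.predictions)
    sig = paired_bootstrap(
        _gold(corpus, test_ids), both.predictions, clin.predictions,
        corpus.inventory, B=manifest.bootstrap_B, seed=manifest.seed,
    )
    logger.info("ablation: F1 both=%.4f clinician_only=%.4f delta=%.4f p=%.4f",
                both.test.macro_f1, clin.test.macro_f1, sig.delta_f1,
                sig.p_value)
    return AblationReport(both=both, clinician_only=clin, significance=sig)
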