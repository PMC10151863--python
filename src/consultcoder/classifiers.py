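"""Multinomial naive Bayes, nearest centroid and RBF max-margin classifiers.

All three operate on n-gram count vectors and support the two assignment
modes used for chapter coding:

* ``multiclass`` — one classifier assigns the single most likely chapter;
  training documents with several gold chapters contribute their
  alphabetically first chapter as the training label.
* ``multilabel`` — one binary yes/no classifier per chapter, so a document
  can receive several chapters (or none).

Naive Bayes additionally exposes the per-feature class weights
P(class | feature), the quantity used to visualise which unigrams and
bigrams drive each chapter.

Ties anywhere (posterior, distance, decision value) break to the
alphabetically first chapter.  Predictions are deterministic given the
fitted state.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
from sklearn.svm import SVC

from consultcoder.preprocess import Vocabulary

__all__ = [
    "PredictionSet",
    "NaiveBayesModel",
    "CentroidModel",
    "MarginModel",
    "FeatureClassWeights",
    "train_nb",
    "predict_nb",
    "train_centroid",
    "predict_centroid",
    "train_margin",
    "predict_margin",
    "feature_class_weights",
    "first_alphabetical_label",
]

#: mapping document id -> set of predicted chapter letters
PredictionSet = dict[str, frozenset[str]]

_MODES = ("multilabel", "multiclass")


def _normalize_labels(labels: Sequence) -> list[frozenset[str]]:
    out = []
    for item in labels:
        if isinstance(item, str):
            out.append(frozenset({item}))
        else:
            out.append(frozenset(item))
    return out


def first_alphabetical_label(codes: Iterable[str]) -> str | None:
    """The multiclass training label: the alphabetically first gold chapter."""
    codes = sorted(codes)
    return codes[0] if codes else None


def vocabulary_hash(vocab: Vocabulary | None) -> str | None:
    if vocab is None:
        return None
    h = hashlib.sha256("\x00".join(vocab.ngrams).encode("utf-8"))
    return h.hexdigest()


def _check_vocab(model_hash: str | None, vocab: Vocabulary | None) -> None:
    if model_hash is not None and vocab is not None:
        if vocabulary_hash(vocab) != model_hash:
            raise ValueError("vocabulary hash mismatch: vectors are not on the "
                             "training vocabulary")


def _ids_or_default(n: int, ids: Sequence[str] | None) -> list[str]:
    if ids is None:
        return [str(i) for i in range(n)]
    if len(ids) != n:
        raise ValueError(f"{len(ids)} ids for {n} vectors")
    return list(ids)


# ---------------------------------------------------------------------------
# naive Bayes


@dataclass
class NaiveBayesModel:
    """Fitted multinomial naive Bayes state.

    ``multiclass``: one distribution per chapter — ``class_log_prior[c]`` and
    ``feature_log_prob[c]`` (alpha-smoothed multinomial over the vocabulary).
    ``multilabel``: per chapter a binary yes/no model; ``binary_log_prior``
    maps letter -> (log P(yes), log P(no)) and ``binary_feature_log_prob``
    maps letter -> a (2, V) array of smoothed log likelihoods [yes, no].
    """

    inventory: tuple[str, ...]
    mode: str
    alpha: float
    n_features: int
    class_log_prior: np.ndarray | None = None
    feature_log_prob: np.ndarray | None = None
    binary_log_prior: dict[str, tuple[float, float]] | None = None
    binary_feature_log_prob: dict[str, np.ndarray] | None = None
    vocab_hash: str | None = None

    def to_json(self, path: str | Path) -> None:
        payload: dict = {
            "model": "naive_bayes",
            "inventory": list(self.inventory),
            "mode": self.mode,
            "alpha": self.alpha,
            "n_features": self.n_features,
            "vocab_hash": self.vocab_hash,
        }
        if self.mode == "multiclass":
            payload["class_log_prior"] = self.class_log_prior.tolist()
            payload["feature_log_prob"] = self.feature_log_prob.tolist()
        else:
            payload["binary_log_prior"] = {
                c: list(v) for c, v in self.binary_log_prior.items()
            }
            payload["binary_feature_log_prob"] = {
                c: v.tolist() for c, v in self.binary_feature_log_prob.items()
            }
        Path(path).write_text(json.dumps(payload), encoding="utf-8")

    @classmethod
    def from_json(cls, path: str | Path) -> "NaiveBayesModel":
        payload = json.loads(Path(path).read_text(encoding="utf-8"))
        if payload.get("model") != "naive_bayes":
            raise ValueError(f"{path}: not a serialized naive Bayes model")
        model = cls(
            inventory=tuple(payload["inventory"]),
            mode=payload["mode"],
            alpha=payload["alpha"],
            n_features=payload["n_features"],
            vocab_hash=payload["vocab_hash"],
        )
        if model.mode == "multiclass":
            model.class_log_prior = np.asarray(payload["class_log_prior"])
            model.feature_log_prob = np.asarray(payload["feature_log_prob"])
        else:
            model.binary_log_prior = {
                c: (v[0], v[1]) for c, v in payload["binary_log_prior"].items()
            }
            model.binary_feature_log_prob = {
                c: np.asarray(v) for c, v in payload["binary_feature_log_prob"].items()
            }
        return model


def _smoothed_loglik(count_rows: np.ndarray, alpha: float) -> np.ndarray:
    """Alpha-smoothed multinomial log likelihoods, one row per class."""
    counts = count_rows + alpha
    return np.log(counts) - np.log(counts.sum(axis=1, keepdims=True))


def train_nb(
    vectors: np.ndarray,
    labels: Sequence,
    *,
    inventory: Sequence[str],
    mode: str = "multiclass",
    alpha: float = 1.0,
    vocab: Vocabulary | None = None,
) -> NaiveBayesModel:
    """Fit multinomial naive Bayes on count vectors.

    ``labels`` holds one gold label set (or a single letter) per row of
    ``vectors``.  Multiclass training uses the alphabetically first gold
    chapter of each document; unlabelled documents are excluded from
    multiclass training but count as negatives in multilabel training.
    Priors are the training label frequencies.
    """
    if mode not in _MODES:
        raise ValueError(f"mode must be one of {_MODES}")
    if alpha <= 0:
        raise ValueError("smoothing alpha must be positive")
    vectors = np.asarray(vectors, dtype=float)
    inventory = tuple(sorted(inventory))
    label_sets = _normalize_labels(labels)
    if len(label_sets) != vectors.shape[0]:
        raise ValueError("number of labels must match number of vectors")

    model = NaiveBayesModel(
        inventory=inventory, mode=mode, alpha=float(alpha),
        n_features=vectors.shape[1], vocab_hash=vocabulary_hash(vocab),
    )

    if mode == "multiclass":
        train_labels = [first_alphabetical_label(ls) for ls in label_sets]
        keep = [i for i, lbl in enumerate(train_labels) if lbl is not None]
        counts = np.zeros((len(inventory), vectors.shape[1]))
        n_per_class = np.zeros(len(inventory))
        idx = {c: i for i, c in enumerate(inventory)}
        for i in keep:
            lbl = train_labels[i]
            if lbl not in idx:
                raise ValueError(f"training label {lbl!r} outside inventory")
            counts[idx[lbl]] += vectors[i]
            n_per_class[idx[lbl]] += 1
        empty = [c for c, n in zip(inventory, n_per_class) if n == 0]
        if empty:
            raise ValueError(f"no training documents for class(es) {empty}")
        model.class_log_prior = np.log(n_per_class) - np.log(n_per_class.sum())
        model.feature_log_prob = _smoothed_loglik(counts, alpha)
    else:
        model.binary_log_prior = {}
        model.binary_feature_log_prob = {}
        n = len(label_sets)
        for c in inventory:
            pos = [i for i, ls in enumerate(label_sets) if c in ls]
            neg = [i for i in range(n) if c not in label_sets[i]]
            if not pos:
                raise ValueError(f"no positive training documents for class {c!r}")
            rows = np.vstack([
                vectors[pos].sum(axis=0),
                vectors[neg].sum(axis=0) if neg else np.zeros(vectors.shape[1]),
            ])
            model.binary_feature_log_prob[c] = _smoothed_loglik(rows, alpha)
            # no-negative degenerate case: P(yes) = 1
            p_yes = len(pos) / n
            with np.errstate(divide="ignore"):
                model.binary_log_prior[c] = (
                    float(np.log(p_yes)),
                    float(np.log1p(-p_yes)) if neg else -np.inf,
                )
    return model


def nb_posteriors(model: NaiveBayesModel, vectors: np.ndarray) -> np.ndarray:
    """Posterior matrix.

    Multiclass: (n_docs, n_classes) rows summing to 1.
    Multilabel: (n_docs, n_classes) of per-class P(yes | doc).
    """
    vectors = np.asarray(vectors, dtype=float)
    if vectors.ndim == 1:
        vectors = vectors[None, :]
    if vectors.shape[1] != model.n_features:
        raise ValueError(
            f"vectors have {vectors.shape[1]} features, model expects {model.n_features}"
        )
    if model.mode == "multiclass":
        joint = vectors @ model.feature_log_prob.T + model.class_log_prior
        joint -= joint.max(axis=1, keepdims=True)
        post = np.exp(joint)
        return post / post.sum(axis=1, keepdims=True)
    out = np.zeros((vectors.shape[0], len(model.inventory)))
    for j, c in enumerate(model.inventory):
        loglik = vectors @ model.binary_feature_log_prob[c].T  # (n, 2)
        log_prior = np.asarray(model.binary_log_prior[c])
        joint = loglik + log_prior
        m = joint.max(axis=1, keepdims=True)
        post = np.exp(joint - m)
        out[:, j] = post[:, 0] / post.sum(axis=1)
    return out


def predict_nb(
    model: NaiveBayesModel,
    vectors: np.ndarray,
    ids: Sequence[str] | None = None,
    *,
    threshold: float = 0.5,
    vocab: Vocabulary | None = None,
) -> PredictionSet:
    """Predict chapter sets: multiclass argmax (ties alphabetical) or
    multilabel ``P(yes) > threshold``.

    A zero count vector falls back to the priors: multiclass returns the
    highest-prior chapter, multilabel the chapters whose positive prior
    exceeds the threshold.
    """
    _check_vocab(model.vocab_hash, vocab)
    vectors = np.asarray(vectors, dtype=float)
    if vectors.ndim == 1:
        vectors = vectors[None, :]
    doc_ids = _ids_or_default(vectors.shape[0], ids)
    post = nb_posteriors(model, vectors)
    out: PredictionSet = {}
    if model.mode == "multiclass":
        # argmax with alphabetical tie-break: inventory is sorted, np.argmax
        # returns the first maximal index
        for did, row in zip(doc_ids, post):
            out[did] = frozenset({model.inventory[int(np.argmax(row))]})
    else:
        for did, row in zip(doc_ids, post):
            out[did] = frozenset(
                c for c, p in zip(model.inventory, row) if p > threshold
            )
    return out


@dataclass(frozen=True)
class FeatureClassWeights:
    """P(class | feature) matrix, classes x features; columns sum to 1."""

    inventory: tuple[str, ...]
    weights: np.ndarray

    def top_features(self, letter: str, vocab: Vocabulary, k: int = 20) -> list[tuple[str, float]]:
        """The k n-grams most associated with a chapter, for wordcloud-style
        inspection."""
        row = self.weights[self.inventory.index(letter)]
        order = np.argsort(-row)[:k]
        return [(vocab.ngrams[i], float(row[i])) for i in order]


def feature_class_weights(model: NaiveBayesModel) -> FeatureClassWeights:
    """P(c | w) ∝ P(w | c) P(c), normalized over classes for each feature."""
    if model.mode != "multiclass":
        raise ValueError("feature-class weights require a multiclass model")
    joint = np.exp(model.feature_log_prob) * np.exp(model.class_log_prior)[:, None]
    weights = joint / joint.sum(axis=0, keepdims=True)
    return FeatureClassWeights(model.inventory, weights)


# ---------------------------------------------------------------------------
# nearest centroid


@dataclass
class CentroidModel:
    """Per-chapter centroid (mean training vector); Euclidean prediction."""

    inventory: tuple[str, ...]
    centroids: np.ndarray
    vocab_hash: str | None = None

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps({
            "model": "nearest_centroid",
            "inventory": list(self.inventory),
            "centroids": self.centroids.tolist(),
            "vocab_hash": self.vocab_hash,
        }), encoding="utf-8")

    @classmethod
    def from_json(cls, path: str | Path) -> "CentroidModel":
        payload = json.loads(Path(path).read_text(encoding="utf-8"))
        if payload.get("model") != "nearest_centroid":
            raise ValueError(f"{path}: not a serialized nearest-centroid model")
        return cls(tuple(payload["inventory"]), np.asarray(payload["centroids"]),
                   payload["vocab_hash"])


def train_centroid(
    vectors: np.ndarray,
    labels: Sequence,
    *,
    inventory: Sequence[str],
    vocab: Vocabulary | None = None,
) -> CentroidModel:
    """Class centroids = arithmetic means of the class training vectors
    (multiclass labels: alphabetically first gold chapter)."""
    vectors = np.asarray(vectors, dtype=float)
    inventory = tuple(sorted(inventory))
    label_sets = _normalize_labels(labels)
    idx = {c: i for i, c in enumerate(inventory)}
    sums = np.zeros((len(inventory), vectors.shape[1]))
    counts = np.zeros(len(inventory))
    for vec, ls in zip(vectors, label_sets):
        lbl = first_alphabetical_label(ls)
        if lbl is None:
            continue
        if lbl not in idx:
            raise ValueError(f"training label {lbl!r} outside inventory")
        sums[idx[lbl]] += vec
        counts[idx[lbl]] += 1
    empty = [c for c, n in zip(inventory, counts) if n == 0]
    if empty:
        raise ValueError(f"no training documents for class(es) {empty}")
    return CentroidModel(inventory, sums / counts[:, None],
                         vocabulary_hash(vocab))


def predict_centroid(
    model: CentroidModel,
    vectors: np.ndarray,
    ids: Sequence[str] | None = None,
    *,
    vocab: Vocabulary | None = None,
) -> PredictionSet:
    """Assign each document the chapter of the nearest centroid (Euclidean);
    equidistant centroids break to the alphabetically first chapter."""
    _check_vocab(model.vocab_hash, vocab)
    vectors = np.asarray(vectors, dtype=float)
    if vectors.ndim == 1:
        vectors = vectors[None, :]
    if vectors.shape[1] != model.centroids.shape[1]:
        raise ValueError("vector length does not match centroid length")
    doc_ids = _ids_or_default(vectors.shape[0], ids)
    d2 = ((vectors[:, None, :] - model.centroids[None, :, :]) ** 2).sum(axis=2)
    out: PredictionSet = {}
    for did, row in zip(doc_ids, d2):
        out[did] = frozenset({model.inventory[int(np.argmin(row))]})
    return out


# ---------------------------------------------------------------------------
# RBF max-margin


@dataclass
class MarginModel:
    """RBF-kernel support vector classifier; numerics delegated to sklearn.

    Multiclass: a single one-vs-rest SVC, argmax decision value.
    Multilabel: one binary SVC per chapter, positive on decision value > 0.
    """

    inventory: tuple[str, ...]
    mode: str
    C: float
    gamma: float | str
    estimators: dict[str, SVC] | SVC | None = None
    vocab_hash: str | None = None


def train_margin(
    vectors: np.ndarray,
    labels: Sequence,
    *,
    inventory: Sequence[str],
    mode: str = "multiclass",
    C: float = 1.0,
    gamma: float | str = "scale",
    vocab: Vocabulary | None = None,
) -> MarginModel:
    if mode not in _MODES:
        raise ValueError(f"mode must be one of {_MODES}")
    vectors = np.asarray(vectors, dtype=float)
    inventory = tuple(sorted(inventory))
    label_sets = _normalize_labels(labels)
    model = MarginModel(inventory, mode, float(C), gamma,
                        vocab_hash=vocabulary_hash(vocab))
    if mode == "multiclass":
        train_labels = [first_alphabetical_label(ls) for ls in label_sets]
        keep = [i for i, lbl in enumerate(train_labels) if lbl is not None]
        y = [train_labels[i] for i in keep]
        if len(set(y)) < 2:
            raise ValueError("multiclass margin training needs at least two classes")
        clf = SVC(kernel="rbf", C=C, gamma=gamma, decision_function_shape="ovr")
        clf.fit(vectors[keep], y)
        model.estimators = clf
    else:
        estimators: dict[str, SVC] = {}
        for c in inventory:
            y = np.array([1 if c in ls else 0 for ls in label_sets])
            if y.sum() == 0:
                raise ValueError(f"no positive training documents for class {c!r}")
            if y.sum() == len(y):
                raise ValueError(f"no negative training documents for class {c!r}")
            clf = SVC(kernel="rbf", C=C, gamma=gamma)
            clf.fit(vectors, y)
            estimators[c] = clf
        model.estimators = estimators
    return model


def predict_margin(
    model: MarginModel,
    vectors: np.ndarray,
    ids: Sequence[str] | None = None,
    *,
    vocab: Vocabulary | None = None,
) -> PredictionSet:
    _check_vocab(model.vocab_hash, vocab)
    vectors = np.asarray(vectors, dtype=float)
    if vectors.ndim == 1:
        vectors = vectors[None, :]
    doc_ids = _ids_or_default(vectors.shape[0], ids)
    out: PredictionSet = {}
    if model.mode == "multiclass":
        clf: SVC = model.estimators
        preds = clf.predict(vectors)
        for did, p in zip(doc_ids, preds):
            out[did] = frozenset({str(p)})
    else:
        decision = {
            c: model.estimators[c].decision_function(vectors)
            for c in model.inventory
        }
        for i, did in enumerate(doc_ids):
            out[did] = frozenset(c for c in model.inventory if decision[c][i] > 0)
    return out
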