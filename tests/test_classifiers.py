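"""Naive Bayes, nearest centroid, RBF margin classifiers and feature weights.

The naive-Bayes contract is checked two ways: against a brute-force
enumeration of the smoothed multinomial posterior (written independently of
the implementation), and against scikit-learn's MultinomialNB on the same
data.
"""

import numpy as np
import pytest
from sklearn.naive_bayes import MultinomialNB

from consultcoder.classifiers import (
    feature_class_weights,
    first_alphabetical_label,
    nb_posteriors,
    predict_centroid,
    predict_margin,
    predict_nb,
    train_centroid,
    train_margin,
    train_nb,
    vocabulary_hash,
)
from consultcoder.preprocess import Vocabulary


def brute_force_posterior(class_counts, priors, query, alpha):
    """Independent oracle: smoothed multinomial posterior by direct evaluation.

    class_counts: dict label -> count vector; priors: dict label -> prob;
    query: count vector.  Likelihood of the query under each class is the
    product over features of P(w|c)^count with P(w|c) = (n_cw + alpha) /
    (n_c + alpha * V).
    """
    scores = {}
    V = len(query)
    for label, counts in class_counts.items():
        total = sum(counts)
        lik = priors[label]
        for w in range(V):
            p_w = (counts[w] + alpha) / (total + alpha * V)
            lik *= p_w ** query[w]
        scores[label] = lik
    norm = sum(scores.values())
    return {label: s / norm for label, s in scores.items()}


class TestNaiveBayesMulticlass:
    def test_hand_worked_two_class_posterior(self):
        # docs: X = "cough fever cough", Y = "rash itch"; unigram vocabulary
        # (cough, fever, rash, itch); alpha=1; query "cough":
        # P(cough|X) = (2+1)/(3+4) = 3/7, P(cough|Y) = (0+1)/(2+4) = 1/6
        # posterior(X) = (1/2 * 3/7) / (1/2 * 3/7 + 1/2 * 1/6) ~= 0.720
        X = np.array([[2, 1, 0, 0], [0, 0, 1, 1]])
        model = train_nb(X, ["X", "Y"], inventory=("X", "Y"), alpha=1.0)
        post = nb_posteriors(model, np.array([1, 0, 0, 0]))[0]
        expected = (0.5 * 3 / 7) / (0.5 * 3 / 7 + 0.5 * 1 / 6)
        assert post[0] == pytest.approx(expected, abs=1e-12)
        assert post[0] == pytest.approx(0.720, abs=5e-4)
        preds = predict_nb(model, np.array([1, 0, 0, 0]))
        assert preds["0"] == frozenset({"X"})

    def test_matches_brute_force_on_randomized_small_corpora(self):
        rng = np.random.default_rng(12345)
        for trial in range(50):
            n_classes = int(rng.integers(2, 5))
            n_docs = int(rng.integers(n_classes, 6))
            V = int(rng.integers(2, 7))
            alpha = float(rng.choice([0.5, 1.0, 2.0]))
            letters = [chr(ord("A") + i) for i in range(n_classes)]
            labels = letters + [str(rng.choice(letters))
                                for _ in range(n_docs - n_classes)]
            X = rng.integers(0, 5, size=(n_docs, V))
            model = train_nb(X, labels, inventory=letters, alpha=alpha)

            counts = {c: X[[i for i, l in enumerate(labels) if l == c]].sum(axis=0)
                      for c in letters}
            priors = {c: labels.count(c) / n_docs for c in letters}
            query = rng.integers(0, 4, size=V)
            expected = brute_force_posterior(counts, priors, query, alpha)
            got = nb_posteriors(model, query)[0]
            for j, c in enumerate(sorted(letters)):
                assert got[j] == pytest.approx(expected[c], abs=1e-9)

    def test_agrees_with_sklearn_multinomial_nb(self):
        rng = np.random.default_rng(7)
        X = rng.integers(0, 6, size=(20, 10))
        y = [str(rng.choice(["A", "B", "C"])) for _ in range(20)]
        model = train_nb(X, y, inventory=("A", "B", "C"), alpha=1.0)
        sk = MultinomialNB(alpha=1.0).fit(X, y)
        Xq = rng.integers(0, 6, size=(8, 10))
        np.testing.assert_allclose(nb_posteriors(model, Xq),
                                   sk.predict_proba(Xq), atol=1e-9)

    def test_symmetric_tie_breaks_alphabetically(self):
        X = np.array([[1, 0], [0, 1]])
        model = train_nb(X, ["B", "A"], inventory=("A", "B"))
        # query with identical likelihood under both classes
        preds = predict_nb(model, np.array([1, 1]))
        assert preds["0"] == frozenset({"A"})

    def test_zero_vector_falls_back_to_prior(self):
        X = np.array([[3, 0], [0, 3], [0, 2]])
        model = train_nb(X, ["A", "B", "B"], inventory=("A", "B"))
        preds = predict_nb(model, np.zeros(2))
        assert preds["0"] == frozenset({"B"})  # prior 2/3 beats 1/3

    def test_multiclass_training_uses_first_alphabetical_code(self):
        assert first_alphabetical_label({"P", "L"}) == "L"
        X = np.array([[5, 0], [0, 5]])
        model = train_nb(X, [{"P", "L"}, {"R"}], inventory=("L", "R"))
        # the {L, P} document trains chapter L, so feature 0 favours L
        assert predict_nb(model, np.array([3, 0]))["0"] == frozenset({"L"})
        # a chapter that is never the first-alphabetical label gets no
        # training document and is rejected
        with pytest.raises(ValueError, match="P"):
            train_nb(X, [{"P", "L"}, {"R"}], inventory=("L", "P", "R"))

    def test_class_without_training_document_rejected(self):
        X = np.array([[1, 0], [0, 1]])
        with pytest.raises(ValueError, match="C"):
            train_nb(X, ["A", "B"], inventory=("A", "B", "C"))


class TestNaiveBayesMultilabel:
    def test_threshold_rule(self):
        X = np.array([[4, 0, 0], [0, 4, 0], [2, 2, 0], [0, 0, 4]])
        labels = [{"L"}, {"P"}, {"L", "P"}, {"D"}]
        model = train_nb(X, labels, inventory=("D", "L", "P"),
                         mode="multilabel")
        preds = predict_nb(model, np.array([3, 3, 0]))
        assert preds["0"] == frozenset({"L", "P"})

    def test_no_positive_examples_rejected(self):
        X = np.array([[1, 0], [0, 1]])
        with pytest.raises(ValueError, match="P"):
            train_nb(X, [{"L"}, {"L"}], inventory=("L", "P"),
                     mode="multilabel")

    def test_one_hot_separable_data_reproduces_multiclass(self):
        rng = np.random.default_rng(3)
        # disjoint vocabularies per class -> both modes must agree
        X, y = [], []
        for i, c in enumerate("ABC"):
            for _ in range(5):
                row = np.zeros(6, dtype=int)
                row[2 * i:2 * i + 2] = rng.integers(2, 6, size=2)
                X.append(row)
                y.append({c})
        X = np.array(X)
        mc = train_nb(X, y, inventory=("A", "B", "C"), mode="multiclass")
        ml = train_nb(X, y, inventory=("A", "B", "C"), mode="multilabel")
        assert predict_nb(mc, X) == predict_nb(ml, X)

    def test_zero_vector_uses_positive_prior(self):
        X = np.array([[1, 0], [0, 1], [1, 1]])
        labels = [{"L"}, {"L"}, {"L", "P"}]
        model = train_nb(X, labels, inventory=("L", "P"), mode="multilabel")
        preds = predict_nb(model, np.zeros(2))
        assert preds["0"] == frozenset({"L"})  # P(L)=1 > 0.5 > P(P)=1/3


class TestFeatureClassWeights:
    def test_hand_worked_weight(self):
        # same arithmetic as the posterior example: balanced classes, feature
        # counts 2 vs 0, vocab 4 -> P(X|w) = (3/7)/(3/7 + 1/6)
        X = np.array([[2, 1, 0, 0], [0, 0, 1, 1]])
        model = train_nb(X, ["X", "Y"], inventory=("X", "Y"))
        w = feature_class_weights(model)
        assert w.weights[0, 0] == pytest.approx(
            (3 / 7) / (3 / 7 + 1 / 6), abs=1e-12)

    def test_uniform_model_gives_uniform_weights(self):
        X = np.ones((3, 4), dtype=int)
        model = train_nb(X, ["A", "B", "C"], inventory=("A", "B", "C"))
        w = feature_class_weights(model)
        np.testing.assert_allclose(w.weights, 1 / 3)

    def test_columns_sum_to_one(self):
        rng = np.random.default_rng(11)
        X = rng.integers(0, 5, size=(8, 9))
        y = [str(rng.choice(["A", "B", "C"])) for _ in range(8)]
        w = feature_class_weights(train_nb(X, y, inventory=("A", "B", "C")))
        np.testing.assert_allclose(w.weights.sum(axis=0), 1.0, atol=1e-12)

    def test_multilabel_model_rejected(self):
        X = np.array([[1, 0], [0, 1]])
        model = train_nb(X, [{"A"}, {"B"}], inventory=("A", "B"),
                         mode="multilabel")
        with pytest.raises(ValueError):
            feature_class_weights(model)


class TestCentroid:
    def test_query_on_a_centroid_returns_its_class(self):
        X = np.array([[2.0, 0.0], [4.0, 0.0], [0.0, 6.0]])
        model = train_centroid(X, ["X", "X", "Y"], inventory=("X", "Y"))
        np.testing.assert_allclose(model.centroids, [[3, 0], [0, 6]])
        assert predict_centroid(model, np.array([3.0, 0.0]))["0"] == frozenset({"X"})

    def test_one_feature_toy(self):
        model = train_centroid(np.array([[1.0], [3.0]]), ["X", "Y"],
                               inventory=("X", "Y"))
        assert predict_centroid(model, np.array([1.5]))["0"] == frozenset({"X"})

    def test_equidistant_tie_breaks_alphabetically(self):
        model = train_centroid(np.array([[0.0], [2.0]]), ["B", "A"],
                               inventory=("A", "B"))
        # centroids: A at 2.0, B at 0.0; query 1.0 is equidistant
        assert predict_centroid(model, np.array([1.0]))["0"] == frozenset({"A"})

    def test_empty_class_rejected(self):
        with pytest.raises(ValueError, match="Y"):
            train_centroid(np.array([[1.0]]), ["X"], inventory=("X", "Y"))


class TestMargin:
    def _separable(self):
        rng = np.random.default_rng(5)
        X, y = [], []
        for i, c in enumerate("AB"):
            for _ in range(10):
                row = np.zeros(4)
                row[2 * i:2 * i + 2] = rng.integers(3, 8, size=2)
                X.append(row)
                y.append(c)
        return np.array(X), y

    def test_separable_training_points_recovered(self):
        X, y = self._separable()
        model = train_margin(X, y, inventory=("A", "B"), C=10.0)
        preds = predict_margin(model, X)
        assert all(preds[str(i)] == frozenset({y[i]}) for i in range(len(y)))

    def test_multilabel_all_negative_gives_empty_set(self):
        X, y = self._separable()
        labels = [{c} for c in y]
        model = train_margin(X, labels, inventory=("A", "B"),
                             mode="multilabel", C=10.0)
        far = np.full(4, 50.0)  # far from all training mass
        preds = predict_margin(model, far)
        assert isinstance(preds["0"], frozenset)

    def test_refit_determinism(self):
        X, y = self._separable()
        m1 = train_margin(X, y, inventory=("A", "B"), C=1.0, gamma=0.1)
        m2 = train_margin(X, y, inventory=("A", "B"), C=1.0, gamma=0.1)
        assert predict_margin(m1, X) == predict_margin(m2, X)

    def test_single_class_input_rejected(self):
        X = np.ones((4, 2))
        with pytest.raises(ValueError):
            train_margin(X, ["A"] * 4, inventory=("A",), mode="multiclass")


class TestSerialization:
    def test_nb_round_trip_and_vocabulary_guard(self, tmp_path):
        vocab = Vocabulary(("cough", "fever"), (2, 1), 2)
        X = np.array([[2, 0], [0, 2]])
        model = train_nb(X, ["A", "B"], inventory=("A", "B"), vocab=vocab)
        model.to_json(tmp_path / "m.json")
        from consultcoder.classifiers import NaiveBayesModel
        back = NaiveBayesModel.from_json(tmp_path / "m.json")
        assert predict_nb(back, X, vocab=vocab) == predict_nb(model, X)
        other = Vocabulary(("rash", "itch"), (1, 1), 2)
        with pytest.raises(ValueError, match="hash"):
            predict_nb(back, X, vocab=other)

    def test_vocabulary_hash_sensitivity(self):
        a = Vocabulary(("x", "y"), (1, 1), 2)
        b = Vocabulary(("x", "z"), (1, 1), 2)
        assert vocabulary_hash(a) != vocabulary_hash(b)
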