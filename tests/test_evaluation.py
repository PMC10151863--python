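"""Macro metrics, bootstrap inference, splits, folds and the random baseline.

macro_prf is validated against an independent brute-force confusion-matrix
implementation written here from the definitions.
"""

import numpy as np
import pytest

from consultcoder.corpus_io import LabeledCorpus, LabelSet, Transcript, Turn
from consultcoder.evaluation import (
    bootstrap_ci,
    kfold,
    macro_prf,
    paired_bootstrap,
    random_baseline,
    stratified_split,
)
from consultcoder.synthetic_data import (
    GeneratorConfig,
    LexiconSpec,
    generate_corpus,
    generate_lexicons,
)


def brute_force_macro(gold, pred, inventory):
    """Independent oracle: explicit confusion counts per class."""
    ps, rs, fs = [], [], []
    for c in sorted(inventory):
        tp = sum(1 for d in gold if c in gold[d] and c in pred[d])
        fp = sum(1 for d in gold if c not in gold[d] and c in pred[d])
        fn = sum(1 for d in gold if c in gold[d] and c not in pred[d])
        p = tp / (tp + fp) if tp + fp else 0.0
        r = tp / (tp + fn) if tp + fn else 0.0
        f = 2 * p * r / (p + r) if p + r else 0.0
        ps.append(p); rs.append(r); fs.append(f)
    n = len(inventory)
    return sum(ps) / n, sum(rs) / n, sum(fs) / n


def _corpus(n, labels_by_id=None, inventory=("D", "L")):
    transcripts = [Transcript(f"d{i}", (Turn("clinician", "hi"),))
                   for i in range(n)]
    labels = {}
    for i, t in enumerate(transcripts):
        codes = (labels_by_id or {}).get(t.id, frozenset({inventory[i % len(inventory)]}))
        labels[t.id] = LabelSet(t.id, frozenset(codes))
    return LabeledCorpus(transcripts, labels, inventory)


class TestMacroPrf:
    def test_perfect_prediction(self):
        gold = {"a": frozenset({"L"}), "b": frozenset({"D", "P"})}
        report = macro_prf(gold, dict(gold), ("D", "L", "P"))
        assert report.macro_precision == report.macro_recall == report.macro_f1 == 1.0

    def test_hand_worked_two_class_example(self):
        # gold {d1:{X}, d2:{X,Y}}, pred {d1:{X,Y}, d2:{Y}}:
        # class X: TP=1 (d1), FN=1 (d2), FP=0 -> P=1, R=1/2, F1=2/3
        # class Y: TP=1 (d2), FP=1 (d1), FN=0 -> P=1/2, R=1, F1=2/3
        gold = {"d1": frozenset({"X"}), "d2": frozenset({"X", "Y"})}
        pred = {"d1": frozenset({"X", "Y"}), "d2": frozenset({"Y"})}
        report = macro_prf(gold, pred, ("X", "Y"))
        assert report.macro_precision == pytest.approx(0.75)
        assert report.macro_recall == pytest.approx(0.75)
        assert report.macro_f1 == pytest.approx(2 / 3)

    def test_all_empty_predictions_zero_convention(self):
        gold = {"a": frozenset({"L"}), "b": frozenset({"D"})}
        pred = {"a": frozenset(), "b": frozenset()}
        report = macro_prf(gold, pred, ("D", "L"))
        assert report.macro_precision == report.macro_recall == report.macro_f1 == 0.0

    def test_id_mismatch_rejected(self):
        with pytest.raises(ValueError, match="ids differ"):
            macro_prf({"a": frozenset()}, {"b": frozenset()}, ("L",))

    def test_matches_brute_force_on_randomized_instances(self):
        rng = np.random.default_rng(99)
        inventory = ("A", "B", "C")
        for _ in range(200):
            n = int(rng.integers(1, 7))
            gold = {f"d{i}": frozenset(c for c in inventory if rng.random() < 0.4)
                    for i in range(n)}
            pred = {f"d{i}": frozenset(c for c in inventory if rng.random() < 0.4)
                    for i in range(n)}
            report = macro_prf(gold, pred, inventory)
            p, r, f = brute_force_macro(gold, pred, inventory)
            assert report.macro_precision == p
            assert report.macro_recall == r
            assert report.macro_f1 == f


class TestBootstrap:
    gold = {f"d{i}": frozenset({"L"}) if i % 2 else frozenset({"D"})
            for i in range(12)}

    def test_perfect_predictions_give_degenerate_ci(self):
        ci = bootstrap_ci(self.gold, dict(self.gold), ("D", "L"), B=50, seed=1)
        assert (ci.lower, ci.upper) == (1.0, 1.0)

    def test_seeded_reproducibility(self):
        pred = {d: frozenset({"D"}) for d in self.gold}
        a = bootstrap_ci(self.gold, pred, ("D", "L"), B=200, seed=3)
        b = bootstrap_ci(self.gold, pred, ("D", "L"), B=200, seed=3)
        assert (a.lower, a.upper) == (b.lower, b.upper)

    def test_interval_brackets_point_estimate(self):
        rng = np.random.default_rng(4)
        pred = {d: (frozenset({"L"}) if rng.random() < 0.8 else frozenset({"D"}))
                for d in self.gold}
        point = macro_prf(self.gold, pred, ("D", "L")).macro_f1
        ci = bootstrap_ci(self.gold, pred, ("D", "L"), B=500, seed=4)
        assert ci.lower <= point <= ci.upper

    def test_invalid_replicate_count(self):
        with pytest.raises(ValueError):
            bootstrap_ci(self.gold, dict(self.gold), ("D", "L"), B=0)


class TestPairedBootstrap:
    gold = {f"d{i}": frozenset({"L"}) if i % 2 else frozenset({"D"})
            for i in range(20)}

    def test_identical_systems_give_p_one(self):
        pred = {d: frozenset({"D"}) for d in self.gold}
        res = paired_bootstrap(self.gold, pred, dict(pred), ("D", "L"),
                               B=100, seed=0)
        assert res.delta_f1 == 0.0
        assert res.p_value == 1.0

    def test_perfect_vs_all_wrong_is_significant(self):
        wrong = {d: frozenset({"L"}) if "D" in self.gold[d] else frozenset({"D"})
                 for d in self.gold}
        res = paired_bootstrap(self.gold, dict(self.gold), wrong, ("D", "L"),
                               B=500, seed=0)
        assert res.delta_f1 == pytest.approx(1.0)
        assert res.p_value < 0.01

    def test_seeded_reproducibility(self):
        wrong = {d: frozenset() for d in self.gold}
        a = paired_bootstrap(self.gold, dict(self.gold), wrong, ("D", "L"),
                             B=200, seed=9)
        b = paired_bootstrap(self.gold, dict(self.gold), wrong, ("D", "L"),
                             B=200, seed=9)
        assert (a.delta_f1, a.p_value) == (b.delta_f1, b.p_value)


class TestStratifiedSplit:
    def test_proportional_allocation_two_strata(self):
        corpus = _corpus(10)  # 5 docs keyed D, 5 keyed L
        split = stratified_split(corpus, test_fraction=0.2, seed=0)
        assert len(split.test_ids) == 2
        test_keys = [sorted(corpus.label_set(i))[0] for i in split.test_ids]
        assert sorted(test_keys) == ["D", "L"]

    def test_239_documents_at_20_percent_gives_48(self):
        lex = generate_lexicons(LexiconSpec(keywords_per_class=4,
                                            n_filler_words=40), seed=0)
        corpus = generate_corpus(GeneratorConfig(n_transcripts=239,
                                                 turns_range=(2, 4),
                                                 tokens_per_turn_range=(2, 4)),
                                 lex, seed=0)
        split = stratified_split(corpus, test_fraction=0.2, seed=0)
        assert len(split.test_ids) == 48
        assert len(split.train_ids) == 191

    def test_partition_and_seed_reproducibility(self):
        corpus = _corpus(17)
        s1 = stratified_split(corpus, 0.3, seed=5)
        s2 = stratified_split(corpus, 0.3, seed=5)
        assert s1 == s2
        assert set(s1.train_ids) | set(s1.test_ids) == set(corpus.ids)
        assert not set(s1.train_ids) & set(s1.test_ids)

    def test_invalid_fraction_rejected(self):
        corpus = _corpus(4)
        for frac in (0.0, 1.0, -0.1):
            with pytest.raises(ValueError):
                stratified_split(corpus, frac)


class TestKfold:
    def test_equal_fold_sizes(self):
        folds = kfold(_corpus(10), k=5, seed=0)
        assert [len(valid) for _, valid in folds] == [2] * 5

    def test_validation_folds_partition_corpus(self):
        corpus = _corpus(13)
        folds = kfold(corpus, k=5, seed=1)
        seen = [i for _, valid in folds for i in valid]
        assert sorted(seen) == sorted(corpus.ids)
        sizes = sorted(len(v) for _, v in folds)
        assert sizes[-1] - sizes[0] <= 1

    def test_seeded_reproducibility_and_k_validation(self):
        corpus = _corpus(8)
        assert kfold(corpus, 4, seed=2) == kfold(corpus, 4, seed=2)
        with pytest.raises(ValueError):
            kfold(corpus, 1)
        with pytest.raises(ValueError):
            kfold(corpus, 9)


class TestRandomBaseline:
    ids = [f"d{i}" for i in range(30)]

    def test_saturation_and_zero(self):
        full = random_baseline(self.ids, ("D", "L"), q=1.0, seed=0)
        assert all(v == frozenset({"D", "L"}) for v in full.values())
        empty = random_baseline(self.ids, ("D", "L"), q=0.0, seed=0)
        assert all(v == frozenset() for v in empty.values())

    def test_expected_macro_recall_approximates_q(self):
        # with independent assignment, per-class recall estimates q
        n = 500
        ids = [f"d{i}" for i in range(n)]
        gold = {d: frozenset({"D"}) if i % 2 else frozenset({"L"})
                for i, d in enumerate(ids)}
        q = 0.3
        pred = random_baseline(ids, ("D", "L"), q=q, seed=8)
        report = macro_prf(gold, pred, ("D", "L"))
        se = np.sqrt(q * (1 - q) / (n / 2))
        assert abs(report.macro_recall - q) < 3 * se


class TestMulticlassRecallCeiling:
    def test_singleton_systems_cannot_fully_recall_multilabel_documents(self):
        # m of n documents carry >= 2 labels; a singleton predictor achieves
        # complete per-document recall on at most n - m documents
        rng = np.random.default_rng(21)
        inventory = ("D", "L", "P")
        n, m = 30, 12
        gold = {}
        for i in range(n):
            if i < m:
                gold[f"d{i}"] = frozenset(rng.choice(inventory, 2, replace=False))
            else:
                gold[f"d{i}"] = frozenset({str(rng.choice(inventory))})
        # an adversarially favourable singleton system: always pick a gold label
        pred = {d: frozenset({sorted(gold[d])[0]}) for d in gold}
        complete = sum(1 for d in gold if gold[d] <= pred[d])
        assert complete <= n - m
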