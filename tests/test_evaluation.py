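import math

import numpy as np
import pytest

from pvpscm import (
    ConfusionCounts,
    LabeledDataset,
    ProteinSequence,
    auroc,
    evaluate_independent,
    initial_scorecard,
    kfold_cv,
    metrics_from_counts,
    pvp_scores,
    select_threshold,
)
from pvpscm.evaluation import roc_points
from pvpscm.scm import ScoreCard, ThresholdUnsetError


def oracle_metrics(tp, tn, fp, fn):
    """Independent direct evaluation of the four confusion formulas."""
    total = tp + tn + fp + fn
    acc = (tp + tn) / total
    sn = tp / (tp + fn) if tp + fn else math.nan
    sp = tn / (tn + fp) if tn + fp else math.nan
    denom = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    mcc = (tp * tn - fp * fn) / math.sqrt(denom) if denom else 0.0
    return acc, sn, sp, mcc


def oracle_auroc(scores, labels):
    """Exhaustive pair counting: positives vs negatives, ties half."""
    pos = [s for s, y in zip(scores, labels) if y == 1]
    neg = [s for s, y in zip(scores, labels) if y == 0]
    wins = sum((p > n) + 0.5 * (p == n) for p in pos for n in neg)
    return wins / (len(pos) * len(neg))


class TestMetricsFromCounts:
    @pytest.mark.parametrize(
        "counts, expected",
        [
            ((5, 5, 0, 0), (1.0, 1.0, 1.0, 1.0)),
            ((0, 0, 5, 5), (0.0, 0.0, 0.0, -1.0)),
            ((3, 4, 1, 2), (0.7, 0.6, 0.8, 10 / math.sqrt(600))),
        ],
    )
    def test_worked_examples(self, counts, expected):
        m = metrics_from_counts(ConfusionCounts(*counts))
        assert (m.ACC, m.SN, m.SP, m.MCC) == pytest.approx(expected)

    def test_zero_marginal_flags_mcc(self):
        m = metrics_from_counts(ConfusionCounts(TP=3, TN=0, FP=0, FN=2))
        assert m.MCC == 0.0 and m.mcc_degenerate

    def test_fuzz_against_oracle(self):
        rng = np.random.default_rng(42)
        for _ in range(1000):
            tp, tn, fp, fn = rng.integers(0, 40, size=4)
            if tp + tn + fp + fn == 0:
                continue
            m = metrics_from_counts(ConfusionCounts(int(tp), int(tn), int(fp), int(fn)))
            acc, sn, sp, mcc = oracle_metrics(int(tp), int(tn), int(fp), int(fn))
            assert m.ACC == pytest.approx(acc)
            assert m.MCC == pytest.approx(mcc)
            for got, want in ((m.SN, sn), (m.SP, sp)):
                assert (math.isnan(got) and math.isnan(want)) or got == pytest.approx(want)


class TestAuroc:
    def test_perfect_separation(self):
        assert auroc([2, 3, 0, 1], [1, 1, 0, 0]) == 1.0

    def test_all_ties_is_half(self):
        assert auroc([5, 5, 5, 5], [1, 1, 0, 0]) == 0.5

    def test_enumerated_pairs(self):
        assert auroc([3, 1, 2, 0], [1, 1, 0, 0]) == 0.75

    def test_single_class_errors(self):
        with pytest.raises(ValueError):
            auroc([1, 2], [1, 1])

    def test_fuzz_against_pair_counting(self):
        rng = np.random.default_rng(7)
        for _ in range(200):
            n = int(rng.integers(4, 15))
            scores = rng.integers(0, 6, size=n).astype(float)  # many ties
            labels = np.zeros(n, dtype=int)
            labels[: int(rng.integers(1, n))] = 1
            rng.shuffle(labels)
            if labels.min() == labels.max():
                continue
            assert auroc(scores, labels) == pytest.approx(
                oracle_auroc(scores, labels)
            )

    def test_negation_complement_identity(self):
        rng = np.random.default_rng(3)
        scores = rng.normal(size=30)
        labels = rng.integers(0, 2, size=30)
        labels[0], labels[1] = 0, 1
        assert auroc(scores, labels) + auroc(-scores, labels) == pytest.approx(1.0)

    def test_roc_points_span_unit_square(self):
        pts = roc_points([3, 1, 2, 0], [1, 1, 0, 0])
        assert pts[0] == pytest.approx([0, 0])
        assert pts[-1] == pytest.approx([1, 1])


def oracle_best_threshold(scores, labels, criterion="mcc"):
    """Exhaustive scan over every midpoint plus guards."""
    distinct = sorted(set(scores))
    candidates = (
        [distinct[0] - 1]
        + [(a + b) / 2 for a, b in zip(distinct, distinct[1:])]
        + [distinct[-1] + 1]
    )
    best = None
    for t in candidates:
        tp = sum(s > t and y for s, y in zip(scores, labels))
        fp = sum(s > t and not y for s, y in zip(scores, labels))
        tn = sum(s <= t and not y for s, y in zip(scores, labels))
        fn = sum(s <= t and y for s, y in zip(scores, labels))
        acc, _, _, mcc = oracle_metrics(tp, tn, fp, fn)
        key = (mcc, acc, -t) if criterion == "mcc" else (acc, mcc, -t)
        if best is None or key > best[0]:
            best = (key, t)
    return best[1]


class TestSelectThreshold:
    def test_clean_separation_midpoint(self):
        t = select_threshold([460, 470, 440, 450], [1, 1, 0, 0])
        assert t == 455.0

    @pytest.mark.parametrize("criterion", ["mcc", "acc"])
    def test_matches_exhaustive_scan(self, criterion):
        rng = np.random.default_rng(19)
        for _ in range(50):
            n = int(rng.integers(6, 25))
            scores = np.round(rng.uniform(0, 1000, size=n), 1)
            labels = rng.integers(0, 2, size=n)
            labels[0], labels[1] = 1, 0
            got = select_threshold(scores, labels, criterion=criterion)
            want = oracle_best_threshold(list(scores), list(labels), criterion)
            assert got == pytest.approx(want)

    def test_interleaved_never_perfect(self):
        scores = [10, 30, 20, 40]  # one positive above all negatives, one below
        labels = [1, 1, 0, 0]
        t = select_threshold(scores, labels)
        assert t == pytest.approx(oracle_best_threshold(scores, labels))
        tp = sum(s > t and y for s, y in zip(scores, labels))
        tn = sum(s <= t and not y for s, y in zip(scores, labels))
        fp = 2 - tn
        fn = 2 - tp
        _, _, _, mcc = oracle_metrics(tp, tn, fp, fn)
        assert mcc < 1.0  # no cut separates interleaved scores perfectly


def _init_trainer(data):
    card = initial_scorecard(data)
    scores = pvp_scores(data.sequences, card)
    return card.with_threshold(select_threshold(scores, data.labels))


class TestKFoldCV:
    def test_each_sequence_predicted_exactly_once(self, biased_dataset):
        result = kfold_cv(biased_dataset, k=5, seed=0, trainer=_init_trainer)
        assert len(result.pooled_predictions) == len(biased_dataset)
        assert len(result.per_fold) == 5
        counts = np.bincount(result.fold_assignment, minlength=5)
        assert counts.sum() == len(biased_dataset)
        # stratification: every fold holds both classes
        y = np.asarray(biased_dataset.labels)
        for fold in range(5):
            fold_labels = y[result.fold_assignment == fold]
            assert 0 < fold_labels.sum() < len(fold_labels)

    def test_fixed_seed_is_deterministic(self, biased_dataset):
        a = kfold_cv(biased_dataset, k=5, seed=3, trainer=_init_trainer)
        b = kfold_cv(biased_dataset, k=5, seed=3, trainer=_init_trainer)
        np.testing.assert_array_equal(a.fold_assignment, b.fold_assignment)
        assert a.pooled == b.pooled

    def test_majority_trainer_on_balanced_data_is_chance(self, biased_dataset):
        def majority_trainer(data):
            # constant card + impossible threshold: always predicts negative
            return ScoreCard(scores=np.full(400, 500.0)).with_threshold(1000.0)

        result = kfold_cv(biased_dataset, k=5, seed=0, trainer=majority_trainer)
        assert result.pooled.ACC == pytest.approx(0.5, abs=1e-9)

    def test_class_smaller_than_k_suggests_smaller_k(self):
        data = LabeledDataset(
            [ProteinSequence(f"s{i}", "ACDE") for i in range(6)], [1, 1, 0, 0, 0, 0]
        )
        with pytest.raises(ValueError, match="smaller k"):
            kfold_cv(data, k=3, seed=0, trainer=_init_trainer)

    def test_k_equals_n_is_leave_one_out(self):
        data = LabeledDataset(
            [ProteinSequence(f"p{i}", "AAAAAA") for i in range(3)]
            + [ProteinSequence(f"n{i}", "CCCCCC") for i in range(3)],
            [1, 1, 1, 0, 0, 0],
        )
        result = kfold_cv(data, k=6, seed=0, trainer=_init_trainer)
        assert len(result.per_fold) == 6
        assert all(np.bincount(result.fold_assignment) == 1)


class TestEvaluateIndependent:
    def test_perfect_separation(self, toy_dataset):
        card = _init_trainer(toy_dataset)
        m = evaluate_independent(card, toy_dataset)
        assert (m.ACC, m.MCC, m.auROC) == (1.0, 1.0, 1.0)

    def test_threshold_below_all_scores(self, toy_dataset, uniform_card):
        card = uniform_card.with_threshold(0.0)  # uniform scores 500 > 0
        m = evaluate_independent(card, toy_dataset)
        assert m.SN == 1.0 and m.SP == 0.0

    def test_single_class_test_set_reports_sn_but_no_auroc(self, uniform_card):
        card = uniform_card.with_threshold(0.0)
        positives_only = LabeledDataset(
            [ProteinSequence("p", "MKLV"), ProteinSequence("q", "ACDE")], [1, 1]
        )
        m = evaluate_independent(card, positives_only)
        assert m.SN == 1.0
        assert math.isnan(m.auROC)

    def test_unset_threshold_errors(self, toy_dataset, uniform_card):
        with pytest.raises(ThresholdUnsetError):
            evaluate_independent(uniform_card, toy_dataset)
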