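"""Classifier evaluation: confusion metrics, ROC, thresholds, cross-validation.

Metric conventions: ACC = (TP+TN)/total, SN = TP/(TP+FN), SP = TN/(TN+FP),
MCC = (TP*TN - FP*FN) / sqrt((TP+FP)(TP+FN)(TN+FP)(TN+FN)); auROC is the
probability a random positive outscores a random negative, ties counting
half. Cross-validation is stratified (the phage virion benchmark is
imbalanced, roughly 1:2, and unstratified small folds can be single-class)
and summarized on pooled out-of-fold predictions, which stays well defined
when individual folds are small; per-fold metrics are retained for
transparency.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Literal

import numpy as np
from sklearn.metrics import roc_auc_score, roc_curve
from sklearn.model_selection import StratifiedKFold

from .scm import ScoreCard, ThresholdUnsetError, pvp_scores
from .sequence_io import LabeledDataset


@dataclass(frozen=True)
class ConfusionCounts:
    TP: int
    TN: int
    FP: int
    FN: int

    def __post_init__(self) -> None:
        if min(self.TP, self.TN, self.FP, self.FN) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.TP + self.TN + self.FP + self.FN

    @classmethod
    def from_predictions(cls, y_true, y_pred) -> "ConfusionCounts":
        y_true = np.asarray(y_true, dtype=bool)
        y_pred = np.asarray(y_pred, dtype=bool)
        return cls(
            TP=int((y_true & y_pred).sum()),
            TN=int((~y_true & ~y_pred).sum()),
            FP=int((~y_true & y_pred).sum()),
            FN=int((y_true & ~y_pred).sum()),
        )


@dataclass(frozen=True)
class MetricSet:
    """ACC/SN/SP on [0,1], MCC on [-1,1], auROC on [0,1] (NaN if not computed).

    ``mcc_degenerate`` flags an MCC reported as 0 because a confusion-matrix
    marginal was zero (the usual convention for the undefined case).
    """

    ACC: float
    SN: float
    SP: float
    MCC: float
    auROC: float = float("nan")
    mcc_degenerate: bool = False

    def as_row(self) -> dict[str, float]:
        return {
            "ACC_pct": 100 * self.ACC,
            "SN_pct": 100 * self.SN,
            "SP_pct": 100 * self.SP,
            "MCC": self.MCC,
            "auROC": self.auROC,
        }


def metrics_from_counts(c: ConfusionCounts) -> MetricSet:
    """Accuracy, sensitivity, specificity and MCC from confusion counts.

    SN (SP) is NaN when there are no actual positives (negatives). A zero
    marginal makes MCC's denominator vanish; it is reported as 0 with the
    ``mcc_degenerate`` flag set.
    """
    if c.total == 0:
        raise ValueError("empty confusion table")
    acc = (c.TP + c.TN) / c.total
    sn = c.TP / (c.TP + c.FN) if (c.TP + c.FN) else float("nan")
    sp = c.TN / (c.TN + c.FP) if (c.TN + c.FP) else float("nan")
    denom = (c.TP + c.FP) * (c.TP + c.FN) * (c.TN + c.FP) * (c.TN + c.FN)
    if denom == 0:
        mcc, degenerate = 0.0, True
    else:
        mcc = (c.TP * c.TN - c.FP * c.FN) / np.sqrt(denom)
        degenerate = False
    return MetricSet(ACC=acc, SN=sn, SP=sp, MCC=float(mcc), mcc_degenerate=degenerate)


def auroc(scores, labels) -> float:
    """Area under the ROC curve of real-valued scores against binary labels.

    Equals the Mann–Whitney statistic: the fraction of (positive, negative)
    pairs in which the positive scores strictly higher, ties counting 1/2.
    """
    labels = np.asarray(labels)
    if labels.min() == labels.max():
        raise ValueError("auROC needs at least one positive and one negative")
    return float(roc_auc_score(labels, np.asarray(scores, dtype=float)))


def roc_points(scores, labels) -> np.ndarray:
    """Empirical ROC curve as an (n, 2) array of (FPR, TPR) points."""
    fpr, tpr, _ = roc_curve(np.asarray(labels), np.asarray(scores, dtype=float))
    return np.column_stack([fpr, tpr])


def _criterion_value(
    scores: np.ndarray, labels: np.ndarray, threshold: float,
    criterion: Literal["mcc", "acc"],
) -> tuple[float, float]:
    pred = scores > threshold
    m = metrics_from_counts(ConfusionCounts.from_predictions(labels, pred))
    return (m.MCC, m.ACC) if criterion == "mcc" else (m.ACC, m.MCC)


def select_threshold(
    scores, labels, criterion: Literal["mcc", "acc"] = "mcc"
) -> float:
    """Pick the cutoff maximizing MCC (default) or accuracy.

    Candidates are the midpoints between consecutive distinct sorted scores,
    plus guard candidates below the minimum and above the maximum score.
    Ties are broken toward the candidate with the better secondary criterion
    (ACC when optimizing MCC and vice versa), then toward the lowest
    threshold. MCC is the default because the benchmark classes are
    imbalanced.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    if labels.min() == labels.max():
        raise ValueError("threshold selection needs both classes present")
    distinct = np.unique(scores)
    candidates = np.concatenate(
        [[distinct[0] - 1.0], (distinct[:-1] + distinct[1:]) / 2.0, [distinct[-1] + 1.0]]
    )
    best = None
    for t in candidates:
        key = (*_criterion_value(scores, labels, t, criterion), -t)
        if best is None or key > best[0]:
            best = (key, t)
    return float(best[1])


Trainer = Callable[[LabeledDataset], ScoreCard]


@dataclass
class CVResult:
    pooled: MetricSet
    per_fold: list[MetricSet]
    fold_assignment: np.ndarray  # fold index per sequence
    pooled_scores: np.ndarray  # out-of-fold score per sequence
    pooled_predictions: np.ndarray  # out-of-fold label per sequence


def kfold_cv(
    data: LabeledDataset, k: int, seed: int, trainer: Trainer
) -> CVResult:
    """Stratified k-fold cross-validation of a score-card training procedure.

    The trainer fits on k-1 folds (including its own threshold selection)
    and the held-out fold is scored with the frozen card; every sequence is
    predicted exactly once. The summary MetricSet (including auROC) is
    computed on the pooled out-of-fold predictions; per-fold metrics are
    kept as well. Setting k to the dataset size gives leave-one-out.
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    y = np.asarray(data.labels)
    n_min = min(data.n_positive, data.n_negative)
    if n_min < k and k != len(data):
        raise ValueError(
            f"smallest class has {n_min} sequences < k={k}; use a smaller k"
        )
    if k == len(data):
        # leave-one-out: stratification is vacuous with singleton test folds
        splits = [
            (np.delete(np.arange(len(y)), i), np.array([i])) for i in range(len(y))
        ]
    else:
        splitter = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
        splits = list(splitter.split(np.zeros(len(y)), y))
    fold_assignment = np.empty(len(data), dtype=int)
    oof_scores = np.empty(len(data), dtype=float)
    oof_pred = np.empty(len(data), dtype=int)
    per_fold: list[MetricSet] = []
    for fold, (train_idx, test_idx) in enumerate(splits):
        card = trainer(data.subset(train_idx))
        if not card.has_threshold:
            raise ThresholdUnsetError("trainer must return a card with a threshold")
        scores = pvp_scores([data.sequences[i] for i in test_idx], card)
        pred = (scores > card.threshold).astype(int)
        fold_assignment[test_idx] = fold
        oof_scores[test_idx] = scores
        oof_pred[test_idx] = pred
        fold_metrics = metrics_from_counts(
            ConfusionCounts.from_predictions(y[test_idx], pred)
        )
        if y[test_idx].min() != y[test_idx].max():
            fold_metrics = _with_auroc(fold_metrics, auroc(scores, y[test_idx]))
        per_fold.append(fold_metrics)
    pooled = metrics_from_counts(ConfusionCounts.from_predictions(y, oof_pred))
    pooled = _with_auroc(pooled, auroc(oof_scores, y))
    return CVResult(pooled, per_fold, fold_assignment, oof_scores, oof_pred)


def _with_auroc(m: MetricSet, value: float) -> MetricSet:
    return MetricSet(m.ACC, m.SN, m.SP, m.MCC, value, m.mcc_degenerate)


def evaluate_independent(card: ScoreCard, test: LabeledDataset) -> MetricSet:
    """Score a held-out dataset with a frozen, thresholded card.

    auROC is reported only when both classes are present in the test set
    (NaN otherwise); threshold-dependent metrics are always computed.
    """
    if not card.has_threshold:
        raise ThresholdUnsetError("card has no threshold; train or select one first")
    y = np.asarray(test.labels)
    scores = pvp_scores(test.sequences, card)
    pred = (scores > card.threshold).astype(int)
    m = metrics_from_counts(ConfusionCounts.from_predictions(y, pred))
    if y.min() != y.max():
        m = _with_auroc(m, auroc(scores, y))
    return m
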