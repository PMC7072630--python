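"""Scikit-learn estimator facade over the scoring card method.

`ScoreCardClassifier` wires the pieces — statistical initialization,
optional genetic-algorithm refinement, threshold selection — into a
fit/predict estimator that composes with sklearn model selection. Input X
is a sequence of protein strings (or :class:`ProteinSequence` records);
`decision_function` returns the weighted-sum score on the card's own
[0, 1000] scale.
"""

from __future__ import annotations

import numbers

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.utils.validation import check_is_fitted

from .evaluation import select_threshold
from .features import DipeptideComposition
from .ga import GAConfig, evolve
from .scm import ScoreCard, initial_scorecard
from .sequence_io import LabeledDataset, ProteinSequence


def _as_residues(X) -> list[str]:
    out = []
    for item in X:
        out.append(item.residues if isinstance(item, ProteinSequence) else str(item))
    return out


class ScoreCardClassifier(ClassifierMixin, BaseEstimator):
    """Interpretable dipeptide scoring-card classifier.

    Each of the 400 dipeptides receives a propensity score in [0, 1000];
    a sequence's score is its composition-weighted mean of card scores and
    is compared against a fitted threshold (strictly greater = positive).

    Parameters
    ----------
    optimize : bool, default=True
        Refine the statistically initialized card with the elitist
        real-coded genetic algorithm.
    population_size, generations, crossover_rate, mutation_rate,
    mutation_scale, elite_count, tournament_size, w1, w2, cv_folds :
        Genetic-algorithm hyperparameters; see :class:`pvpscm.ga.GAConfig`.
        ``w1``/``w2`` weight the auROC and initialization-correlation terms
        of the fitness (defaults 0.9 / 0.1).
    threshold_criterion : {"mcc", "acc"}, default="mcc"
        Statistic maximized when selecting the decision threshold on the
        training data.
    random_state : int, default=0
        Seed driving the GA; identical inputs and seed give a bit-identical
        fitted card.

    Attributes
    ----------
    card_ : ScoreCard
        The fitted (optimized if requested) card with its threshold.
    init_card_ : ScoreCard
        The statistical initialization, before refinement.
    threshold_ : float
        Decision cutoff on the [0, 1000] score scale.
    fitness_trace_ : list of FitnessRecord
        Per-generation GA log (empty when ``optimize=False``).
    classes_ : ndarray
        Always ``[0, 1]`` (negative, positive).
    """

    def __init__(
        self,
        optimize: bool = True,
        population_size: int = 50,
        generations: int = 100,
        crossover_rate: float = 0.5,
        mutation_rate: float = 0.05,
        mutation_scale: float = 50.0,
        elite_count: int = 2,
        tournament_size: int = 3,
        w1: float = 0.9,
        w2: float = 0.1,
        cv_folds: int = 10,
        threshold_criterion: str = "mcc",
        random_state: int = 0,
    ):
        self.optimize = optimize
        self.population_size = population_size
        self.generations = generations
        self.crossover_rate = crossover_rate
        self.mutation_rate = mutation_rate
        self.mutation_scale = mutation_scale
        self.elite_count = elite_count
        self.tournament_size = tournament_size
        self.w1 = w1
        self.w2 = w2
        self.cv_folds = cv_folds
        self.threshold_criterion = threshold_criterion
        self.random_state = random_state

    def _ga_config(self) -> GAConfig:
        return GAConfig(
            population_size=self.population_size,
            generations=self.generations,
            crossover_rate=self.crossover_rate,
            mutation_rate=self.mutation_rate,
            mutation_scale=self.mutation_scale,
            elite_count=self.elite_count,
            tournament_size=self.tournament_size,
            w1=self.w1,
            w2=self.w2,
            cv_folds=self.cv_folds,
            seed=int(self.random_state),
        )

    def fit(self, X, y):
        """Fit the card on sequences X with binary labels y (1 = positive)."""
        if self.threshold_criterion not in ("mcc", "acc"):
            raise ValueError("threshold_criterion must be 'mcc' or 'acc'")
        residues = _as_residues(X)
        y = np.asarray(y)
        if len(residues) != len(y):
            raise ValueError("X and y have different lengths")
        labels = [int(v) for v in y]
        data = LabeledDataset(
            [ProteinSequence(id=f"seq_{i}", residues=r) for i, r in enumerate(residues)],
            labels,
        )
        data.require_both_classes()
        self.init_card_ = initial_scorecard(data)
        if self.optimize:
            card, self.fitness_trace_ = evolve(data, self.init_card_, self._ga_config())
        else:
            card, self.fitness_trace_ = self.init_card_, []
        X_dpc = DipeptideComposition().fit_transform(residues)
        scores = X_dpc @ card.scores
        threshold = select_threshold(scores, y, criterion=self.threshold_criterion)
        self.card_ = card.with_threshold(threshold)
        self.threshold_ = self.card_.threshold
        self.classes_ = np.array([0, 1])
        self.n_features_in_ = 1
        return self

    def decision_function(self, X) -> np.ndarray:
        """Weighted-sum PVP score of each sequence, on [0, 1000]."""
        check_is_fitted(self, "card_")
        X_dpc = DipeptideComposition().fit_transform(_as_residues(X))
        return X_dpc @ self.card_.scores

    def predict(self, X) -> np.ndarray:
        """1 where the score strictly exceeds the fitted threshold, else 0."""
        return (self.decision_function(X) > self.threshold_).astype(int)


def fit_scorecard(
    data: LabeledDataset,
    optimize: bool = True,
    seed: int = 0,
    threshold_criterion: str = "mcc",
    **ga_params,
) -> ScoreCardClassifier:
    """Convenience wrapper: fit a classifier directly from a LabeledDataset."""
    clf = ScoreCardClassifier(
        optimize=optimize, random_state=seed,
        threshold_criterion=threshold_criterion, **ga_params,
    )
    return clf.fit(data.sequences, data.labels)
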