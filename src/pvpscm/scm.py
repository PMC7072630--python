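"""The scoring card: initialization, normalization, scoring, propensities.

A score card assigns each of the 400 dipeptides a propensity score in
[0, 1000]. A sequence's PVP score is the composition-weighted sum
S(P) = sum_i w_i * S_i, where w_i is the sequence's dipeptide frequency —
a convex combination of card scores, hence itself in [0, 1000]. A sequence
is called positive when its score is strictly greater than the card's
decision threshold.

The initial card (init-DPS) scores each dipeptide by the difference between
its mean composition in the positive and negative classes, min–max rescaled
to [0, 1000]; genetic-algorithm refinement (opti-DPS) lives in
:mod:`pvpscm.ga`.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping

import numpy as np

from .features import DIPEPTIDES, N_DIPEPTIDES, class_mean_dpc, dipeptide_composition
from .sequence_io import AMINO_ACIDS, LabeledDataset, ProteinSequence

#: Sentinel meaning "no decision threshold selected yet".
THRESHOLD_UNSET = float("nan")


class ThresholdUnsetError(RuntimeError):
    """Classification was attempted before a threshold was selected."""


@dataclass
class ScoreCard:
    """400 dipeptide propensity scores plus a decision threshold.

    Attributes
    ----------
    scores : ndarray of shape (400,)
        Propensity score per dipeptide (alphabetical index order), each in
        [0, 1000].
    threshold : float
        Decision cutoff; NaN until selected (see
        :func:`pvpscm.evaluation.select_threshold`).
    provenance : str
        ``"init"`` for the statistical initialization, ``"optimized"`` after
        genetic-algorithm refinement.
    seed : int or None
        Seed of the training run that produced the card.
    fitness : float or None
        Fitness achieved (optimized cards only).
    """

    scores: np.ndarray
    threshold: float = THRESHOLD_UNSET
    provenance: str = "init"
    seed: int | None = None
    fitness: float | None = None

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=float)
        if self.scores.shape != (N_DIPEPTIDES,):
            raise ValueError(f"expected {N_DIPEPTIDES} scores, got {self.scores.shape}")
        if self.scores.min() < -1e-9 or self.scores.max() > 1000 + 1e-9:
            raise ValueError("scores must lie in [0, 1000]")
        np.clip(self.scores, 0.0, 1000.0, out=self.scores)

    @property
    def has_threshold(self) -> bool:
        return not np.isnan(self.threshold)

    def with_threshold(self, threshold: float) -> "ScoreCard":
        # thresholds from guard candidates may fall marginally outside the
        # score range; clip so the stored cutoff stays in [0, 1000]
        return replace(self, threshold=float(np.clip(threshold, 0.0, 1000.0)))

    def score_of(self, dipeptide: str) -> float:
        from .features import dipeptide_index

        return float(self.scores[dipeptide_index(dipeptide)])

    # ------------------------------------------------------------------ I/O
    def to_file(self, path: str | Path) -> None:
        """Persist as a self-describing tab-separated file.

        A ``#key\\tvalue`` header block (threshold, provenance, seed,
        fitness) is followed by one ``dipeptide\\tscore`` row per dipeptide
        in index order, so results are reproducible from the file alone.
        """
        with open(path, "w") as fh:
            fh.write(f"#threshold\t{float(self.threshold)!r}\n")
            fh.write(f"#provenance\t{self.provenance}\n")
            fh.write(f"#seed\t{self.seed if self.seed is not None else 'none'}\n")
            fh.write(f"#fitness\t{self.fitness if self.fitness is not None else 'none'}\n")
            for dp, s in zip(DIPEPTIDES, self.scores):
                fh.write(f"{dp}\t{float(s)!r}\n")

    @classmethod
    def from_file(cls, path: str | Path) -> "ScoreCard":
        meta: dict[str, str] = {}
        scores: dict[str, float] = {}
        with open(path) as fh:
            for line in fh:
                line = line.rstrip("\n")
                if not line:
                    continue
                key, _, value = line.partition("\t")
                if key.startswith("#"):
                    meta[key[1:]] = value
                else:
                    scores[key] = float(value)
        missing = set(DIPEPTIDES) - set(scores)
        if missing:
            raise ValueError(f"score card file missing {len(missing)} dipeptides")
        return cls(
            scores=np.array([scores[dp] for dp in DIPEPTIDES]),
            threshold=float(meta.get("threshold", "nan")),
            provenance=meta.get("provenance", "init"),
            seed=None if meta.get("seed", "none") == "none" else int(meta["seed"]),
            fitness=None if meta.get("fitness", "none") == "none" else float(meta["fitness"]),
        )


def rescale_to_0_1000(raw: np.ndarray) -> np.ndarray:
    """Affine min–max map of a raw score vector onto [0, 1000].

    A constant input has no span to map; it degenerates to all-500 so that
    pathological (signal-free) inputs stay usable rather than erroring.
    """
    raw = np.asarray(raw, dtype=float)
    lo, hi = raw.min(), raw.max()
    if hi == lo:
        return np.full_like(raw, 500.0)
    # guard the endpoints against floating-point overshoot
    return np.clip((raw - lo) * (1000.0 / (hi - lo)), 0.0, 1000.0)


def initial_scorecard(data: LabeledDataset) -> ScoreCard:
    """Statistical initialization of the card from class composition.

    Raw score of dipeptide d = mean positive-class DPC of d minus mean
    negative-class DPC of d (each sequence weighted equally), min–max
    rescaled to [0, 1000]. The threshold is left unset until selected.
    """
    pos_mean, neg_mean = class_mean_dpc(data)
    return ScoreCard(scores=rescale_to_0_1000(pos_mean - neg_mean), provenance="init")


def pvp_score(seq: ProteinSequence | str, card: ScoreCard) -> float:
    """Weighted-sum score S(P) = sum_i w_i * S_i of a sequence under a card."""
    return float(dipeptide_composition(seq) @ card.scores)


def pvp_scores(sequences, card: ScoreCard) -> np.ndarray:
    """Vectorized :func:`pvp_score` over an iterable of sequences."""
    from .features import DipeptideComposition

    return DipeptideComposition().fit_transform(sequences) @ card.scores


def classify(seq: ProteinSequence | str, card: ScoreCard) -> tuple[int, float]:
    """Label a sequence (1 = positive) and return its score.

    Positive iff score is strictly greater than the threshold; a score
    exactly at the threshold is negative.
    """
    if not card.has_threshold:
        raise ThresholdUnsetError(
            "score card has no decision threshold; train the card or select "
            "a threshold (see pvpscm.evaluation.select_threshold) first"
        )
    score = pvp_score(seq, card)
    return (1 if score > card.threshold else 0), score


def aa_propensity(card: ScoreCard) -> np.ndarray:
    """Per-amino-acid propensity: mean of the 40 positional dipeptide scores.

    For amino acid a, the 20 dipeptides with a in the first position and the
    20 with a in the second position contribute one term each — 40 terms over
    39 distinct dipeptides, the homodipeptide aa counted twice. Returns a
    20-vector in amino-acid alphabetical order; for a card in [0, 1000] every
    propensity is also in [0, 1000].
    """
    grid = card.scores.reshape(20, 20)
    return (grid.sum(axis=1) + grid.sum(axis=0)) / 40.0


def aa_propensity_table(card: ScoreCard):
    """AA propensities as a rank-annotated DataFrame (descending score)."""
    import pandas as pd

    prop = aa_propensity(card)
    order = np.argsort(-prop, kind="stable")
    rank = np.empty(20, dtype=int)
    rank[order] = np.arange(1, 21)
    return pd.DataFrame(
        {"propensity": prop, "rank": rank}, index=list(AMINO_ACIDS)
    )
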