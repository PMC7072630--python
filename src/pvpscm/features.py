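"""Dipeptide and amino-acid composition features.

A protein of length N has N-1 overlapping dipeptide windows; its dipeptide
composition (DPC) is the 400-vector of window frequencies, summing to 1.
Dipeptides are indexed alphabetically: index = 20*rank(first) + rank(second)
with A < C < D < ... < Y, so AA=0, AC=1, ..., YY=399. All serialized score
cards carry this ordering explicitly.

`DipeptideComposition` wraps the per-sequence computation as a scikit-learn
transformer so the scoring card classifier composes with sklearn pipelines.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator, TransformerMixin

from .sequence_io import AMINO_ACIDS, LabeledDataset, ProteinSequence

N_DIPEPTIDES = 400

#: All 400 dipeptides in index order (AA, AC, AD, ..., YY).
DIPEPTIDES: tuple[str, ...] = tuple(a + b for a in AMINO_ACIDS for b in AMINO_ACIDS)

_AA_INDEX = {aa: i for i, aa in enumerate(AMINO_ACIDS)}
# residue character code -> alphabet rank, -1 for anything non-canonical
_CODE_TO_RANK = np.full(128, -1, dtype=np.int64)
for _aa, _i in _AA_INDEX.items():
    _CODE_TO_RANK[ord(_aa)] = _i


def dipeptide_index(dipeptide: str) -> int:
    """Index of a dipeptide in the alphabetical 400-long ordering."""
    return 20 * _AA_INDEX[dipeptide[0]] + _AA_INDEX[dipeptide[1]]


def _ranks(residues: str) -> np.ndarray:
    ranks = _CODE_TO_RANK[np.frombuffer(residues.encode("ascii"), dtype=np.uint8)]
    if (ranks < 0).any():
        bad = sorted({c for c in residues if c not in _AA_INDEX})
        raise ValueError(f"non-canonical residue(s) {''.join(bad)!r}")
    return ranks


def dipeptide_composition(seq: ProteinSequence | str) -> np.ndarray:
    """Overlapping dipeptide frequencies of a sequence (400-vector, sums to 1)."""
    residues = seq.residues if isinstance(seq, ProteinSequence) else seq
    if len(residues) < 2:
        raise ValueError("sequence must have length >= 2 to form a dipeptide")
    ranks = _ranks(residues)
    idx = 20 * ranks[:-1] + ranks[1:]
    counts = np.bincount(idx, minlength=N_DIPEPTIDES)
    return counts / (len(residues) - 1)


def amino_acid_composition(seq: ProteinSequence | str) -> np.ndarray:
    """Residue frequencies of a sequence (20-vector, sums to 1)."""
    residues = seq.residues if isinstance(seq, ProteinSequence) else seq
    if not residues:
        raise ValueError("empty sequence")
    counts = np.bincount(_ranks(residues), minlength=20)
    return counts / len(residues)


class DipeptideComposition(BaseEstimator, TransformerMixin):
    """Transform protein sequences into dipeptide-composition row vectors.

    Stateless; ``fit`` only validates. ``transform`` accepts an iterable of
    sequences (strings or :class:`ProteinSequence`) and returns an
    (n_sequences, 400) array whose rows sum to 1.
    """

    def fit(self, X, y=None):  # noqa: D102 — sklearn contract
        self.n_features_in_ = 1
        return self

    def transform(self, X) -> np.ndarray:
        return np.vstack([dipeptide_composition(seq) for seq in X])

    def get_feature_names_out(self, input_features=None) -> np.ndarray:
        return np.asarray(DIPEPTIDES, dtype=object)


def class_mean_dpc(data: LabeledDataset) -> tuple[np.ndarray, np.ndarray]:
    """Unweighted class means of per-sequence DPC (positive, negative)."""
    data.require_both_classes()
    X = DipeptideComposition().fit_transform(data.sequences)
    y = np.asarray(data.labels, dtype=bool)
    return X[y].mean(axis=0), X[~y].mean(axis=0)


@dataclass
class CompositionReport:
    """Class-wise amino-acid composition comparison.

    One row per amino acid: mean per-sequence composition (as %) of each
    class, their difference (positive minus negative), the rank of that
    difference (1 = largest), and a two-sided Welch t-test p-value on the
    per-sequence fractions. Each sequence is weighted equally, matching the
    per-protein statistical test; pooled residue counts would overweight
    long proteins.
    """

    table: pd.DataFrame  # index: amino acid; columns below

    COLUMNS = ("positive_pct", "negative_pct", "difference", "rank", "p_value")

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index_label="amino_acid",
                          float_format="%.6g")


def composition_report(data: LabeledDataset) -> CompositionReport:
    """Compare per-class amino-acid composition, rank the differences.

    Ranks are a permutation of 1..20 in descending difference order. With a
    class of fewer than 2 sequences the t-test is undefined and p-values are
    reported as NaN; means and differences are still computed.
    """
    data.require_both_classes()
    X = np.vstack([amino_acid_composition(s) for s in data.sequences])
    y = np.asarray(data.labels, dtype=bool)
    pos, neg = X[y] * 100.0, X[~y] * 100.0
    pos_mean, neg_mean = pos.mean(axis=0), neg.mean(axis=0)
    diff = pos_mean - neg_mean
    # descending-difference ranks; stable for ties (first occurrence ranks higher)
    order = np.argsort(-diff, kind="stable")
    rank = np.empty(20, dtype=int)
    rank[order] = np.arange(1, 21)
    if len(pos) >= 2 and len(neg) >= 2:
        with warnings.catch_warnings():
            # zero-variance columns are handled explicitly below
            warnings.simplefilter("ignore", RuntimeWarning)
            pvals = stats.ttest_ind(pos, neg, axis=0, equal_var=False).pvalue
        # identical degenerate columns (zero variance in both classes) -> p=1
        pvals = np.where(np.isnan(pvals), 1.0, pvals)
        same = (pos.std(axis=0) == 0) & (neg.std(axis=0) == 0) & (diff == 0)
        pvals = np.where(same, 1.0, pvals)
    else:
        pvals = np.full(20, np.nan)
    table = pd.DataFrame(
        {
            "positive_pct": pos_mean,
            "negative_pct": neg_mean,
            "difference": diff,
            "rank": rank,
            "p_value": pvals,
        },
        index=list(AMINO_ACIDS),
    )
    return CompositionReport(table)
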