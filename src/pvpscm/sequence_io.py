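"""Protein sequence containers, FASTA I/O, and residue validation.

The scoring card method operates on plain protein sequences over the 20
canonical amino acids. Sequences are carried as :class:`ProteinSequence`
records; a training set is a :class:`LabeledDataset` pairing sequences with
binary labels (positive = phage virion protein). Class membership is assigned
by file, not by header: positive and negative sequences arrive in separate
FASTA files.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Literal, Sequence

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

AMINO_ACIDS: str = "ACDEFGHIKLMNPQRSTVWY"
_AA_SET = frozenset(AMINO_ACIDS)

POSITIVE = 1
NEGATIVE = 0

logger = logging.getLogger(__name__)


class SequenceError(ValueError):
    """A sequence record violates the alphabet or length contract."""


@dataclass(frozen=True)
class ProteinSequence:
    """An identified protein sequence over the canonical 20-letter alphabet.

    Validation is not enforced at construction so raw records can be carried
    to :func:`validate_sequence`; every downstream scoring operation assumes
    a validated sequence (canonical alphabet, length >= 2 so that at least
    one dipeptide exists).
    """

    id: str
    residues: str

    def __len__(self) -> int:
        return len(self.residues)

    @property
    def is_canonical(self) -> bool:
        return len(self.residues) >= 2 and set(self.residues) <= _AA_SET


@dataclass
class LabeledDataset:
    """Sequences plus parallel binary labels (1 = positive class)."""

    sequences: list[ProteinSequence]
    labels: list[int]

    def __post_init__(self) -> None:
        if len(self.sequences) != len(self.labels):
            raise ValueError(
                f"{len(self.sequences)} sequences but {len(self.labels)} labels"
            )
        if not self.sequences:
            raise ValueError("dataset is empty")
        bad = set(self.labels) - {POSITIVE, NEGATIVE}
        if bad:
            raise ValueError(f"labels must be 0/1, got {sorted(bad)}")

    def __len__(self) -> int:
        return len(self.sequences)

    @property
    def n_positive(self) -> int:
        return sum(self.labels)

    @property
    def n_negative(self) -> int:
        return len(self.labels) - self.n_positive

    def subset(self, indices: Sequence[int]) -> "LabeledDataset":
        return LabeledDataset(
            [self.sequences[i] for i in indices],
            [self.labels[i] for i in indices],
        )

    def require_both_classes(self) -> None:
        if self.n_positive == 0 or self.n_negative == 0:
            raise ValueError(
                "training requires at least one sequence of each class "
                f"(got {self.n_positive} positive, {self.n_negative} negative)"
            )

    @classmethod
    def from_fasta(
        cls,
        positive_path: str | Path,
        negative_path: str | Path,
        policy: Literal["strict", "drop", "mask"] = "strict",
    ) -> "LabeledDataset":
        """Build a labeled dataset from a positive and a negative FASTA file."""
        seqs: list[ProteinSequence] = []
        labels: list[int] = []
        for path, label in ((positive_path, POSITIVE), (negative_path, NEGATIVE)):
            for raw in read_fasta(path):
                validated = validate_sequence(raw, policy=policy)
                if validated is None:
                    continue
                seqs.append(validated)
                labels.append(label)
        return cls(seqs, labels)


def read_fasta(path: str | Path) -> list[ProteinSequence]:
    """Read a FASTA file into raw (unvalidated) protein sequence records.

    Headers are taken up to the first whitespace as the id; sequence lines
    are concatenated and uppercased. Records appear in file order. Duplicate
    ids are permitted (classification is per record) but logged.
    """
    records = []
    with open(path) as handle:
        for rec in SeqIO.parse(handle, "fasta"):
            residues = str(rec.seq).upper()
            if not residues:
                raise SequenceError(f"record {rec.id!r} in {path} has an empty sequence")
            records.append(ProteinSequence(id=rec.id, residues=residues))
    dup = [i for i, n in Counter(r.id for r in records).items() if n > 1]
    if dup:
        logger.warning("duplicate FASTA ids in %s: %s", path, ", ".join(dup))
    return records


def write_fasta(records: Iterable[ProteinSequence], path: str | Path) -> None:
    """Write records to FASTA, preserving ids and residue strings exactly."""
    seqio_records = (
        SeqRecord(Seq(r.residues), id=r.id, description="") for r in records
    )
    with open(path, "w") as handle:
        SeqIO.write(seqio_records, handle, "fasta-2line")


@dataclass(frozen=True)
class Rejection:
    """A record refused by validation, with the offending reason."""

    sequence: ProteinSequence
    reason: str


def validate_sequence(
    raw: ProteinSequence,
    policy: Literal["strict", "drop", "mask"] = "strict",
) -> ProteinSequence | None:
    """Validate a raw sequence against the canonical alphabet.

    Policies:

    - ``strict``: any non-canonical letter (B, J, O, U, X, Z, ...) raises
      :class:`SequenceError`. Default — benchmark data is curated and silent
      mutation of inputs would corrupt the compositions.
    - ``drop``: non-canonical letters are removed; the sequence is kept if
      at least 2 residues remain, otherwise rejected as too short.
    - ``mask``: the record is excluded (returns ``None``) but never altered;
      the exclusion is logged.

    A resulting length below 2 is always a rejection: a one-residue sequence
    has no dipeptides and no defined score.
    """
    residues = raw.residues
    noncanonical = sorted(set(residues) - _AA_SET)
    if noncanonical:
        if policy == "strict":
            raise SequenceError(
                f"sequence {raw.id!r} contains non-canonical residue(s) "
                f"{''.join(noncanonical)!r}"
            )
        if policy == "mask":
            logger.warning(
                "sequence %r excluded (non-canonical residues %s)",
                raw.id, "".join(noncanonical),
            )
            return None
        if policy == "drop":
            residues = "".join(c for c in residues if c in _AA_SET)
    if len(residues) < 2:
        raise SequenceError(f"sequence {raw.id!r} too short after validation")
    return ProteinSequence(id=raw.id, residues=residues)


def iter_validated(
    records: Iterable[ProteinSequence],
    policy: Literal["strict", "drop", "mask"] = "strict",
) -> Iterator[ProteinSequence]:
    for raw in records:
        validated = validate_sequence(raw, policy=policy)
        if validated is not None:
            yield validated
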