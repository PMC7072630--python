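"""Physicochemical-property correlation of amino-acid propensities.

The interpretation stage of the scoring card method: the 20 amino-acid
propensity scores derived from a trained card are correlated (Pearson R)
against AAindex1 property scales — alpha-helix propensity, hydrophobicity,
side-chain size and so on. Scales whose |R| exceeds a cutoff (0.5 by
default, strict inequality) are flagged as informative for the positive
class. Scales with missing ("NA") entries are excluded from correlation but
counted, so a 544-in / 531-used style accounting is always available.

A full AAindex1 flat file can be supplied by the user; a small bundled
excerpt of published reference scales keeps the stage testable offline.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .sequence_io import AMINO_ACIDS

#: AAindex1 value-row order: two rows of ten, A R N D C Q E G H I / L K M F P S T W Y V.
AAINDEX_ORDER = "ARNDCQEGHILKMFPSTWYV"
_REORDER = [AAINDEX_ORDER.index(aa) for aa in AMINO_ACIDS]


class AAindexFormatError(ValueError):
    """An AAindex1 block could not be parsed."""


@dataclass(frozen=True)
class PhysicochemicalProperty:
    """One AAindex property: accession, description, 20 amino-acid values.

    ``values`` are keyed to the package's alphabetical amino-acid order
    (A, C, D, ... Y), re-ordered from the AAindex file layout. Missing
    entries are NaN and mark the property incomplete.
    """

    accession: str
    description: str
    values: np.ndarray

    @property
    def complete(self) -> bool:
        return not np.isnan(self.values).any()


def _parse_values(lines: list[str], accession: str) -> np.ndarray:
    tokens: list[str] = []
    for line in lines:
        tokens.extend(line.split())
    if len(tokens) != 20:
        raise AAindexFormatError(
            f"property {accession}: expected 20 values, got {len(tokens)}"
        )
    vals = np.array(
        [float("nan") if t.upper() == "NA" else float(t) for t in tokens]
    )
    return vals[_REORDER]


def read_aaindex(path: str | Path) -> list[PhysicochemicalProperty]:
    """Parse an AAindex1 flat file into property records.

    Each entry is an ``H`` accession line, an optional ``D`` description,
    an ``I`` line introducing two rows of ten values in the standard
    AAindex amino-acid order, and a ``//`` terminator. Other record types
    (R, A, T, J, C) are ignored. An empty file yields an empty list.
    """
    properties: list[PhysicochemicalProperty] = []
    accession: str | None = None
    description = ""
    value_lines: list[str] = []
    in_values = False
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if line.startswith("H "):
                accession = line[2:].strip()
                description, value_lines, in_values = "", [], False
            elif line.startswith("D ") and accession is not None:
                description = line[2:].strip()
            elif line.startswith("I ") and accession is not None:
                in_values = True
            elif line.startswith("//"):
                if accession is not None:
                    properties.append(
                        PhysicochemicalProperty(
                            accession, description,
                            _parse_values(value_lines, accession),
                        )
                    )
                accession, in_values, value_lines = None, False, []
            elif in_values:
                value_lines.append(line)
    if accession is not None:
        raise AAindexFormatError(f"property {accession}: unterminated block")
    return properties


def correlate_propensity(
    propensity: np.ndarray, pcp: PhysicochemicalProperty
) -> float:
    """Pearson R between 20 amino-acid propensities and one property scale."""
    if not pcp.complete:
        raise ValueError(
            f"property {pcp.accession} has missing values; filter incomplete "
            "properties before correlating"
        )
    propensity = np.asarray(propensity, dtype=float)
    if propensity.std() == 0 or pcp.values.std() == 0:
        raise ValueError(
            "Pearson R is undefined for a constant vector "
            f"(property {pcp.accession} vs propensity)"
        )
    return float(stats.pearsonr(propensity, pcp.values)[0])


@dataclass
class CorrelationReport:
    """Per-property correlation results, sorted by |R| descending."""

    table: pd.DataFrame  # columns: accession, description, R, selected
    n_excluded_incomplete: int
    cutoff: float

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False, float_format="%.4f")


def informative_pcps(
    propensity: np.ndarray,
    pcps: list[PhysicochemicalProperty],
    cutoff: float = 0.5,
) -> CorrelationReport:
    """Correlate a propensity vector against property scales, flag |R| > cutoff.

    Selection uses strict inequality at the cutoff. Incomplete properties
    are excluded from correlation but counted in the report, so none is
    silently dropped.
    """
    complete = [p for p in pcps if p.complete]
    if not complete:
        raise ValueError("no complete property to correlate against")
    rows = [
        {
            "accession": p.accession,
            "description": p.description,
            "R": correlate_propensity(propensity, p),
        }
        for p in complete
    ]
    table = pd.DataFrame(rows)
    table["selected"] = table["R"].abs() > cutoff
    table = table.reindex(
        table["R"].abs().sort_values(ascending=False, kind="stable").index
    ).reset_index(drop=True)
    return CorrelationReport(table, len(pcps) - len(complete), cutoff)


# --------------------------------------------------------------- bundled data
def load_reference_scales() -> list[PhysicochemicalProperty]:
    """The three bundled published property scales (AAindex1-format excerpt).

    KOEP990101 (alpha-helix propensity), WOLR790101 (hydrophobicity index)
    and a side-chain size scale that has no AAindex accession and carries
    the synthetic accession SIDECHAIN.
    """
    ref = resources.files("pvpscm.data") / "reference_scales_aaindex.txt"
    with resources.as_file(ref) as path:
        return read_aaindex(path)


def load_reference_propensity() -> pd.Series:
    """Published amino-acid propensity scores of the PVP benchmark model.

    20 values indexed by amino acid (alphabetical), as printed by the
    reference scoring-card study; used as a worked-example input for the
    correlation stage.
    """
    ref = resources.files("pvpscm.data") / "reference_aa_propensity.tsv"
    with resources.as_file(ref) as path:
        table = pd.read_csv(path, sep="\t", index_col="amino_acid")
    return table["propensity"].reindex(list(AMINO_ACIDS))


def load_reference_composition() -> pd.DataFrame:
    """Published per-class amino-acid compositions (%) of the PVP benchmark.

    Columns: positive_pct, negative_pct, printed_difference, printed_rank —
    the worked-example input for the composition-difference analysis.
    """
    ref = resources.files("pvpscm.data") / "reference_composition.tsv"
    with resources.as_file(ref) as path:
        return pd.read_csv(path, sep="\t", index_col="amino_acid")
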