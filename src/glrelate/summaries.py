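"""Summary statistics derived from the Jacquard vector and the 2D-SFS.

Two families of pairwise statistics are provided:

* IBD-based: linear combinations of the nine condensed Jacquard
  coefficients (relatedness, kinship, per-individual inbreeding, and the
  identity/fraternity/zygosity decomposition), which require population
  allele frequencies to estimate J.
* IBS-based: ratios of cells of the pairwise 3x3 joint genotype-class
  distribution (2D-SFS) — R0, R1 and the KING-robust kinship — which need
  no allele frequencies but assume non-inbred individuals.

The 2D-SFS cells are labelled row-major A..I with individual a's genotype
(0, 1, 2 copies of the counted allele) on rows::

    A B C        a=0
    D E F        a=1
    G H I        a=2
        (b=0, 1, 2 on columns)

so E is the double heterozygote and C, G the opposite homozygotes — the
orientation under which R0, R1 and KING take their usual closed forms.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass

import numpy as np

from .core import validate_jacquard

__all__ = [
    "IbdSummaries",
    "IbsSummaries",
    "ibd_summaries",
    "ibs_summaries",
    "RESULT_COLUMNS",
]

#: Column contract for per-pair result tables.
RESULT_COLUMNS = [
    "ida", "idb",
    "J1", "J2", "J3", "J4", "J5", "J6", "J7", "J8", "J9",
    "rab", "Fa", "Fb", "theta", "F12", "F21",
    "fraternity", "identity", "zygosity", "ibd23", "Fdiff",
    "R0", "R1", "King",
    "loglik", "nSites", "nIter", "converged", "seed",
]


@dataclass(frozen=True)
class IbdSummaries:
    """Linear-combination statistics of the condensed Jacquard coefficients.

    rab
        Relatedness: expected proportion of homologous alleles IBD.
    Fa, Fb
        Inbreeding coefficients of individuals a and b.
    theta
        Kinship coefficient.
    F12, F21
        Directional inbred-relatedness terms.
    fraternity, identity, zygosity
        Double-pair IBD decomposition.
    ibd23, Fdiff
        The two additional identifiable combinations for biallelic markers.
    """

    rab: float
    Fa: float
    Fb: float
    theta: float
    F12: float
    F21: float
    fraternity: float
    identity: float
    zygosity: float
    ibd23: float
    Fdiff: float

    def as_dict(self) -> dict[str, float]:
        return asdict(self)


@dataclass(frozen=True)
class IbsSummaries:
    """Allele-frequency-free statistics from the pairwise 2D-SFS."""

    R0: float
    R1: float
    King: float

    def as_dict(self) -> dict[str, float]:
        return asdict(self)


def ibd_summaries(j) -> IbdSummaries:
    """All IBD-based summary statistics of a Jacquard vector ``(J1..J9)``."""
    j = validate_jacquard(j)
    j1, j2, j3, j4, j5, j6, j7, j8, _j9 = j
    return IbdSummaries(
        rab=float(j1 + j7 + 0.75 * (j3 + j5) + 0.5 * j8),
        Fa=float(j1 + j2 + j3 + j4),
        Fb=float(j1 + j2 + j5 + j6),
        theta=float(j1 + 0.5 * (j3 + j5 + j7) + 0.25 * j8),
        F12=float(j1 + 0.5 * j3),
        F21=float(j1 + 0.5 * j5),
        fraternity=float(j2 + j7),
        identity=float(j1),
        zygosity=float(j1 + j2 + j7),
        ibd23=float(j1 + j2 + j3 + j5 + j7 + 0.5 * (j4 + j6 + j8)),
        Fdiff=float(0.5 * (j4 - j6)),
    )


def _ratio(num: float, den: float) -> float:
    """Cell-ratio with NaN for an undefined (zero-denominator) statistic."""
    return num / den if den > 0 else float("nan")


def ibs_summaries(s) -> IbsSummaries:
    """R0, R1 and the KING-robust kinship from a pairwise 2D-SFS.

    Parameters
    ----------
    s
        3x3 joint genotype-class distribution (rows: individual a's
        genotype; columns: individual b's).  Any positive scaling is
        accepted; the statistics are ratios and scale-invariant.

    Undefined ratios (zero denominator) are reported as NaN so that
    tabulation over many pairs can proceed.
    """
    s = np.asarray(s, dtype=float)
    if s.shape != (3, 3):
        raise ValueError(f"2D-SFS must be 3x3; got {s.shape}")
    if np.min(s) < 0:
        raise ValueError("2D-SFS cells must be non-negative")
    (_a, b, c), (d, e, f_), (g, h, _i) = s
    het_discordant = b + d + h + f_
    opposite_hom = c + g
    return IbsSummaries(
        R0=_ratio(opposite_hom, e),
        R1=_ratio(e, het_discordant + opposite_hom),
        King=_ratio(e - 2.0 * opposite_hom, het_discordant + 2.0 * e),
    )
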