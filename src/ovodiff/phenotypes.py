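"""Morphometry and the classical tests used for phenotype comparisons.

Oocyte morphometry: perimeters traced along the oolemma are converted to
diameters (d = P / pi) and volumes via a spherical approximation,
V = (4/3) pi (d/2)^3, reported in picoliters (1 pL = 1000 um^3).

Count data (developmental arrest distributions, embryo-transfer outcomes,
lineage compositions) are compared with Fisher's exact test (2x2,
probability-mass two-sided convention) or the chi-square homogeneity test
(k x 2, no continuity correction by default); continuous measurements
(zona pellucida thickness, diameters, weights) with the two-sample
Wilcoxon rank-sum test, exact when feasible.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .datamodel import ContingencyTable

UM3_PER_PL = 1000.0


def diameter_from_perimeter(perimeter_um: float) -> float:
    """Oocyte diameter from its traced perimeter: d = P / pi (micrometers)."""
    if perimeter_um <= 0:
        raise ValueError("perimeter must be positive")
    return perimeter_um / math.pi


def sphere_volume_pl(diameter_um: float) -> float:
    """Volume of a sphere of the given diameter, in picoliters."""
    if diameter_um <= 0:
        raise ValueError("diameter must be positive")
    r = diameter_um / 2.0
    return (4.0 / 3.0) * math.pi * r**3 / UM3_PER_PL


@dataclass
class OocyteMorphometry:
    """Per-oocyte measurements; diameter may be derived from the perimeter."""

    diameter_um: float
    perimeter_um: float | None = None
    zp_thickness_um: float | None = None

    @classmethod
    def from_perimeter(
        cls, perimeter_um: float, zp_thickness_um: float | None = None
    ) -> "OocyteMorphometry":
        return cls(
            diameter_um=diameter_from_perimeter(perimeter_um),
            perimeter_um=perimeter_um,
            zp_thickness_um=zp_thickness_um,
        )

    @property
    def volume_pl(self) -> float:
        return sphere_volume_pl(self.diameter_um)


def _as_table(table) -> np.ndarray:
    if isinstance(table, ContingencyTable):
        return table.counts
    return ContingencyTable(np.asarray(table)).counts


def fisher_exact_2x2(table) -> tuple[float, float]:
    """Fisher's exact test on a 2x2 table: (odds ratio, two-sided p).

    The two-sided p follows the probability-mass convention: the sum of
    all conditional table probabilities not exceeding the observed table's
    probability (within a 1e-7 relative tolerance).  The odds ratio is the
    sample odds ratio ad/bc (0 and inf allowed).
    """
    counts = _as_table(table)
    if counts.shape != (2, 2):
        raise ValueError("fisher_exact_2x2 requires a 2x2 table")
    (a, b), (c, d) = counts
    if b * c == 0:
        odds = math.inf if a * d > 0 else math.nan
    else:
        odds = (a * d) / (b * c)
    _, p = stats.fisher_exact(counts, alternative="two-sided")
    return float(odds), float(p)


def wilcoxon_rank_sum(x, y, mode: str = "auto") -> tuple[float, str]:
    """Two-sample Wilcoxon rank-sum (Mann-Whitney) two-sided p-value.

    ``mode="auto"`` enumerates the exact rank-sum distribution when the
    pooled size is at most 12 and the data are tie-free, and falls back to
    the tie-corrected normal approximation otherwise.  Returns (p, mode
    actually used).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both groups must be non-empty")
    pooled = np.concatenate([x, y])
    has_ties = len(np.unique(pooled)) < pooled.size
    if mode == "auto":
        mode = "exact" if (pooled.size <= 12 and not has_ties) else "normal_approx"
    if mode == "exact":
        if has_ties:
            raise ValueError("exact mode is undefined with ties; use normal_approx")
        p = stats.mannwhitneyu(x, y, alternative="two-sided", method="exact")[1]
    elif mode == "normal_approx":
        p = stats.mannwhitneyu(x, y, alternative="two-sided", method="asymptotic")[1]
    else:
        raise ValueError(f"unknown mode {mode!r}")
    return float(min(p, 1.0)), mode


def chi_square_homogeneity(
    table, yates: bool = False
) -> tuple[float, int, float]:
    """Chi-square homogeneity test on a k x 2 count table.

    Returns (X^2, degrees of freedom, upper-tail p).  No continuity
    correction unless ``yates=True``.  Warns when any expected count is
    below 5 (the usual asymptotic-validity caveat).
    """
    counts = _as_table(table)
    expected = stats.contingency.expected_freq(counts)
    if (expected < 5).any():
        warnings.warn(
            "chi-square approximation may be poor: expected count < 5",
            stacklevel=2,
        )
    stat, p, dof, _ = stats.chi2_contingency(counts, correction=yates)
    return float(stat), int(dof), float(p)
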