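"""Demographic comparisons and SUV-biomarker correlations.

Categorical demographics are compared with the Pearson chi-square test on
2x2 tables (no continuity correction, 1 df); normally distributed
continuous variables with a two-sample t-test computable from summary
statistics (Welch form); non-normal ones with the Mann-Whitney U test.
Seed-region SUV is related to peripheral biomarkers (AST, prothrombin
time) by Pearson correlation with a t-based two-sided p.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "ContingencyTable2x2",
    "CorrelationReport",
    "chi_square_2x2",
    "two_sample_t_from_summary",
    "mann_whitney_u",
    "suv_biomarker_correlation",
    "demographics_table",
]


class DegenerateTableError(ValueError):
    """A 2x2 table with a zero row or column margin."""


@dataclass(frozen=True)
class ContingencyTable2x2:
    """Counts [[a, b], [c, d]]: rows = groups, columns = trait yes/no."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self):
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("counts must be >= 0")
        if self.a + self.b + self.c + self.d == 0:
            raise ValueError("table total must be > 0")

    @property
    def counts(self) -> np.ndarray:
        return np.array([[self.a, self.b], [self.c, self.d]], dtype=float)


@dataclass(frozen=True)
class CorrelationReport:
    pair: tuple[str, str]
    r: float
    p: float
    n: int


def chi_square_2x2(
    table: ContingencyTable2x2 | np.ndarray, correction: bool = False
) -> tuple[float, float]:
    """Pearson chi-square on a 2x2 table, 1 df, uncorrected by default."""
    counts = (
        table.counts
        if isinstance(table, ContingencyTable2x2)
        else np.asarray(table, dtype=float)
    )
    if counts.shape != (2, 2):
        raise ValueError("expected a 2x2 table")
    if np.any(counts.sum(axis=0) == 0) or np.any(counts.sum(axis=1) == 0):
        raise DegenerateTableError("zero row or column margin")
    res = stats.chi2_contingency(counts, correction=correction)
    return float(res.statistic), float(res.pvalue)


def two_sample_t_from_summary(
    mean1: float, se1: float, n1: int, mean2: float, se2: float, n2: int
) -> tuple[float, float]:
    """Two-sample t-test from group means and standard errors (Welch form).

    t = (mean1 - mean2) / sqrt(se1^2 + se2^2), with Welch-Satterthwaite
    degrees of freedom.
    """
    if se1 < 0 or se2 < 0:
        raise ValueError("standard errors must be >= 0")
    if n1 < 2 or n2 < 2:
        raise ValueError("need n >= 2 per group")
    v = se1**2 + se2**2
    if v == 0:
        if mean1 == mean2:
            raise ValueError("t undefined: equal means with zero variance")
        return float(np.inf) * np.sign(mean1 - mean2), 0.0
    t = (mean1 - mean2) / np.sqrt(v)
    df = v**2 / (se1**4 / (n1 - 1) + se2**4 / (n2 - 1))
    p = 2.0 * stats.t.sf(abs(t), df)
    return float(t), float(p)


def mann_whitney_u(x, y) -> tuple[float, float, float]:
    """Mann-Whitney U with midrank ties.

    Returns ``(U, z, p)`` where U counts pairs in which x precedes y, z is
    the tie-corrected normal approximation (no continuity correction), and
    p is scipy's two-sided p-value (exact for small tie-free samples,
    asymptotic otherwise).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    n1, n2 = x.size, y.size
    pooled = np.concatenate([x, y])
    if np.all(pooled == pooled[0]):
        warnings.warn("all values identical; p set to 1", stacklevel=2)
        return n1 * n2 / 2.0, 0.0, 1.0
    ranks = stats.rankdata(pooled)
    u = ranks[:n1].sum() - n1 * (n1 + 1) / 2.0
    mu = n1 * n2 / 2.0
    _, tie_counts = np.unique(pooled, return_counts=True)
    n = n1 + n2
    tie_term = ((tie_counts**3 - tie_counts).sum()) / (n * (n - 1))
    sigma = np.sqrt(n1 * n2 / 12.0 * (n + 1 - tie_term))
    z = 0.0 if sigma == 0 else (u - mu) / sigma
    p = float(stats.mannwhitneyu(x, y, alternative="two-sided").pvalue)
    return float(u), float(z), p


def suv_biomarker_correlation(
    suv_seed, biomarker, pair: tuple[str, str] = ("SUV", "biomarker")
) -> CorrelationReport:
    """Pearson correlation between seed-region SUV and a biomarker."""
    x = np.asarray(suv_seed, dtype=float)
    y = np.asarray(biomarker, dtype=float)
    if x.size != y.size:
        raise ValueError("samples must align")
    if x.size < 4:
        raise ValueError("need n >= 4")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise ValueError("values must be finite")
    if x.std() == 0 or y.std() == 0:
        raise ValueError("correlation undefined for zero-variance input")
    res = stats.pearsonr(x, y)
    return CorrelationReport(pair, float(res.statistic), float(res.pvalue),
                             int(x.size))


def demographics_table(tables: dict[str, np.ndarray]) -> pd.DataFrame:
    """Chi-square tests for a set of per-variable 2x2 count tables."""
    rows = []
    for name, counts in tables.items():
        counts = np.asarray(counts)
        try:
            stat, p = chi_square_2x2(counts)
        except DegenerateTableError:
            stat, p = np.nan, np.nan
        rows.append(
            {
                "variable": name,
                "yes_group1": int(counts[0, 0]),
                "yes_group2": int(counts[1, 0]),
                "chi2": stat,
                "p": p,
            }
        )
    return pd.DataFrame(rows).set_index("variable")
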