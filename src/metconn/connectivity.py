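"""Group-level metabolic connectivity.

Metabolic connectivity is a *group-level* construct: for each pair of brain
regions, the Pearson correlation of their normalized SUVs is computed
*across the subjects* of one group, yielding one 90x90 matrix per group.
Between-group differences in an edge are tested by comparing two
independent correlations with the Fisher r-to-z two-sample statistic,

    z = (atanh(r1) - atanh(r2)) / sqrt(1/(n1-3) + 1/(n2-3)),

with a subject-level permutation alternative available for cross-checking.
Edge-wise p-values are controlled with Benjamini-Hochberg FDR; the default
test family is the 89 seed edges of the seed-region analysis.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .regions import AAL90_REGIONS, region_index

__all__ = [
    "ConnectivityMatrix",
    "correlation_matrix",
    "seed_connectivity",
    "compare_edge_correlations",
    "permutation_edge_pvalue",
    "fdr_adjust",
    "seed_edge_tests",
]


@dataclass
class ConnectivityMatrix:
    """Cross-subject Pearson correlation matrix for one group."""

    r: np.ndarray
    n_subjects: int
    group: str = ""
    region_names: tuple[str, ...] = AAL90_REGIONS

    def __post_init__(self):
        r = np.asarray(self.r, dtype=float)
        if r.ndim != 2 or r.shape[0] != r.shape[1]:
            raise ValueError("r must be square")
        if not np.allclose(r, r.T, atol=1e-12):
            raise ValueError("r must be symmetric")
        if not np.allclose(np.diag(r), 1.0):
            raise ValueError("r must have unit diagonal")
        if np.nanmax(np.abs(r)) > 1 + 1e-12:
            raise ValueError("correlations must lie in [-1, 1]")
        self.r = r

    def to_frame(self) -> pd.DataFrame:
        names = list(self.region_names)
        return pd.DataFrame(self.r, index=names, columns=names)


def correlation_matrix(
    suv: np.ndarray | pd.DataFrame,
    group: str = "",
    region_names: tuple[str, ...] | None = None,
) -> ConnectivityMatrix:
    """Pearson correlation across subjects between every pair of ROI columns.

    Zero-variance columns (a degenerate input the pipeline should survive)
    get correlation 0 with every other region, with a warning.
    """
    if isinstance(suv, pd.DataFrame):
        if region_names is None:
            region_names = tuple(suv.columns)
        x = suv.to_numpy(dtype=float)
    else:
        x = np.asarray(suv, dtype=float)
        if region_names is None:
            region_names = AAL90_REGIONS if x.shape[1] == 90 else tuple(
                f"ROI{i+1}" for i in range(x.shape[1])
            )
    n, p = x.shape
    if n < 3:
        raise ValueError(f"need >= 3 subjects, got {n}")
    if np.isnan(x).any():
        raise ValueError("SUV matrix contains missing values")
    sd = x.std(axis=0)
    constant = sd == 0
    if constant.any():
        warnings.warn(
            f"{int(constant.sum())} zero-variance region(s); their "
            "correlations are set to 0",
            stacklevel=2,
        )
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.corrcoef(x, rowvar=False)
    r[np.isnan(r)] = 0.0
    np.fill_diagonal(r, 1.0)
    r = np.clip(r, -1.0, 1.0)
    return ConnectivityMatrix(r, n_subjects=n, group=group,
                              region_names=tuple(region_names))


def seed_connectivity(c: ConnectivityMatrix, seed: str) -> pd.Series:
    """The seed region's correlation with each of the other regions.

    Returns a Series of length ``n_regions - 1`` indexed by region name.
    """
    i = region_index(seed, c.region_names)
    names = [nm for k, nm in enumerate(c.region_names) if k != i]
    vals = np.delete(c.r[i], i)
    return pd.Series(vals, index=names, name=seed)


def compare_edge_correlations(
    r1: float, n1: int, r2: float, n2: int
) -> tuple[float, float]:
    """Fisher r-to-z test for the difference of two independent correlations.

    Returns (z, two-sided normal p).
    """
    for r in (r1, r2):
        if abs(r) >= 1.0:
            raise ValueError("|r| = 1 has an infinite Fisher transform")
    for n in (n1, n2):
        if n < 4:
            raise ValueError("need n >= 4 per group")
    se = np.sqrt(1.0 / (n1 - 3) + 1.0 / (n2 - 3))
    z = (np.arctanh(r1) - np.arctanh(r2)) / se
    p = 2.0 * stats.norm.sf(abs(z))
    return float(z), float(p)


def permutation_edge_pvalue(
    x1: np.ndarray,
    y1: np.ndarray,
    x2: np.ndarray,
    y2: np.ndarray,
    n_perm: int = 10_000,
    rng: np.random.Generator | int | None = None,
) -> tuple[float, float]:
    """Subject-level permutation test for a correlation difference.

    Pools the subjects of both groups, permutes group membership ``n_perm``
    times (group sizes preserved), and recomputes the Fisher statistic
    atanh(r1) - atanh(r2) each time.  Returns (observed statistic,
    empirical two-tailed p with the +1 convention).  This is the
    stochastic cross-check for :func:`compare_edge_correlations`.
    """
    rng = np.random.default_rng(rng)
    x = np.concatenate([x1, x2])
    y = np.concatenate([y1, y2])
    n1 = len(x1)
    n = len(x)

    def rdiff(idx):
        a = idx[:n1]
        b = idx[n1:]
        ra = np.corrcoef(x[a], y[a])[0, 1]
        rb = np.corrcoef(x[b], y[b])[0, 1]
        return np.arctanh(ra) - np.arctanh(rb)

    obs = rdiff(np.arange(n))
    null = np.empty(n_perm)
    for k in range(n_perm):
        null[k] = rdiff(rng.permutation(n))
    p = (1.0 + np.count_nonzero(np.abs(null) >= abs(obs))) / (1.0 + n_perm)
    return float(obs), float(p)


def fdr_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted q-values, input order preserved."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)) or np.isnan(p).any():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def seed_edge_tests(
    c1: ConnectivityMatrix,
    c2: ConnectivityMatrix,
    seed: str,
    method: str = "fisher",
    suv1: np.ndarray | None = None,
    suv2: np.ndarray | None = None,
    n_perm: int = 10_000,
    rng: np.random.Generator | int | None = None,
) -> pd.DataFrame:
    """Between-group tests on the 89 seed edges, with BH q-values.

    Columns: region, r_<group1>, r_<group2>, z, p, q.  The FDR family is the
    seed's edges (matching the seed-based connectivity analysis), not all
    4,005 edges.  ``method="fisher"`` (default) uses the deterministic
    r-to-z test; ``method="permutation"`` replaces each p with a
    subject-level permutation of the same statistic and needs the two
    groups' SUV matrices (subjects x regions, columns ordered as the
    connectivity matrices).
    """
    if method not in ("fisher", "permutation"):
        raise ValueError("method must be 'fisher' or 'permutation'")
    s1 = seed_connectivity(c1, seed)
    s2 = seed_connectivity(c2, seed)
    if list(s1.index) != list(s2.index):
        raise ValueError("groups have different region orderings")
    zs, ps = [], []
    for r1, r2 in zip(s1.to_numpy(), s2.to_numpy()):
        z, p = compare_edge_correlations(r1, c1.n_subjects, r2, c2.n_subjects)
        zs.append(z)
        ps.append(p)
    if method == "permutation":
        if suv1 is None or suv2 is None:
            raise ValueError("permutation method needs suv1 and suv2")
        rng = np.random.default_rng(rng)
        i = region_index(seed, c1.region_names)
        x1 = np.asarray(suv1, dtype=float)
        x2 = np.asarray(suv2, dtype=float)
        others = [k for k in range(len(c1.region_names)) if k != i]
        ps = [
            permutation_edge_pvalue(
                x1[:, i], x1[:, j], x2[:, i], x2[:, j],
                n_perm=n_perm, rng=rng,
            )[1]
            for j in others
        ]
    g1 = c1.group or "group1"
    g2 = c2.group or "group2"
    out = pd.DataFrame(
        {
            "region": s1.index,
            f"r_{g1}": s1.to_numpy(),
            f"r_{g2}": s2.to_numpy(),
            "z": zs,
            "p": ps,
            "q": fdr_adjust(ps),
        }
    )
    return out
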