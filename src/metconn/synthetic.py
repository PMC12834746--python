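"""Synthetic PET cohorts with the statistical structure the analysis assumes.

No raw patient data accompany the study this pipeline reimplements, so the
whole analysis chain is exercised on simulated cohorts: two groups of
subjects x 90 regions of normalized SUV drawn from group-specific
multivariate Gaussians, with

* a planted mean shift at a seed region (right postcentral gyrus) in the
  patient group,
* planted cross-subject *decorrelation* on named seed-target edges (right
  caudate, left amygdala, left hippocampus, left supramarginal gyrus),
* peripheral biomarkers (AST, PT) correlated with the seed-region SUV in the
  patient group via a Gaussian copula, and
* demographics reproducing the study's 2x2 count tables.

Correlation matrices with planted entries are repaired to the nearest
positive-semidefinite correlation matrix by eigenvalue clipping and
rescaling before sampling.
"""

from __future__ import annotations

import dataclasses
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .regions import (
    AAL90_REGIONS,
    DEFAULT_EDGE_TARGETS,
    DEFAULT_SEED_REGION,
    region_index,
)

__all__ = [
    "CohortConfig",
    "CohortDataset",
    "default_base_correlation",
    "nearest_psd_correlation",
    "plant_edge_correlation",
    "generate_cohort",
    "generate_demographics",
    "TABLE1_COUNTS",
]

#: Per-variable (patient_yes, control_yes) counts of the study's demographic
#: table, out of 70 subjects per group.
TABLE1_COUNTS: dict[str, tuple[int, int]] = {
    "male": (52, 42),
    "hypertension": (23, 13),
    "hyperglycemia": (10, 6),
    "hyperlipidemia": (14, 20),
    "smoking": (10, 1),
    "drinking": (6, 0),
}


def nearest_psd_correlation(c: np.ndarray, min_eig: float = 0.0) -> np.ndarray:
    """Repair a symmetric matrix to a positive-semidefinite correlation.

    Clips negative eigenvalues at ``min_eig``, reconstructs, and rescales to
    unit diagonal.  A valid correlation matrix passes through unchanged (up
    to floating-point noise).
    """
    c = np.asarray(c, dtype=float)
    c = (c + c.T) / 2.0
    w, v = np.linalg.eigh(c)
    if w.min() >= min_eig:
        out = c.copy()
    else:
        w = np.clip(w, min_eig, None)
        out = (v * w) @ v.T
    d = np.sqrt(np.clip(np.diag(out), 1e-300, None))
    out = out / np.outer(d, d)
    out = (out + out.T) / 2.0
    np.fill_diagonal(out, 1.0)
    return np.clip(out, -1.0, 1.0)


def plant_edge_correlation(
    c: np.ndarray,
    edges,
    tol: float = 1e-8,
    max_iter: int = 500,
) -> np.ndarray:
    """Set chosen off-diagonal correlations, repaired to a PSD correlation.

    ``edges`` is a list of ``(i, j, target_r)`` with integer indices.  With
    an empty list the input is returned unchanged.  The repair alternates
    between re-imposing the planted entries and projecting onto the PSD
    correlation matrices (eigenvalue clipping + unit-diagonal rescaling),
    so the planted entries are honored to within ``tol`` whenever a PSD
    matrix with those entries exists near the input; non-targeted entries
    absorb the (typically much smaller) adjustment.
    """
    c = np.asarray(c, dtype=float)
    edges = list(edges)
    if not edges:
        return c.copy()
    for i, j, r in edges:
        if i == j:
            raise ValueError("cannot plant a diagonal entry")
        if abs(r) >= 1.0:
            raise ValueError(f"|target r| must be < 1, got {r}")
    out = c.copy()
    for _ in range(max_iter):
        for i, j, r in edges:
            out[i, j] = out[j, i] = r
        out = nearest_psd_correlation(out)
        if max(abs(out[i, j] - r) for i, j, r in edges) < tol:
            break
    else:
        worst = max(abs(out[i, j] - r) for i, j, r in edges)
        warnings.warn(
            f"planted entries converged only to within {worst:.2e}",
            stacklevel=2,
        )
    return out


def default_base_correlation(n_rois: int = 90) -> np.ndarray:
    """Smoothly structured inter-regional coupling.

    Exponential decay ``0.6 ** (1 + |i - j| / 10)`` plus a uniform 0.2
    floor, repaired to PSD — a stand-in for the strong, distance-graded
    positive coupling of regional glucose metabolism.
    """
    idx = np.arange(n_rois)
    d = np.abs(idx[:, None] - idx[None, :])
    c = 0.6 ** (1.0 + d / 10.0) + 0.2
    np.fill_diagonal(c, 1.0)
    return nearest_psd_correlation(c)


@dataclass
class CohortConfig:
    """Generator settings; the defaults are the study conditions.

    ``mean_shift_delta`` is in SUV-ratio units and defaults to half the
    regional SD (0.5 * 0.1); ``decorrelated_edges`` carry the patient-group
    target correlations, while ``edge_base_r`` is planted on the same edges
    in the control group so the planted contrast is 0.6 -> 0.2.
    """

    n_per_group: int = 70
    n_rois: int = 90
    region_names: tuple[str, ...] = AAL90_REGIONS
    base_correlation_matrix: np.ndarray | None = None
    seed_roi: str = DEFAULT_SEED_REGION
    mean_shift_delta: float = 0.05
    suv_sd: float = 0.1
    decorrelated_edges: tuple = tuple(
        (DEFAULT_SEED_REGION, t, 0.2) for t in DEFAULT_EDGE_TARGETS
    )
    edge_base_r: float = 0.6
    biomarker_effects: tuple = (("AST", -0.277), ("PT", 0.256))
    demographics_counts: dict = field(
        default_factory=lambda: dict(TABLE1_COUNTS)
    )
    rng_seed: int = 0

    def __post_init__(self):
        if self.n_per_group < 3:
            raise ValueError("n_per_group must be >= 3")
        if len(self.region_names) != self.n_rois:
            raise ValueError("region_names length must equal n_rois")
        for _, _, r in self.decorrelated_edges:
            if abs(r) >= 1.0:
                raise ValueError("|target r| must be < 1")
        for name, (a, b) in self.demographics_counts.items():
            if a < 0 or b < 0:
                raise ValueError(f"negative count for {name}")

    def _edge_indices(self):
        return [
            (region_index(a, self.region_names),
             region_index(b, self.region_names), r)
            for a, b, r in self.decorrelated_edges
        ]

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["region_names"] = list(self.region_names)
        if self.base_correlation_matrix is not None:
            d["base_correlation_matrix"] = np.asarray(
                self.base_correlation_matrix
            ).tolist()
        d["decorrelated_edges"] = [list(e) for e in self.decorrelated_edges]
        d["biomarker_effects"] = [list(e) for e in self.biomarker_effects]
        return d


@dataclass
class CohortDataset:
    """One simulated two-group cohort, ready for every downstream stage."""

    suv: pd.DataFrame            # subjects x ROIs, columns = region names
    group: pd.Series             # "LS" | "HC" per subject
    covariates: pd.DataFrame     # age, sex (M|F), bmi
    biomarkers: pd.DataFrame     # AST (U/L), PT (s)
    region_names: tuple[str, ...]
    config: CohortConfig

    def __post_init__(self):
        if len(self.region_names) != self.suv.shape[1]:
            raise ValueError("region_names must match SUV columns")
        for other in (self.group, self.covariates):
            if not self.suv.index.equals(other.index):
                raise ValueError("subject indices disagree across tables")
        if self.suv.isna().any().any():
            raise ValueError("SUV matrix contains missing values")

    def group_suv(self, label: str) -> pd.DataFrame:
        return self.suv.loc[self.group == label]

    def write(self, outdir: str | Path) -> None:
        """Write suv.tsv, manifest.tsv and a config echo (JSON)."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.suv.to_csv(outdir / "suv.tsv", sep="\t", index_label="subject")
        manifest = pd.concat(
            [self.group.rename("group"), self.covariates, self.biomarkers],
            axis=1,
        )
        manifest.to_csv(outdir / "manifest.tsv", sep="\t",
                        index_label="subject")
        with open(outdir / "cohort_config.json", "w") as fh:
            json.dump(self.config.to_dict(), fh, indent=2)


def _sample_mvn(rng, mean, corr, sd, size):
    cov = corr * np.outer(sd, sd)
    return rng.multivariate_normal(mean, cov, size=size, method="eigh")


def generate_cohort(config: CohortConfig) -> CohortDataset:
    """Draw one cohort: patient group "LS" first, controls "HC" after.

    Fully reproducible from ``config.rng_seed``; independent substreams are
    derived for SUV, covariates and biomarkers so adding a component never
    perturbs the others.
    """
    n = config.n_per_group
    p = config.n_rois
    ss = np.random.SeedSequence(config.rng_seed)
    rng_suv, rng_cov, rng_bio = (np.random.default_rng(s) for s in ss.spawn(3))

    base = (
        default_base_correlation(p)
        if config.base_correlation_matrix is None
        else nearest_psd_correlation(config.base_correlation_matrix)
    )
    edges = config._edge_indices()
    corr_hc = plant_edge_correlation(
        base, [(i, j, config.edge_base_r) for i, j, _ in edges]
    )
    corr_ls = plant_edge_correlation(corr_hc, edges)

    seed_idx = region_index(config.seed_roi, config.region_names)
    mu = np.ones(p)
    mu_ls = mu.copy()
    mu_ls[seed_idx] += config.mean_shift_delta
    sd = np.full(p, config.suv_sd)

    suv_ls = _sample_mvn(rng_suv, mu_ls, corr_ls, sd, n)
    suv_hc = _sample_mvn(rng_suv, mu, corr_hc, sd, n)
    suv = np.vstack([suv_ls, suv_hc])
    if not np.isfinite(suv).all():
        raise RuntimeError("cohort generation produced non-finite SUVs")

    subjects = [f"S{k+1:03d}" for k in range(2 * n)]
    group = pd.Series(["LS"] * n + ["HC"] * n, index=subjects, name="group")
    suv_df = pd.DataFrame(suv, index=subjects,
                          columns=list(config.region_names))

    # covariates: magnitudes are conveniences roughly matching the study's
    # demographic table, not claims about LS biology
    age = np.concatenate([rng_cov.normal(54, 8, n), rng_cov.normal(50, 6, n)])
    sex_p = np.concatenate([np.full(n, 52 / 70), np.full(n, 42 / 70)])
    sex = np.where(rng_cov.random(2 * n) < sex_p, "M", "F")
    bmi = np.concatenate(
        [rng_cov.normal(24.6, 2.5, n), rng_cov.normal(23.6, 2.8, n)]
    )
    covariates = pd.DataFrame(
        {"age": np.round(age, 1), "sex": sex, "bmi": np.round(bmi, 2)},
        index=subjects,
    )

    # biomarkers: Gaussian copula on the patient group's seed-ROI SUV;
    # controls get independent draws from the same marginals
    marginals = {"AST": (25.0, 8.0), "PT": (12.5, 1.0)}
    z_seed = suv_ls[:, seed_idx]
    z_seed = (z_seed - z_seed.mean()) / z_seed.std()
    bio = {}
    for name, target_r in config.biomarker_effects:
        m, s = marginals.get(name, (0.0, 1.0))
        eps = rng_bio.standard_normal(n)
        latent_ls = target_r * z_seed + np.sqrt(1 - target_r**2) * eps
        latent_hc = rng_bio.standard_normal(n)
        bio[name] = m + s * np.concatenate([latent_ls, latent_hc])
    biomarkers = pd.DataFrame(bio, index=subjects)

    dataset = CohortDataset(
        suv=suv_df,
        group=group,
        covariates=covariates,
        biomarkers=biomarkers,
        region_names=tuple(config.region_names),
        config=config,
    )
    assert len(dataset.suv) == 2 * n  # generator contract
    return dataset


def generate_demographics(config: CohortConfig) -> dict[str, np.ndarray]:
    """Per-variable 2x2 count tables (rows = LS, HC; cols = yes, no)."""
    n = config.n_per_group
    tables = {}
    for name, (yes_ls, yes_hc) in config.demographics_counts.items():
        if yes_ls > n or yes_hc > n:
            raise ValueError(f"count exceeds group size for {name}")
        tables[name] = np.array(
            [[yes_ls, n - yes_ls], [yes_hc, n - yes_hc]], dtype=int
        )
    return tables
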