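"""Atlas parcellation, whole-brain SUV normalization, and regional tests.

The standardized uptake value (SUV) of a region is defined operationally as
the region's mean raw uptake divided by the subject's mean whole-brain
uptake, where "whole brain" is the union of the 90 cerebral atlas regions
(cerebellum excluded).  The resulting values are unitless ratios whose
volume-weighted mean over the atlas is exactly 1 for every subject —
regional comparisons are therefore relative to the subject's own global
metabolism, and globally rescaling the uptake volume changes nothing.

Regional group comparisons use an ordinary-least-squares model per ROI,

    SUV ~ group + age + sex + BMI,

reporting the group coefficient's t and two-sided p, with Benjamini-
Hochberg adjustment across the 90 regions.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .connectivity import fdr_adjust
from .regions import AAL90_REGIONS

__all__ = [
    "AtlasLabelMap",
    "SUVVector",
    "load_atlas",
    "load_uptake_volume",
    "aggregate_label_image",
    "normalize_suv",
    "covariate_adjusted_group_difference",
]


class EmptyROIError(ValueError):
    """An expected atlas label has no voxels in the label volume."""


class DesignError(ValueError):
    """Rank-deficient regression design."""


@dataclass
class AtlasLabelMap:
    """Integer label volume plus label -> region-name table (0 = background)."""

    label_volume: np.ndarray
    label_table: dict[int, str]

    def __post_init__(self):
        vol = np.asarray(self.label_volume)
        if not np.issubdtype(vol.dtype, np.integer):
            raise ValueError("label volume must be integer-valued")
        if 0 in self.label_table:
            raise ValueError("label 0 is reserved for background")
        present = set(np.unique(vol)) - {0}
        unknown = present - set(self.label_table)
        if unknown:
            raise ValueError(f"voxel labels missing from table: {sorted(unknown)}")
        self.label_volume = vol

    @property
    def labels(self) -> list[int]:
        return sorted(self.label_table)

    @property
    def region_names(self) -> list[str]:
        return [self.label_table[k] for k in self.labels]


def load_atlas(label_nifti: str | Path, table_tsv: str | Path) -> AtlasLabelMap:
    """Read an atlas from a NIfTI label image and a (label, region_name) TSV."""
    import nibabel as nib

    vol = np.asanyarray(nib.load(str(label_nifti)).dataobj).astype(np.int64)
    table = pd.read_csv(table_tsv, sep="\t")
    mapping = dict(zip(table["label"].astype(int), table["region_name"]))
    return AtlasLabelMap(vol, mapping)


def load_uptake_volume(path: str | Path) -> np.ndarray:
    import nibabel as nib

    return np.asanyarray(nib.load(str(path)).dataobj).astype(float)


@dataclass
class SUVVector:
    """Whole-brain-normalized regional uptake for one subject."""

    values: np.ndarray
    roi_volumes: np.ndarray
    region_names: tuple[str, ...] = AAL90_REGIONS

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        w = np.asarray(self.roi_volumes, dtype=float)
        if v.shape != w.shape:
            raise ValueError("values and roi_volumes must align")
        if np.any(v < 0):
            raise ValueError("SUV ratios must be >= 0")
        wm = float(np.average(v, weights=w))
        if abs(wm - 1.0) > 1e-9:
            raise ValueError(f"volume-weighted mean must be 1, got {wm}")
        self.values = v
        self.roi_volumes = w


def aggregate_label_image(
    uptake_volume: np.ndarray, atlas: AtlasLabelMap
) -> tuple[np.ndarray, np.ndarray]:
    """Mean uptake and voxel count per atlas region, background excluded."""
    up = np.asarray(uptake_volume, dtype=float)
    lab = atlas.label_volume
    if up.shape != lab.shape:
        raise ValueError(
            f"uptake shape {up.shape} != atlas shape {lab.shape}"
        )
    flat = lab.ravel()
    nmax = max(int(flat.max()), max(atlas.labels)) + 1
    counts = np.bincount(flat, minlength=nmax)
    sums = np.bincount(flat, weights=up.ravel(), minlength=nmax)
    labels = np.asarray(atlas.labels)
    empty = labels[counts[labels] == 0]
    if empty.size:
        raise EmptyROIError(f"atlas labels with no voxels: {empty.tolist()}")
    roi_volumes = counts[labels]
    roi_means = sums[labels] / roi_volumes
    return roi_means, roi_volumes.astype(int)


def normalize_suv(
    roi_means: np.ndarray,
    roi_volumes: np.ndarray,
    region_names: tuple[str, ...] | None = None,
) -> SUVVector:
    """Divide regional uptake by the volume-weighted whole-brain mean."""
    m = np.asarray(roi_means, dtype=float)
    w = np.asarray(roi_volumes, dtype=float)
    if np.any(w <= 0):
        raise ValueError("roi_volumes must be positive")
    whole_brain = float(np.average(m, weights=w))
    if whole_brain <= 0:
        raise ValueError(f"whole-brain mean uptake must be > 0, got {whole_brain}")
    names = region_names or tuple(f"ROI{i+1}" for i in range(m.size))
    if m.size == 90:
        names = region_names or AAL90_REGIONS
    return SUVVector(m / whole_brain, w, tuple(names))


def covariate_adjusted_group_difference(
    suv: pd.DataFrame | np.ndarray,
    group: pd.Series | np.ndarray,
    covariates: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Per-ROI OLS group comparison, adjusted for age, sex and BMI.

    ``group`` may hold any two labels; the *first* label encountered is
    coded 1 so positive t means that group is higher.  ``covariates`` is a
    DataFrame with columns ``age``, ``sex`` (M/F or 0/1) and ``bmi``; pass
    ``None`` for an unadjusted comparison (then the group t equals the
    pooled-variance two-sample t).

    Returns a DataFrame indexed by ROI with columns t, p, q and attribute
    ``result.attrs["covariates"]`` listing the adjusters used.
    """
    if isinstance(suv, pd.DataFrame):
        y = suv.to_numpy(dtype=float)
        rois = list(suv.columns)
    else:
        y = np.asarray(suv, dtype=float)
        rois = [f"ROI{i+1}" for i in range(y.shape[1])]
    g = np.asarray(group)
    labels = pd.unique(g)
    if len(labels) != 2:
        raise ValueError(f"need exactly 2 group labels, got {list(labels)}")
    gi = (g == labels[0]).astype(float)
    if min(gi.sum(), len(gi) - gi.sum()) < 2:
        raise ValueError("need >= 2 subjects per group")

    cols = [np.ones_like(gi), gi]
    used = []
    if covariates is not None:
        cov = covariates.copy()
        if cov["sex"].dtype == object:
            cov["sex"] = (cov["sex"].astype(str).str.upper() == "M").astype(float)
        for name in ("age", "sex", "bmi"):
            cols.append(cov[name].to_numpy(dtype=float))
            used.append(name)
    x = np.column_stack(cols)
    n, k = x.shape
    if np.linalg.matrix_rank(x) < k:
        raise DesignError(
            "design matrix is rank deficient (covariate collinear with "
            "the group indicator?)"
        )

    xtx_inv = np.linalg.inv(x.T @ x)
    beta = xtx_inv @ (x.T @ y)          # k x n_rois
    resid = y - x @ beta
    df = n - k
    sigma2 = (resid**2).sum(axis=0) / df
    se = np.sqrt(sigma2 * xtx_inv[1, 1])
    with np.errstate(divide="ignore", invalid="ignore"):
        t = beta[1] / se
    p = 2.0 * stats.t.sf(np.abs(t), df)
    out = pd.DataFrame({"t": t, "p": p, "q": fdr_adjust(p)}, index=rois)
    out.index.name = "region"
    out.attrs["covariates"] = used
    out.attrs["group_coded_1"] = labels[0]
    return out
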