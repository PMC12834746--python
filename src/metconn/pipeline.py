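"""End-to-end orchestration of the metabolic-connectomics analysis.

One configuration object drives the full chain: cohort generation (or
ingestion of a precomputed SUV table / NIfTI volumes) -> whole-brain SUV
normalization -> covariate-adjusted regional tests -> seed connectivity and
edge tests -> sparsity-swept network metrics -> permutation inference ->
clinical statistics.  Every numeric output is reproducible bit-for-bit from
the configuration plus the root seed, and all tables are written as TSV
with a JSON summary and a run manifest.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .clinical import demographics_table, suv_biomarker_correlation
from .connectivity import correlation_matrix, seed_edge_tests
from .graphs import auc_over_sparsity
from .inference import GLOBAL_METRICS, metric_auc_curves, permutation_test_multi
from .regions import DEFAULT_SEED_REGION
from .suv import covariate_adjusted_group_difference
from .synthetic import CohortConfig, CohortDataset, generate_cohort, generate_demographics

log = logging.getLogger("metconn")

__all__ = ["PipelineConfig", "ReportBundle", "run_pipeline", "load_roi_table"]


@dataclass
class PipelineConfig:
    """Settings for one full analysis run."""

    mode: str = "synthetic"               # synthetic | roi_table | nifti
    cohort: CohortConfig | None = None    # synthetic mode
    suv_path: str | None = None           # roi_table mode
    manifest_path: str | None = None      # roi_table + nifti modes
    atlas_label_path: str | None = None   # nifti mode
    atlas_table_path: str | None = None
    seed_region: str = DEFAULT_SEED_REGION
    sparsity_min: float = 0.10
    sparsity_max: float = 0.50
    sparsity_step: float = 0.01
    metrics: tuple[str, ...] = GLOBAL_METRICS
    n_perm: int = 5000
    n_null: int = 100
    alpha: float = 0.05
    rng_seed: int = 0
    outdir: str = "results/run"

    def __post_init__(self):
        if not (0.0 < self.sparsity_min < self.sparsity_max < 1.0):
            raise ValueError("need 0 < sparsity_min < sparsity_max < 1")
        if self.sparsity_step <= 0:
            raise ValueError("sparsity_step must be > 0")
        if self.n_perm < 1:
            raise ValueError("n_perm must be >= 1")
        if self.mode not in ("synthetic", "roi_table", "nifti"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.mode == "roi_table" and not (self.suv_path and self.manifest_path):
            raise ValueError("roi_table mode needs suv_path and manifest_path")
        if self.mode == "nifti" and not (
            self.manifest_path and self.atlas_label_path and self.atlas_table_path
        ):
            raise ValueError(
                "nifti mode needs manifest_path (with an uptake_path column), "
                "atlas_label_path and atlas_table_path"
            )

    @property
    def sparsities(self) -> np.ndarray:
        grid = np.arange(self.sparsity_min, self.sparsity_max + 1e-9,
                         self.sparsity_step)
        return np.round(grid, 10)


@dataclass
class ReportBundle:
    summary: dict
    regional_tests: pd.DataFrame
    edge_tests: pd.DataFrame
    global_curves: pd.DataFrame
    permutation_results: pd.DataFrame
    demographics: pd.DataFrame
    biomarker_correlations: pd.DataFrame
    outdir: Path


def load_roi_table(suv_path, manifest_path) -> CohortDataset:
    """Ingest a precomputed subjects x ROIs SUV TSV plus subject manifest."""
    suv = pd.read_csv(suv_path, sep="\t", index_col="subject")
    man = pd.read_csv(manifest_path, sep="\t", index_col="subject")
    missing = [c for c in ("group", "age", "sex", "bmi") if c not in man.columns]
    if missing:
        raise ValueError(f"manifest missing columns: {missing}")
    if not suv.index.equals(man.index):
        raise ValueError("suv and manifest subject IDs disagree")
    bio_cols = [c for c in ("AST", "PT") if c in man.columns]
    n = len(suv) // 2
    cfg = CohortConfig(n_per_group=max(n, 3), n_rois=suv.shape[1],
                       region_names=tuple(suv.columns))
    return CohortDataset(
        suv=suv,
        group=man["group"],
        covariates=man[["age", "sex", "bmi"]],
        biomarkers=man[bio_cols] if bio_cols else pd.DataFrame(index=man.index),
        region_names=tuple(suv.columns),
        config=cfg,
    )


def load_nifti_cohort(
    manifest_path, atlas_label_path, atlas_table_path
) -> CohortDataset:
    """Parcellate per-subject uptake volumes into an SUV table.

    The manifest TSV needs subject, group, age, sex, bmi and an
    ``uptake_path`` column pointing at each subject's NIfTI volume
    (relative paths resolve against the manifest's directory).
    """
    from .suv import aggregate_label_image, load_atlas, load_uptake_volume, normalize_suv

    man = pd.read_csv(manifest_path, sep="\t", index_col="subject")
    if "uptake_path" not in man.columns:
        raise ValueError("nifti manifest needs an uptake_path column")
    atlas = load_atlas(atlas_label_path, atlas_table_path)
    base = Path(manifest_path).parent
    rows = []
    for subject, rel in man["uptake_path"].items():
        path = Path(rel)
        vol = load_uptake_volume(path if path.is_absolute() else base / path)
        means, vols = aggregate_label_image(vol, atlas)
        rows.append(normalize_suv(means, vols, tuple(atlas.region_names)).values)
    suv = pd.DataFrame(rows, index=man.index, columns=atlas.region_names)
    bio_cols = [c for c in ("AST", "PT") if c in man.columns]
    cfg = CohortConfig(n_per_group=max(len(suv) // 2, 3), n_rois=suv.shape[1],
                       region_names=tuple(suv.columns))
    return CohortDataset(
        suv=suv,
        group=man["group"],
        covariates=man[["age", "sex", "bmi"]],
        biomarkers=man[bio_cols] if bio_cols else pd.DataFrame(index=man.index),
        region_names=tuple(suv.columns),
        config=cfg,
    )


def run_pipeline(config: PipelineConfig) -> ReportBundle:
    """Execute every analysis stage and write all outputs under ``outdir``."""
    t0 = time.time()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    sparsities = config.sparsities

    handler = logging.FileHandler(outdir / "run.log", mode="w")
    handler.setFormatter(
        logging.Formatter("%(asctime)s %(levelname)s %(message)s")
    )
    log.addHandler(handler)
    log.setLevel(logging.INFO)
    stage_t = time.time()

    def stage_done(name: str) -> None:
        nonlocal stage_t
        log.info("stage %-22s %.2fs", name, time.time() - stage_t)
        stage_t = time.time()

    logging.captureWarnings(True)
    logging.getLogger("py.warnings").addHandler(handler)

    # --- cohort ---------------------------------------------------------
    if config.mode == "synthetic":
        cohort_cfg = config.cohort or CohortConfig(rng_seed=config.rng_seed)
        dataset = generate_cohort(cohort_cfg)
        dataset.write(outdir)
    elif config.mode == "roi_table":
        dataset = load_roi_table(config.suv_path, config.manifest_path)
    else:
        dataset = load_nifti_cohort(
            config.manifest_path, config.atlas_label_path,
            config.atlas_table_path,
        )
    groups = list(pd.unique(dataset.group))
    g1, g2 = groups
    suv1 = dataset.group_suv(g1)
    suv2 = dataset.group_suv(g2)
    log.info("cohort: %d + %d subjects, %d regions", len(suv1), len(suv2),
             dataset.suv.shape[1])
    stage_done("cohort")

    # --- regional covariate-adjusted comparison -------------------------
    regional = covariate_adjusted_group_difference(
        dataset.suv, dataset.group, dataset.covariates
    )
    regional.to_csv(outdir / "regional_tests.tsv", sep="\t")
    stage_done("regional_tests")

    # --- connectivity + seed edge tests ---------------------------------
    c1 = correlation_matrix(suv1, group=g1)
    c2 = correlation_matrix(suv2, group=g2)
    c1.to_frame().to_csv(outdir / f"connectivity_{g1}.tsv", sep="\t")
    c2.to_frame().to_csv(outdir / f"connectivity_{g2}.tsv", sep="\t")
    edge_tests = seed_edge_tests(c1, c2, config.seed_region)
    edge_tests.to_csv(outdir / "edge_tests.tsv", sep="\t", index=False)
    stage_done("connectivity")

    # --- network sweep ---------------------------------------------------
    rng = np.random.default_rng(config.rng_seed)
    curves_rows = []
    for label, suv_g in ((g1, suv1), (g2, suv2)):
        curves, aucs = metric_auc_curves(
            suv_g.to_numpy(), config.metrics, sparsities,
            n_null=config.n_null, rng=rng,
        )
        for m in config.metrics:
            for s, v in zip(sparsities, curves[m]):
                curves_rows.append(
                    {"group": label, "metric": m, "sparsity": s, "value": v}
                )
    global_curves = pd.DataFrame(curves_rows)
    global_curves.to_csv(outdir / "global_metrics.tsv", sep="\t", index=False)
    stage_done("network_sweep")

    # --- permutation inference ------------------------------------------
    perm = permutation_test_multi(
        dataset.suv, dataset.group, config.metrics,
        n_perm=config.n_perm, rng_seed=config.rng_seed,
        sparsities=sparsities, n_null=config.n_null,
    )
    perm_df = pd.DataFrame(
        [
            {
                "metric": m,
                "observed_diff": res.observed,
                "p": res.p,
                "n_perm": res.n_perm,
                "rng_seed": res.rng_seed,
            }
            for m, res in perm.items()
        ]
    )
    perm_df.to_csv(outdir / "permutation_results.tsv", sep="\t", index=False)
    stage_done("permutation_inference")

    # --- clinical statistics --------------------------------------------
    if config.mode == "synthetic":
        demo = demographics_table(generate_demographics(dataset.config))
    else:
        demo = pd.DataFrame()
    if not demo.empty:
        demo.to_csv(outdir / "demographics_tests.tsv", sep="\t")

    bio_rows = []
    seed_vals = suv1[config.seed_region].to_numpy()
    for bm in dataset.biomarkers.columns:
        rep = suv_biomarker_correlation(
            seed_vals, dataset.biomarkers.loc[dataset.group == g1, bm],
            pair=(config.seed_region, bm),
        )
        bio_rows.append({"biomarker": bm, "r": rep.r, "p": rep.p, "n": rep.n})
    bio_df = pd.DataFrame(bio_rows)
    if not bio_df.empty:
        bio_df.to_csv(outdir / "biomarker_correlations.tsv", sep="\t",
                      index=False)

    # --- summary + manifest ---------------------------------------------
    top_region = regional["q"].idxmin()
    sig_edges = edge_tests.loc[edge_tests["q"] < config.alpha, "region"]
    summary = {
        "groups": groups,
        "seed_region": config.seed_region,
        "top_regional_difference": {
            "region": top_region,
            "t": float(regional.loc[top_region, "t"]),
            "q": float(regional.loc[top_region, "q"]),
        },
        "significant_seed_edges": sig_edges.tolist(),
        "metric_tests": {
            m: {"observed_diff": res.observed, "p": res.p, "n_perm": res.n_perm}
            for m, res in perm.items()
        },
        "biomarker_correlations": bio_rows,
        "alpha": config.alpha,
    }
    with open(outdir / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2)

    cfg_echo = dataclasses.asdict(config)
    if config.cohort is not None:
        cfg_echo["cohort"] = config.cohort.to_dict()
    manifest = {
        "config": cfg_echo,
        "rng_seed": config.rng_seed,
        "n_perm": config.n_perm,
        "metconn_version": __version__,
        "numpy_version": np.__version__,
        "elapsed_s": round(time.time() - t0, 2),
        "timestamp": time.strftime("%Y-%m-%dT%H:%M:%S"),
    }
    with open(outdir / "run_manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
    stage_done("clinical_and_reports")
    logging.captureWarnings(False)
    logging.getLogger("py.warnings").removeHandler(handler)
    log.removeHandler(handler)
    handler.close()

    return ReportBundle(
        summary=summary,
        regional_tests=regional,
        edge_tests=edge_tests,
        global_curves=global_curves,
        permutation_results=perm_df,
        demographics=demo,
        biomarker_correlations=bio_df,
        outdir=outdir,
    )
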