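#!/usr/bin/env python
"""Demographic tests and SUV-biomarker correlations.

Chi-square tests on the study's 2x2 demographic counts (male, hypertension,
hyperglycemia, hyperlipidemia, smoking, drinking), the summary age t-test,
and Pearson correlations between patient seed-region SUV and AST / PT.
Writes results/demographics_tests.tsv and results/biomarker_correlations.tsv.
"""

from pathlib import Path

import pandas as pd

from metconn.clinical import (
    demographics_table,
    suv_biomarker_correlation,
    two_sample_t_from_summary,
)
from metconn.pipeline import load_roi_table
from metconn.regions import DEFAULT_SEED_REGION
from metconn.synthetic import CohortConfig, generate_demographics

ROOT = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    demo = demographics_table(generate_demographics(CohortConfig()))
    demo.to_csv(ROOT / "demographics_tests.tsv", sep="\t")
    print("demographic chi-square tests:")
    print(demo.round(3).to_string())

    t, p = two_sample_t_from_summary(53.89, 1.198, 70, 50.34, 0.737, 70)
    print(f"\nage (summary t-test): t={t:.3f}, p={p:.4f}")

    cohort = ROOT / "cohort"
    if not (cohort / "suv.tsv").exists():
        raise SystemExit("run analysis/01_simulate_cohort.py first")
    ds = load_roi_table(cohort / "suv.tsv", cohort / "manifest.tsv")
    ls = ds.group == "LS"
    seed_suv = ds.suv.loc[ls, DEFAULT_SEED_REGION]
    rows = []
    for bm in ("AST", "PT"):
        rep = suv_biomarker_correlation(
            seed_suv, ds.biomarkers.loc[ls, bm],
            pair=(DEFAULT_SEED_REGION, bm),
        )
        rows.append({"biomarker": bm, "r": rep.r, "p": rep.p, "n": rep.n})
    bio = pd.DataFrame(rows)
    bio.to_csv(ROOT / "biomarker_correlations.tsv", sep="\t", index=False)
    print("\nseed-SUV vs biomarkers (LS group):")
    print(bio.round(3).to_string(index=False))


if __name__ == "__main__":
    main()
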