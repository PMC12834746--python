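# metconn

Group-level **met**abolic **conn**ectomics of atlas-parcellated FDG-PET:
whole-brain-normalized SUV extraction, cross-subject Pearson metabolic
connectivity, sparsity-swept graph-theoretic network characterization with
small-world null normalization, and permutation/FDR inference — exercised
end to end on a synthetic cohort generator, so the whole chain is testable
without patient data.

## The analysis

For subject *s* and brain region *k* (90 cerebral AAL regions, cerebellum
excluded),

    SUV_sk = (mean uptake in region k) / (subject's whole-brain mean uptake)

making regional values unitless ratios with volume-weighted mean 1.
*Metabolic connectivity* between regions *i* and *j* in a group is the
Pearson correlation r_ij of SUV_i and SUV_j **across that group's
subjects** — one 90×90 matrix per group.  Each matrix is binarized by
keeping the top `round(s · 4005)` edges at sparsity *s*, swept over
0.10–0.50 (step 0.01).  Per graph: clustering coefficient Cp,
characteristic path length Lp, global/local efficiency Eglob/Eloc, and the
small-world indices γ = Cp/⟨Cp_rand⟩, λ = Lp/⟨Lp_rand⟩, σ = γ/λ against
degree-preserving rewired nulls, plus nodal degree, betweenness and
efficiency.  Group differences: Fisher r-to-z tests with BH-FDR on the
89 seed edges of a seed region (right postcentral gyrus); permutation
tests (relabelling group membership, statistic = AUC of the metric over
the sparsity sweep) for network metrics; a per-ROI OLS
`SUV ~ group + age + sex + BMI` for regional uptake; χ²/t/Mann–Whitney for
demographics and Pearson correlations between seed SUV and blood
biomarkers (AST, PT).

Intended users: imaging/network-neuroscience researchers who want a
reproducible, scriptable version of this analysis for parcellated PET
tables, and methodologists who want its statistical behavior on known
ground truth.

## Worked example

```bash
python analysis/01_simulate_cohort.py
python analysis/02_regional_metabolism.py
python analysis/03_seed_connectivity.py
```

prints (seed 0):

```
cohort written to .../results/cohort
  140 subjects, 90 regions
  seed-ROI SUV mean LS=1.0611 HC=0.9899 (planted shift 0.05)
regional tests written to .../results/regional_tests.tsv
  top region: Postcentral_R (t=3.69, q=0.0291); 1 regions at q<0.05
edge tests written to .../results/edge_tests.tsv
  seed: Postcentral_R; 5 edges at q<0.05:
    Supp_Motor_Area_L    r_LS=+0.126 r_HC=+0.604 z=-3.32 q=0.0204
    Hippocampus_L        r_LS=+0.118 r_HC=+0.611 z=-3.42 q=0.0183
    Amygdala_L           r_LS=+0.087 r_HC=+0.687 z=-4.37 q=0.0011
    SupraMarginal_L      r_LS=+0.166 r_HC=+0.668 z=-3.70 q=0.0094
    Caudate_R            r_LS=+0.211 r_HC=+0.637 z=-3.11 q=0.0329
```

The synthetic patient group ("LS") carries a +0.5 SD uptake shift in the
right postcentral gyrus and four seed edges decorrelated from 0.6 to 0.2;
the pipeline recovers the shifted region as the top covariate-adjusted hit
and flags all four planted edges (plus, in this draw, one false positive)
at q < 0.05.  `analysis/04_network_topology.py` and
`analysis/05_network_inference.py` continue with the topology sweep and
permutation tests; `analysis/06_clinical_stats.py` reproduces the
demographic χ² statistics (e.g. smoking 10/70 vs 1/70 → χ² = 7.992) and
the biomarker correlations.

The same stages are available as a CLI (`metconn simulate|suv|connectivity|
network|infer|stats|run-all`) and as one call,
`metconn.run_pipeline(PipelineConfig(...))`, which writes all TSV outputs,
a JSON summary, and a run manifest sufficient to reproduce the run
bit-for-bit.

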