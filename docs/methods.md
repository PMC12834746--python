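# Methods

This package reimplements, as tested library code, a group-level
metabolic-connectomics analysis of atlas-parcellated FDG-PET: whole-brain
SUV normalization, cross-subject Pearson connectivity, sparsity-swept
binary-graph topology with small-world null normalization, and
permutation/FDR inference.  Because no raw patient volumes accompany the
study design this pipeline targets, a synthetic cohort generator emulates
the statistical structure the analysis assumes, and every downstream stage
is validated against it.

## SUV normalization and regional comparison

For each subject, regional uptake is the arithmetic mean of the PET volume
over the voxels of each of the 90 cerebral AAL regions (cerebellum
excluded; background label 0 ignored).  The standardized uptake value of a
region is its mean uptake divided by the subject's whole-brain mean, where
the whole brain is the volume-weighted union of the 90 atlas regions.  Two
consequences are enforced as invariants: the volume-weighted mean of every
SUV vector is exactly 1 (to 1e-9), and globally rescaling the uptake volume
leaves the SUV vector unchanged.  Whether the cerebellum should contribute
to the normalizing mean is not fully determined by the source analysis; we
normalize over the 90 network regions only, and the atlas table is
configurable if a user wants otherwise.

Regional group differences are tested per ROI with ordinary least squares,

    SUV ~ group + age + sex + BMI,

reporting the group coefficient's t, two-sided p, and Benjamini–Hochberg q
across the 90 regions.  This ROI-level GLM deliberately replaces voxel-wise
SPM cluster inference: the artifact operates on the parcellation
throughout, which matches every downstream analysis.  Sex enters as a 0/1
indicator; no interactions.  The fit is a vectorized closed-form OLS (all
regions share one design matrix); it is cross-checked against statsmodels
per-ROI fits to 1e-8 in the test suite, and with `covariates=None` the
group t reduces exactly to the pooled two-sample t.  With noise covariates
in the design the equality to the two-sample t is only approximate — the
exact-equivalence oracle therefore runs on the covariate-free reduced
model.

## Metabolic connectivity and edge tests

Connectivity is a group-level construct: the Pearson correlation, across
the subjects of one group, between the normalized SUVs of two regions.
Zero-variance regions (possible in degenerate synthetic inputs) yield
correlation 0 with a logged warning rather than NaN, keeping the pipeline
total.

The source analysis states only that edge-wise p-values were FDR-corrected;
it does not name the edge test.  We adopt the Fisher r-to-z two-sample
statistic

    z = (atanh r1 − atanh r2) / sqrt(1/(n1−3) + 1/(n2−3))

as the deterministic default, with a subject-level permutation of the same
atanh-difference statistic available as a cross-check
(`permutation_edge_pvalue`).  The two do not coincide per dataset: the
permutation test conditions on the pooled sample while the Fisher p is
asymptotic and unconditional.  On equal-correlation data (r = 0.5,
n = 70/group) the measured per-dataset |Δp| has mean ≈ 0.02 and can reach
≈ 0.1, so the acceptance check asserts agreement *on average* (mean
|Δp| ≤ 0.05 over eight datasets) rather than within Monte-Carlo error.
The FDR family defaults to the 89 seed edges of the seed-region analysis,
not all 4,005 edges; both the family and the test are configurable.

## Binary networks and topology

A group correlation matrix is binarized by keeping the
`K = round_half_up(s · 4005)` most strongly correlated pairs at each
sparsity `s`, swept over 0.10–0.50 in steps of 0.01.  Signed correlation is
ranked (metabolic covariance networks are conventionally built on positive
coupling; a flag switches to |r|), ties break lexicographically by (i, j),
and rounding is half-up — both chosen for cross-platform determinism.

Global metrics: clustering coefficient Cp (nodes of degree < 2 contribute
0), characteristic path length Lp (mean over *connected* ordered pairs — the
common toolbox convention when low-sparsity graphs fragment; the harmonic
alternative is available through Eglob), global efficiency Eglob (mean of
1/d with 1/∞ = 0), and local efficiency Eloc (Eglob of each node's
neighbor-induced subgraph).  Nodal metrics: degree, unnormalized Brandes
betweenness (each pair contributes 1, split over shortest paths), and nodal
efficiency (mean inverse distance to all other nodes).

Small-world indices normalize against a null ensemble of Maslov–Sneppen
degree-preserving double-edge swaps (the source analysis does not specify
its null construction): gamma = Cp/⟨Cp_null⟩, lambda = Lp/⟨Lp_null⟩,
sigma = gamma/lambda, with defaults of 100 nulls per sparsity and
10 × edge-count swaps per null.  A complete graph admits no legal swap and
returns itself, making gamma = lambda = sigma = 1 exactly; an
Erdős–Rényi graph is statistically its own null (gamma, lambda ≈ 1), and
both properties are asserted in the tests.

All metric kernels are vectorized numpy (level-synchronous BFS via stacked
float32 matrix products, triangle counts via einsum, neighbor subgraphs
bucketed by size) because permutation inference re-evaluates on the order
of 10^5–10^6 graphs; naive enumeration and networkx implementations serve
as independent oracles in the test suite (agreement to 1e-12).

## Permutation inference

Each group yields a single network per sparsity, so group comparisons use
permutation of group membership: for every relabelling (group sizes
preserved), both group networks are rebuilt from scratch and the metric
recomputed.  The test statistic collapses the sweep to the trapezoidal
area under the metric-versus-sparsity curve (AUC); the source analysis
reports one p per metric without stating how the sweep is collapsed, and
AUC is the standard choice.  Empirical two-tailed p-values use the +1
convention, p = (1 + #{|null| ≥ |obs|})/(1 + n_perm), so p is never 0.
The analysis default is 5,000 relabellings; tests and drivers use 100–500
with the corresponding Monte-Carlo tolerance.  Nodal tests share one
relabelling stream across nodes, preserving cross-node dependence for the
BH adjustment.

A caution the tests encode: because thresholding fixes the edge count, a
group-mean offset alone does not make a network statistic extreme — mixed
relabellings of two well-separated groups produce tie-dominated, effectively
random graphs whose metric differences fluctuate broadly.  The minimal-p
regression test therefore plants a *structural* difference (ring versus
two-block coupling) and verifies the observed statistic exceeds every
relabelled one.

## Synthetic cohorts

The generator draws two groups of `n_per_group` subjects × 90 regions from
group-specific multivariate Gaussians.

* **Base coupling.** Correlation `0.6^(1 + |i−j|/10) + 0.2` (unit
  diagonal), repaired to the nearest PSD correlation — a smooth,
  distance-graded stand-in for the strong positive inter-regional coupling
  of regional glucose metabolism.  Any user matrix is accepted.
* **Marginals.** Mean 1 (SUV ratios), SD 0.1 per region.  The source
  analysis publishes no SUV variance or effect sizes, so the SD is a
  placeholder chosen to make "0.5 SD" shifts concrete; planted effects are
  specified in SD units and do not depend on it.
* **Planted effects.** Patients ("LS") get a +0.5 SD mean shift at the
  right postcentral gyrus; the four seed edges (right caudate, left
  amygdala, left hippocampus, left supramarginal gyrus) are planted at
  r = 0.6 in controls and r = 0.2 in patients.  Planting uses alternating
  projections (re-impose entries ↔ PSD projection with eigenvalue clipping
  and rescaling): a single projection drags conflicting targets off their
  values, while the alternating scheme honors them to 1e-8 and lets
  non-targeted entries absorb the (≤ ~0.1) adjustment.
* **Biomarkers.** AST and prothrombin time couple to patient seed-region
  SUV through a Gaussian copula at target correlations −0.277 and +0.256,
  with plausible marginals (AST 25 ± 8 U/L, PT 12.5 ± 1.0 s); controls draw
  independently.
* **Demographics.** 2×2 count tables reproduce the study table exactly
  (e.g. smoking 10/70 vs 1/70); age, sex and BMI covariates are drawn to
  roughly match it (ages N(54, 8) vs N(50, 6), sex Bernoulli 0.74/0.60) —
  conveniences for exercising the GLM, not biological claims.
* **Reproducibility.** One root seed; SUV, covariate and biomarker
  substreams are spawned independently, so adding a component never
  perturbs the others.

What the generator does *not* emulate: voxel-level PET noise, scanner and
partial-volume effects, spatial smoothing, covariate–SUV coupling, or any
real anatomical covariance beyond the smooth base structure.  Passing
recovery tests therefore demonstrate that the *pipeline* detects the
planted statistical structure at the stated sample sizes — not that the
original biological findings would replicate.

## Recovery power calibration

At the study conditions (0.5 SD seed shift, edge contrast 0.6 → 0.2,
70/group, BH over 89 seed edges) each planted edge carries a Fisher z of
only ≈ 2.8, while BH significance at rank 3–4 of 89 needs z ≳ 3.1, so
full recovery is not expected.  A 200-replicate power calibration of this
generator measured: seed region attains the smallest regional q in 52.5%
of cohorts; ≥ 3 of 4 planted edges reach q < 0.05 in 26%.  The regression
tests freeze conservative bounds about three binomial standard deviations
below these rates for a 50-replicate run (top-region rate ≥ 0.30,
≥ 3-of-4-edge rate ≥ 0.10).  These bounds guard against power regressions
in the pipeline; they are properties of this generator configuration, not
universal detection standards.

## Numerical and design notes

* BH adjustment is statsmodels' `fdr_bh`; chi-square (uncorrected Pearson,
  1 df — the printed demographic statistics match the uncorrected form
  exactly, a flag enables Yates), Mann–Whitney (midrank ties; z from the
  tie-corrected normal approximation without continuity correction; p
  exact for small tie-free samples) and Pearson correlations are scipy.
* The study table labels age "mean ± SD", but an SD of ~1.2 years at
  n = 70 is implausible and the printed t is consistent with SE; the
  summary t-test reads those values as standard errors (the operation
  accepts either interpretation, since it takes SEs explicitly).
* Problem sizes in tests and drivers (200 permutations, 100 replicates,
  10-ROI calibration cohorts, 20–50 nulls) are scaled-down study
  conditions chosen so the whole suite runs in minutes; each scaled run
  states its Monte-Carlo tolerance.
* Degenerate inputs have defined behavior throughout: empty graphs return
  zero metrics with a warning, infeasible rewiring returns best-effort
  with a warning, zero-variance columns correlate 0, sparsities keeping
  zero edges raise.

## Known limitations

* Real-data ingestion expects preprocessed, atlas-aligned NIfTI volumes;
  no spatial normalization, smoothing, motion/attenuation or
  partial-volume correction is provided.
* Permutation inference at full scale (5,000 relabellings × 41 sparsities
  × 90 nodes) is minutes-to-hours of compute; drivers default to reduced
  counts and say so.
* The Fisher edge test and its permutation cross-check are asymptotically,
  not per-dataset, interchangeable (see above).
* No weighted-graph metrics, modularity, rich-club, partial correlation,
  or single-subject connectivity.
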