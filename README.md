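# gaitdi

Toolkit for deriving and applying a **population-specific Gait Deviation
Index** from three-dimensional gait-analysis kinematics.

A widely used summary of overall gait pathology reduces a stride to a single
dimensionless score by (1) representing the stride as a 459-component *gait
vector* — nine joint-angle curves (pelvis and hip in three planes, knee
flexion-extension, ankle dorsi/plantarflexion, foot progression angle)
sampled at 2% of the gait cycle — (2) projecting it onto a reduced-order
orthonormal basis of *gait features* obtained by singular value
decomposition of a training cohort, and (3) scaling its distance from a
control mean so that 100 is the control average and every 10 points below
100 is one control standard deviation of (log) deviation. The original
basis of this kind was derived from pediatric cerebral-palsy data; applying
it to other populations (adult spinal cord injury, stroke, Parkinson's …)
can misrepresent impairment. `gaitdi` implements the full derivation so
that any lab with a kinematic dataset can build, validate and apply an
index specific to its own population.

It is intended for clinical-biomechanics researchers and gait-lab engineers
who have per-stride joint-angle curves (exported from their motion-capture
pipeline as a long-format table) and want a defensible, reproducible index.

## The math in brief

With G the 459 × N stride matrix and G = U S Vᵀ its SVD, the first m left
singular vectors F_m are the gait features. Feature-count selection finds
the smallest m in a scan grid (default 10..30) with

* VAF(m) = 100 · Σ_{i≤m} s_i² / Σ s_i² ≥ 98%, and
* mean reconstruction fidelity 100 · ‖F_m F_mᵀ g‖ / ‖g‖ ≥ 98% over the
  training strides,

with the percentage of strides at fidelity ≥ 95% reported alongside, and a
Monte Carlo cross-validation (10 iterations, 5% random stride holdout)
checking that the minimal m is stable to within one feature. Scoring a
stride g against a control reference (c̄, mean/SD of control log-distances)
computes d = ‖F_mᵀ g − c̄‖ and

    index = 100 − 10 · (ln d − mean ln d_ctrl) / sd ln d_ctrl.

Validation statistics against an ordinal clinical scale (normality
screening, stratified histograms, pairwise one-way ANOVA, Kendall's tau-b,
Pearson/OLS between two indexes) are included. Because no clinical dataset
ships with the package, a synthetic-gait module generates control and
severity-graded cohorts with known structure — including cohorts of exactly
known intrinsic rank — so every stage is testable end to end. See
`docs/methods.md` for conventions, defaults and limitations.

## Worked example

```python
from gaitdi import (
    CohortMatrix, GeneratorSpec, GroupSpec, build_cohort_matrix, decompose,
    fit_control_reference, generate_cohort, make_population_template,
    monte_carlo_stability, score_cohort, select_feature_count, summarize_scores,
    kendall_tau_b,
)
from gaitdi.stats import ordinal_pairs

# a control group plus three impairment bands with ordinal labels
template = make_population_template(seed=42)
spec = GeneratorSpec(
    groups=(GroupSpec("control", 150, 0.0), GroupSpec("19", 60, 0.2),
            GroupSpec("16", 60, 0.5), GroupSpec("13", 60, 0.8)),
    seed=7,
)
cohort = build_cohort_matrix(generate_cohort(template, spec))

selection = select_feature_count(cohort)          # grid search m = 10..30
report = monte_carlo_stability(cohort, seed=0)    # 10 iterations, 5% holdout
print("selected m:", selection.m_star)
print("minimal m (VAF):      %.1f +/- %.1f" % report.m_vaf_mean_sd)
print("minimal m (fidelity): %.1f +/- %.1f" % report.m_fidelity_mean_sd)

basis = decompose(cohort)
mask = (cohort.metadata["group_label"] == "control").to_numpy()
controls = CohortMatrix(cohort.matrix[:, mask], cohort.metadata.loc[mask])
ref = fit_control_reference(controls, basis, m=selection.m_star)
scores = score_cohort(cohort, basis, ref)
print(summarize_scores(scores).to_string(index=False))
tau, p = kendall_tau_b(*ordinal_pairs(scores))
print(f"tau-b = {tau:.3f} (p = {p:.2e})")
```

prints

```
selected m: 10
minimal m (VAF):      10.0 +/- 0.0
minimal m (fidelity): 10.0 +/- 0.0
group_label  n_strides  mean_index  sd_index  min_index  max_index
    control        150  100.000000 10.000000  80.256473 140.574505
         19         60   82.296067  6.793015  65.747564 100.317262
         16         60   54.575408  7.344920  35.197548  66.692481
         13         60   37.819321  6.265303  18.712130  51.106397
tau-b = 0.790 (p = 1.09e-42)
```

Reading it: the smooth synthetic cohort needs only 10 features (the scan
floor) for 98% VAF and 98% mean fidelity, perfectly stably across Monte
Carlo holdouts (± 0.0). The control group scores exactly 100 ± 10 — the
self-calibration identity of the scaling — and group means fall
monotonically as severity rises, with the index strongly concordant with
the ordinal labels (tau-b 0.79). Real cohorts are rougher: expect a larger
m, sub-100% fidelity percentages, and weaker concordance.

The same pipeline is scriptable from a shell:

```
gaitdi simulate --group control:150:0 --group 16:60:0.5 --seed 7 --out strides.csv
gaitdi derive-basis --input strides.csv --out-dir basis/
gaitdi score --input strides.csv --basis basis/basis.json --fit-reference --out-dir scores/
gaitdi compare --scores scores/scores.csv --out-dir report/ --plot
```

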