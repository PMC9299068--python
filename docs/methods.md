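# Methods

## The gait vector and the feature basis

A stride from three-dimensional gait analysis is represented by nine
joint-angle curves — pelvic tilt, obliquity and rotation; hip flexion,
abduction and rotation; knee flexion-extension; ankle dorsi/plantarflexion;
and the foot progression angle — each time-normalized to one gait cycle and
sampled at 2% increments (51 points, both endpoints included). Concatenated
in a fixed canonical order these give the gait vector g ∈ R^459. The
concatenation order is a package convention: any fixed order is
mathematically equivalent, so we pin one (pelvis, hip, knee, ankle, foot
progression; see `gaitdi.kinematics.CANONICAL_ANGLES`) and embed it in every
basis file so vectors and bases can never be silently misaligned.
Resampling onto the grid is linear — the least-assumption choice for
already-smooth time-normalized curves — and is recorded in basis provenance.
Left and right strides are pooled as independent columns; a subject-mean
aggregation of scores is available downstream for analyses that require one
value per subject.

A training cohort is the matrix G (459 × N, one column per stride). Its
singular value decomposition G = U S Vᵀ yields the *gait features*: the left
singular vectors, an orthonormal basis of curve space ordered by decreasing
singular value. No mean-centering is applied before the SVD — the features
must reconstruct raw angle curves directly, and the (always-false) centering
flag is stored in the basis file. Singular-vector signs are fixed by making
each feature's largest-magnitude component non-negative, so bases are
bit-reproducible across runs and linear-algebra backends.

## Choosing the feature count m

Two metrics drive the reduction:

* **VAF(m)** = 100 · Σ_{i≤m} s_i² / Σ_i s_i² — variance accounted for by the
  first m features, a function of the singular values alone.
* **Fidelity** of a stride g under the m-th order reconstruction
  ĝ = F_m F_mᵀ g: 100 · ‖ĝ‖ / ‖g‖, the fraction of the stride's norm its
  projection retains. (For an orthogonal projection this is the cosine of
  the angle between g and the feature subspace, and it is non-decreasing in
  m.) Strides with ‖g‖ < 1e−9 are a domain error rather than a 0/0.

`select_feature_count` scans m over a grid (default 10..30) and returns the
smallest m with VAF ≥ 98% **and** mean fidelity ≥ 98% on the training set;
the percentage of strides reconstructed with fidelity ≥ 95% is traced
alongside as a descriptive statistic but is not a gate. When no scanned m
satisfies both floors the result is an explicit "not reached" value carrying
the full trace, not an error.

Stability of the choice is assessed by Monte Carlo cross-validation: each of
10 iterations removes ⌊0.05 · N⌋ strides (at least one; the fraction is
specified without a rounding rule, so we take the floor) uniformly at random
without replacement, re-derives the basis, and records the minimal m meeting
each criterion separately. A spread of at most one feature across iterations
is declared stable. The high-fidelity percentage at the joint minimal m is
computed on the retained (training) strides of each iteration; computing it
on the held-out strides would be the natural alternative, and the choice is
deliberate and documented here because the two are equally defensible.

All randomness flows through an explicitly passed seeded
`numpy.random.Generator`; no global state is touched.

## The deviation index

Scoring needs a control reference fitted once per (basis, m): the mean
control feature vector c̄ = mean(F_mᵀ g_control), and the sample mean and SD
(n−1 denominator) of ln d_i, where d_i = ‖F_mᵀ g_i − c̄‖ are the control
strides' own distances. A new stride with distance d scores

    index = 100 − 10 · (ln d − mean ln d_ctrl) / sd ln d_ctrl.

The log transform before z-scaling follows the established construction of
this family of indexes (distances are strictly positive and right-skewed);
a `log_transform=False` switch exists for sensitivity analysis and is stored
in the reference file. Because z-scores of the fitting sample have mean 0
and SD 1 exactly, the reference control cohort scores to sample mean 100 and
sample SD 10 by construction — this identity (to 1e−8) is the pipeline's
self-calibration check. Distances are computed in m-dimensional feature
space, which by orthonormality equals the 459-dimensional distance between
the m-th order reconstructions, at a fraction of the cost.

Degenerate cases: control strides at zero distance from c̄ are excluded from
the log statistics with a warning (at least two positive-distance strides
must remain, with positive spread); a scored stride at zero distance is a
domain error in single-stride scoring and a flagged invalid row in cohort
scoring. References are bound to their basis by a SHA-256 fingerprint of the
truncated feature matrix; scoring with a mismatched basis raises.

## Validation statistics

Per ordinal impairment level (plus the distinguished control group):
Kolmogorov–Smirnov normality screening — by default the Lilliefors variant,
since the normal's parameters are estimated from the same sample (the
plug-in "fixed" variant is exposed too); stratified histograms on shared
bin edges with each group's sample mean/SD as the fitted normal and the
control mean as a marker; one-way ANOVA for every pair of levels (for two
groups F equals the squared pooled-variance t statistic), with uncorrected
p-values by default and an optional Holm step-down; Kendall's tau-b
(tie-corrected, asymptotic-normal p) between the ordinal level and the
index; and Pearson correlation plus ordinary least squares for comparing
two competing indexes (new index regressed on old). Pairs containing a
group with fewer than two strides are skipped with a logged reason rather
than failing the table — sparse extreme levels are common in clinical
ordinal scales.

## Synthetic cohorts

No public dataset accompanies this index construction, so testing rests on
a generator whose ground truth is known by design. Each population template
draws, per angle, an offset A₀ ∈ [−10, 10]°, a fundamental amplitude
A₁ ∈ [5, 30]°, two higher-harmonic amplitudes A₂, A₃ ∈ [0, 8]° and uniform
phases — three harmonics of the gait cycle suffice to mimic the shape of
smooth time-normalized joint-angle curves (a modelling convenience, not
physiology). Per-stride variability: multiplicative amplitude jitter
(SD 0.05), baseline offset (SD 2°), phase jitter (SD 0.05 rad) and white
per-sample noise (SD 1°) — magnitudes chosen to give high communalities,
i.e. strides that share most of their variance with the population pattern,
the regime in which a few hundred strides support a stable basis. Severity
s ∈ [0, 1] attenuates harmonic amplitudes by (1 − 0.5 s), adds baseline
drift with SD 10 s ° and a phase lag of 0.3 s rad, so group-mean deviation
from the s = 0 template grows monotonically with s; ordinal labels attached
to severity bands emulate a clinical scale ordering without any claim of
clinical equivalence.

`generate_low_rank_cohort` builds cohorts of exactly known intrinsic rank k:
columns are standard-normal linear combinations of k random orthonormal
459-vectors, scaled by 10° so per-stride signal energy is comparable to real
joint-angle excursions (without the scale, sub-degree measurement noise
summed over 459 components would rival the signal and no finite VAF floor
would behave as it does on real gait data), plus optional white noise.
Noiseless output has numerically exact rank k.

What passing these tests shows — and does not. The generator produces
smooth, stationary, unimodal cohorts with isotropic noise; real gait data
has inter-lab marker-placement offsets, soft-tissue artefacts concentrated
in pelvic angles, within-subject stride correlation, and non-normal tails.
Calibration (mean 100/SD 10), orthonormality, rank recovery and monotone
severity response are structural properties that carry over to any data;
specific feature counts, VAF values and group separations measured on
synthetic cohorts do not transfer to clinical populations.

## Problem sizes and numerical choices

Test and acceptance runs use cohorts of 60–200 strides per group (600 for
the four-band severity experiment) — large enough that sample means are
stable at the asserted tolerances while the full suite runs in seconds.
Orthonormality is enforced at max |FᵀF − I| < 1e−10 and energy conservation
at relative 1e−10; the decomposition is validated against an independent
Gram-matrix eigendecomposition at 1e−8. Ties in the sign convention
(two components of equal magnitude) resolve to the first index. CSV I/O
round-trips floats exactly (round-trip parser; exact passthrough at shared
grid nodes during resampling).

## Known limitations

* The index is only as good as its basis: a basis derived from one
  population should not be assumed to transfer to another — quantifying
  exactly that failure is the motivating use case.
* No per-joint sub-indexes (gait variable scores / movement analysis
  profiles); the index is a single global scalar.
* C3D ingestion is out of scope; the package consumes pre-extracted
  long-format angle tables.
* The KS-variant and retained-vs-holdout choices above are documented
  defaults, not the only defensible ones; both have switches.
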