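# Methods

`lesionmap` re-implements, as a tested pipeline, the lesion-mapping analysis
used in moderate–severe traumatic brain injury (TBI) cohort studies of brain
contusions: lesion frequency distribution maps on a common voxel grid,
voxel-based lesion-symptom mapping (VLSM) with permutation familywise-error
(FWE) control, proportional-odds ordinal regression of the 12-month Glasgow
Outcome Scale Extended (GOSE), and the univariable cohort statistics that
populate clinical baseline tables.  Because clinical MRI cohorts of this
kind are not publicly deposited, the package ships a synthetic 3D
lesion-cohort generator whose defaults emulate the published cohort
structure; every downstream stage is exercised and validated against that
generator.

## Data model

All rasters live on a shared `VoxelGrid` (shape + RAS+ index→world affine).
Masks are binary, one per subject and lesion component (total /
hemorrhagic / non-hemorrhagic); geometry is verified on load to 1e-3 mm and
never resampled — upstream spatial normalization is assumed done.  Float
rasters are binarized at 0.5 to tolerate interpolation dust.  Subjects
carry injury severity (moderate = GCS 9–13, severe = GCS ≤ 8; enforced
against the recorded GCS), age, sex, pupil status, days from injury to MRI,
traumatic axonal injury (TAI) measures, GOSE, and derived lesion volumes
(voxel count × voxel volume).  GOSE is categorized 1–4 / 5–6 / 7–8 (severe
disability / moderate disability / good recovery).

Two grids are used throughout:

* a desk-scale grid, 24×28×24 at 3 mm (brain ≈ 228 cm³), the default for
  unit tests and FWE validation, where a full VLSM run takes well under a
  second; and
* an analysis-scale grid, 91×109×91 at 2 mm (brain ≈ 2 854 cm³), used for
  the headline volume-versus-location experiment, where per-voxel lesion
  overlap is sparse (mean ≈ 3 subjects per brain voxel at n = 300, matching
  the regime of a clinical cohort) and the tested-voxel field is large
  (~10⁵), which is what gives the maximum-statistic threshold its proper
  scale.

## Synthetic cohort generator

One seeded `numpy` generator drives all draws in a fixed order (per
subject: covariates, lesion count, total volume, partition, hemorrhagic
fraction, per-lesion seed region / center / shape / noise fields, GOSE
uniform), so cohorts are bit-reproducible.

**Covariates.** Severity is Bernoulli (59% severe). GCS is drawn from
severity-specific discrete distributions (severe median 6, IQR 3–7;
moderate median 12, IQR 11–13). Age is log-normal (median 32 y, IQR ≈
21–49, clipped to 8–70). Days to MRI are log-normal by severity (medians
10 / 6 d). Pupil status and TAI presence/grade follow severity-specific
tables; TAI-absent subjects carry grade 1 and volume 0. Small missingness
rates (GCS 1.7%, GOSE 7%, pupils ~1–2.5% untestable) exercise the
listwise-deletion paths.

**Lesions.** The lesion count is 1 + NegBin(r = 1, p = 0.24), giving
median 3 and IQR 2–6 per subject.  The per-subject total volume is
log-normal with median 13.76 cm³ and σ chosen so the IQR matches
2.8–39.5 cm³, clipped to a realizability cap expressed as a fraction of
the brain-mask volume (default 0.35 of the brain; the headline experiment
uses an absolute 40 cm³ cap, see below).  The total is split over lesions
by a symmetric Dirichlet.  Each lesion draws a seed region from calibrated
region weights, a center uniformly inside that region, and is realized as
the connected component (through the center) of a thresholded sum of an
anisotropic ellipsoidal kernel and smoothed Gaussian noise, clipped to the
brain mask, with the threshold searched so the component lands within 10%
of its target volume.  The hemorrhagic component is the core of each
lesion (voxels nearest its center) scaled to a zero-inflated-Beta
hemorrhagic fraction.

**Region weights.** The default atlas is a deterministic ellipsoidal
"brain" partitioned by coordinate planes into frontal (L/R), temporal
(L/R), parietal, occipital, cerebellum, deep structures and brainstem.
Seed weights were calibrated by simulation on the desk grid so that
subject-level frontal presence lands near the published 75%.  On a
desk-scale brain, lesions of clinically realistic absolute volume are ~6×
larger *relative to the brain* than in reality, so they spill across
region boundaries; small-region presence (parietal, deep, brainstem) is
therefore inflated well above the published percentages and cannot be
calibrated down — a known and accepted artifact of the scaled geometry.
Temporal presence saturates near 95% for the same reason.  Frontal
presence and the per-subject volume distribution are the calibrated,
tested quantities.

**Outcome.** GOSE (1–8) is drawn from a proportional-odds model on the
worse-outcome scale, logit P(GOSE ≤ k) = α_k + η, with

η = β_vol·log1p(V_total) + β_age·age + β_gcs·(15 − GCS) + β_tai·TAI_grade
  + δ·1[lesion intersects the focus region].

The volume dose is logarithmic by default (`volume_effect_scale`):
a saturating dose-response is the physiologically sensible assumption for
mass-lesion burden, and it reproduces the published pattern — a strong
univariable volume–outcome trend together with a modest fitted per-cm³
odds ratio (≈1.02) — without making individual high-overlap voxels carry
outsized outcome contrasts.  Cutpoints α₁<…<α₇ were calibrated
numerically so the marginal 3-category split approximates the published
21/38/41%.  Covariate coefficients are calibrated to the published
adjusted odds ratios (age 1.06/y, GCS-inverted 1.40, TAI grade 1.26).
δ = 0 by default: lesion *location* carries no outcome information unless
explicitly requested, which is exactly the null the VLSM stage should
report.  `generate_null_cohort` additionally sets β_vol = 0, making the
outcome independent of all lesion quantities while covariate effects
remain.

Because the proportional-odds family is closed under merging adjacent
categories, fitting the 3-category model to generated data recovers the
generating coefficients exactly (tested at n = 2000 within 3 SE).

## VLSM

Mass-univariate pooled-variance two-sample t per voxel (lesioned vs
non-lesioned, raw GOSE 1–8), testing only voxels with ≥ `min_overlap`
(default 3, the published choice) lesioned and ≥ 2 non-lesioned subjects.
FWE control is by the permutation distribution of the maximum |t|: the
outcome vector is permuted across subjects (lesion geometry fixed,
preserving the spatial correlation of the t field), the max over tested
voxels recorded per permutation, and the critical value taken as the
smallest observed null maximum whose (k+1)/(N+1) tail probability is ≤ α.
FWE p-values use the same add-one convention, so p ∈ [1/(N+1), 1] and the
test is exactly level-α.  The test is two-sided by default (configurable).
Degenerate voxels (zero pooled variance) are excluded from both the map
and the null rather than set to t = 0, which would deflate the null
maximum.  The permutation pass runs through two BLAS matrix products in
float32 (observed statistics in float64); a relative tie tolerance in the
p-value counting keeps the discrete null's atoms intact across precisions.
Degeneracy detection uses a magnitude-relative variance cutoff because the
sum-of-squares identity cancels catastrophically for constant groups.

Validation: on null cohorts (outcome independent of lesions) the
family-wise false-positive fraction at α = 0.05 is ≈ 3–5% (200 cohorts of
n = 40 on the desk grid, 500 permutations); on 6-subject/2-voxel problems
the Monte-Carlo threshold and FWE p agree with exhaustive enumeration of
all 720 outcome orderings; and a strong focal outcome effect (δ = 4 logit
units at a low-prevalence focus region, n = 100) is localized to the focus
in most runs.  Focal power is limited on the desk grid by diffuse region
presence: at any tested voxel a third of the *non*-lesioned subjects may
also carry the focal effect, so small shifts at n = 60 are usually not
detectable — a dilution effect worth remembering when interpreting
negative VLSM results generally.

## The volume-versus-location experiment

The headline analysis asks whether, when outcome depends on total
contusion volume but not on location (δ = 0), the pipeline reproduces the
published pattern: a significant Jonckheere–Terpstra trend of volume
across outcome categories, a significant adjusted proportional-odds OR for
volume, and **zero** VLSM-significant voxels.  This is run at n = 300 on
the analysis-scale grid with an absolute 40 cm³ volume cap and 500
permutations per run.

Two design choices matter here and are deliberate.  First, the large grid:
the maximum-statistic threshold grows with the size of the tested field,
and per-voxel overlap sparsity limits how much outcome contrast any single
voxel can carry; on the desk grid (≈6 000 tested voxels, dense overlap)
the same generative model produces genuine volume-mediated voxel
associations above threshold, and the published null is *not* expected to
reproduce there.  Second, the volume cap: subjects in the extreme volume
tail cover so much tissue that voxels collecting several of them become
"large-lesion detectors"; capping the realized volume (with the log dose
keeping rank-based trend power intact) bounds that mediation.  Even so,
the volume effect is a true systematic association at every voxel it
touches, and the α = 0.05 FWE test itself rejects in ~4–5% of null runs by
construction, so a fraction of runs (roughly a quarter, across the
configurations examined) reports a handful of significant voxels — these
are true volume-mediated associations, not false positives of the test.
The acceptance experiment therefore reports the success fraction over 20
seeded replicates; the published all-three pattern is the modal outcome,
not a near-certain one.

## Ordinal regression

Cumulative-logit proportional-odds fit, logit P(Y ≤ k|x) = α_k − xβ, with
the outcome order inverted (good recovery = level 1) so β > 0 means worse
outcome, GCS entered as 15 − GCS, and pupil abnormality binary (normal =
reference).  Maximization is damped Newton with analytic gradient and
Hessian (step halved until the likelihood improves and cutpoints stay
ordered); covariance is the inverse observed information; convergence at
gradient max-norm < 1e-8.  Wald 95% CIs use z = 1.959964.  Divergence
(|β| > 50) raises a separation error naming the covariate.  McFadden's
R² = 1 − ll/ll₀ with the cutpoints-only null.  The implementation matches
`statsmodels`' `OrderedModel` on shared data to ~1e-6 and is verified
against an independent optimizer on a fixed 12-row toy problem.  Four
preset covariate sets (model1–model4) pair total or hemorrhagic volume
with TAI volume or Trondheim TAI grade, alongside age, pupil abnormality,
inverted GCS and days-to-MRI.  Missing data are handled by listwise
deletion with the exclusion count reported.

## Cohort statistics

Pinned conventions: Pearson chi-square *without* continuity correction for
r×c tables (this, not the Yates-corrected form, reproduces the published
table p-values); Fisher's exact two-sided test when a 2×2 table has any
expected count < 5; Mann–Whitney U from midranks with tie-corrected
normal approximation and no continuity correction; Jonckheere–Terpstra
with tie-corrected null moments (implemented here — scipy has no JT),
reported two-sided; Spearman via midranks with the t-approximation.
Enumeration oracles (all 70 labelings for 4-vs-4 Mann–Whitney, all 1 680
assignments for 3×3 Jonckheere–Terpstra) bound the normal approximations
in the tests; analysis-time p-values are always the normal approximations,
adequate at cohort sizes in scope.

## What the synthetic validation does and does not show

The generator reproduces the *statistical* structure the pipeline assumes:
frontotemporal predilection, heavy-tailed volumes, covariate-coupled
ordinal outcome, and a location-free volume effect.  It does not emulate
lesion morphology realism, registration error, segmentation disagreement,
scanner effects, or spatially structured injury mechanisms (e.g., falls
producing different lesion patterns than traffic accidents).  Passing
tests therefore validate the computational pipeline and its statistical
calibration, not the clinical claims themselves; on real data the VLSM
null result additionally depends on cohort peculiarities no simulation
certifies.

## Problem sizes

Defaults used by the test-suite and the acceptance script: desk grid for
round-trips, FWE validation (200 null cohorts × 500 permutations) and
enumeration oracles; analysis grid for the 20-replicate headline
experiment (500 permutations per replicate); n = 2000 tabular cohorts ×
100 replicates for coefficient recovery.  These sizes were chosen so the
whole validation runs comfortably on a single CPU while keeping every
Monte-Carlo band well away from its decision boundary.
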