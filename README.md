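# lesionmap

Lesion frequency distribution maps, voxel-based lesion-symptom mapping
(VLSM) and ordinal outcome models for cohorts of traumatic brain injury
(TBI) patients with segmented brain contusions.

## The problem

In moderate–severe TBI, brain contusions concentrate in the frontal and
temporal lobes, and their total volume carries prognostic information for
the 12-month functional outcome (Glasgow Outcome Scale Extended, GOSE).
Whether the *location* of a contusion carries additional prognostic
information is the natural follow-up question, and the standard instrument
for it is VLSM: at every voxel of a common template space, compare the
outcome of patients with versus without a lesion there, then control the
familywise error over all voxels with the permutation distribution of the
maximum statistic.

`lesionmap` implements that full analysis for binary lesion masks already
registered to a shared grid:

* **cohort I/O** — NIfTI lesion masks (total / hemorrhagic components),
  a TSV/CSV clinical manifest, per-subject volumes (cm³), and a coarse
  region atlas for presence tables;
* **frequency maps** — per-voxel lesion overlap counts and relative
  frequencies, stratified by severity or outcome category, with maximum
  intensity projections for display;
* **VLSM** — mass-univariate pooled-variance t-tests (outcome: raw GOSE
  1–8) at voxels with ≥ 3 overlapping lesions, FWE-controlled by the
  max-|t| permutation null: critical value and per-voxel corrected p from
  the (k+1)/(N+1) convention;
* **outcome models** — proportional-odds (cumulative logit) regression of
  the 3-level outcome category (GOSE 1–4 / 5–6 / 7–8, inverted so odds
  ratios > 1 mean worse outcome), logit P(Y ≤ k|x) = α_k − xᵀβ, fitted by
  damped Newton with Wald CIs and McFadden's pseudo-R²;
* **cohort statistics** — Mann–Whitney U, chi-square/Fisher contingency
  tests, Jonckheere–Terpstra ordered trend, Spearman correlation, with the
  exact conventions that reproduce published clinical tables;
* **synthetic cohorts** — a seeded generator of 3D lesion cohorts
  (frontotemporal predilection, log-normal volumes with median
  ≈ 13.8 cm³, clinical covariates, proportional-odds GOSE coupled to
  volume and optionally to a focal location) so the whole pipeline is
  testable without patient data.

## Worked example

```python
from lesionmap import (SyntheticConfig, generate_cohort, run_vlsm, VLSMParams,
                       overlap_counts, tabulate_region_presence, make_default_atlas,
                       VoxelGrid)
from lesionmap.outcome_models import fit_outcome_model, effect_frame

cfg = SyntheticConfig(n_subjects=301, seed=7)      # 24x28x24 grid at 3 mm
cohort = generate_cohort(cfg)

atlas = make_default_atlas(VoxelGrid.default())
print(tabulate_region_presence(cohort, atlas)[["region", "n_all", "pct_all"]])

fit = fit_outcome_model(cohort, "model2")          # age, pupils, GCS, days,
print(effect_frame(fit).round(3))                  # total volume, TAI grade
print(f"McFadden R2 = {fit.mcfadden_r2:.2f}")

res = run_vlsm(cohort, VLSMParams(n_permutations=500, seed=7))
print(f"tested {res.n_tested} voxels, critical |t| = {res.critical_t:.2f}, "
      f"{res.n_significant} significant")
```

Output (seed 7):

```
       region  n_all    pct_all
0     frontal    229  76.079734
1    temporal    295  98.006645
2    parietal    274  91.029900
3   occipital    154  51.162791
4  cerebellum    188  62.458472
5        deep    152  50.498339
6   brainstem    145  48.172757
             covariate     OR  ci_low  ci_high      p
0                  age  1.068   1.050    1.085  0.000
1    pupil_abnormality  1.036   0.501    2.140  0.924
2         gcs_inverted  1.497   1.354    1.655  0.000
3          days_to_mri  1.009   0.987    1.032  0.420
4     total_volume_cm3  1.025   1.011    1.040  0.001
5  tai_trondheim_grade  1.231   0.999    1.517  0.051
McFadden R2 = 0.32
tested 5751 voxels, critical |t| = 4.58, 1 significant
```

The fitted odds ratio of 1.03 per cm³ of contusion — modest per unit but
substantial across the volume range — together with frontal presence near
the calibrated 75%, is the emulated cohort structure (temporal and
small-region presence is inflated on this desk-scale grid; see
`docs/methods.md`).  The single significant VLSM voxel illustrates that on
a small grid a strong volume effect can surface at individual voxels; the
location-effect experiment proper runs on the analysis-scale 91×109×91
grid, where the same generative model reports zero significant voxels in
most runs.

A complete run (simulate → frequency maps → VLSM → models → statistics)
with provenance:

```bash
lesionmap run --config config.yaml --out-dir runs/demo --seed 42
```

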