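# Methods

## The scoring model

The package quantifies abdominal aortic calcification (AAC) on lateral
projections of the lumbar spine using the 24-point Kauppila scheme. For
each lumbar level L1–L4 and each aortic wall (anterior and posterior, where
posterior means spine-adjacent in lateral projection), the *coverage
fraction* `f` is the calcified extent projected onto the vertebral axis
divided by the vertebral height. The per-wall score is

- 0 if `f ≤ ε` (noise floor, default `ε = 0.02`),
- 1 if `f < 1/3`,
- 2 if `1/3 ≤ f ≤ 2/3` (both cut points belong to the middle class, since
  the verbal rule uses "< 1/3", "from 1/3 to 2/3", "> 2/3"),
- 3 if `f > 2/3`,

and the total is the sum over the eight (level, wall) pairs. Coverage is
measured by row projection — presence of any calcified pixel per image row —
not by pixel area, matching a "calcification length" reading of the rule.
The floor `ε` exists because "visible" calcification is reader-dependent; a
numeric floor makes the rule executable.

## Pipelines and ensemble

Two independent pipelines produce a total score:

1. **Segmentation pipeline** — semantic segmentation of the lower spine
   (pelvis + vertebrae), box extraction, spine-curve fit, aortic ROI,
   rule-based detection and scoring.
2. **Detection pipeline** — per-vertebra box detection directly on the
   image, spine-curve fit, aortic ROI, learned regression of the total.

The ensemble is the arithmetic mean of the two totals. If exactly one
pipeline fails localization, its partner's score is reported with a
provenance flag; an image failing both is excluded and reported, mirroring
how automated scoring covers only the localizable subset of a cohort.
(Which outputs the original system averaged is ambiguous; this package
averages its two pipelines' final totals and documents that reading.)

### Localization

The classical segmenter thresholds at Otsu's threshold computed on the
upper intensity quartile (the bright tail containing bone), applies a 3×3
morphological opening, and keeps connected components above 20 px. The
pelvis is the largest component; vertebra candidates are components above
the pelvis with at least 40% of the largest such component's area (smaller
bright objects — deposits, ribs — are thereby excluded). Vertebra labels
anchor on the pelvis and count upward: the nearest candidate above the
pelvis is L4. With more than four candidates the four largest are kept and
the decision logged; with fewer, localization fails.

The learned segmenter is a per-pixel random-forest classifier over
multiscale features (raw and Gaussian-smoothed intensity at σ = 1, 2, 4,
gradient magnitude, local variance, normalized coordinates), trained on
label masks and cleaned by the same component logic. It exists to exercise
the trained-model interface; the classical back-end is the deterministic
reference path. (The learned variants use scikit-learn models; the package
is deep-learning-free by design so that training runs in seconds on a
single CPU.)

### Aortic ROI

A least-squares polynomial `column = p(row)` (degree 2 by default — lumbar
lordosis is one gentle bend) is fit through the four vertebral centroids.
The aortic band is *centered* on the expected aortic centerline at
`offset_factor × mean vertebral height` anterior to the curve (default
1.2×) with width `width_factor × mean vertebral height` (default 0.8×);
the band midline is the centerline, and the split at the midline yields the
posterior and anterior wall sub-bands (the midline pixel itself belongs to
the anterior wall — ties must go somewhere, and the choice is asserted in
tests). In projection nothing in the data defines the two walls; this
split is the single most consequential modelling choice and is isolated in
one function (`scoring.coverage_from_mask`). Per-level row ranges come
from the detected boxes, so unequal vertebrae are handled. Offset and
width are configuration, not anatomy: on real images they would need
tuning, and the phantom generator uses the same constants.

### Rule-based detection

Within each level's band, pixels brighter than
`background + 0.35 × (bone_reference − background)` are marked, where the
background is the band's median intensity and the bone reference the
image's 99th percentile. Components smaller than 3 px are discarded (an
isolated noise pixel cannot span 3 px; a minimal one-row deposit can).
Both constants are exposed in `DetectionConfig`.

### Learned regression

The regressor (gradient-boosted trees) maps 48 band features — per wall
sub-band: mean, max and 90th percentile of background-subtracted row
maxima, plus bright-row fractions at three relative thresholds — to the
total score, clipped to [0, 24]. It trains on (image, ROI, reference
total) pairs; at the published scale of 1,000 training images it reaches
validation MAE ≈ 0.13 on synthetic data (the tests pin only the published
floors, r ≥ 0.67 and MAE ≤ 1.27).

## The phantom generator

Phantoms are 128×80 px, 1 mm/px images: four bright vertebra rectangles
(height 14 px by default, per-image 12–16) stacked along a quadratic spine
curve, a pelvic ellipse inferior to L4, and calcific deposits — 3 px wide
bars at the two wall positions (`±0.2 × vertebral height` around the aortic
centerline), with row extent `round(f × height)` for requested coverage
`f`. Ground truth records the *realized* (pixel-quantized) coverage and
applies the scoring rule to it; realized and requested extents differ by at
most one pixel. Deposits at L1–L2 are rendered at a 0.6 contrast
multiplier, emulating how that region is hard to distinguish from
background on real scans. A non-calcified aorta is not rendered at all —
on DEXA it is invisible.

Noise model (defaults): a smooth random background field (amplitude 0.08),
multiplicative speckle (sd 0.05), and additive Gaussian noise (sd 0.05),
against tissue ≈ 0.15, bone ≈ 0.9, deposit ≈ 0.68 normalized intensity.
Image sets vary curvature, spine position and vertebral height per image
and draw coverage from the score-distribution model below. Everything is
deterministic given config + seed.

**What the phantoms do not emulate:** overlying bowel gas and ribs,
vertebral fractures and osteophytes, aortic tortuosity and
subject-specific aorta–spine distance (the generator places the aorta at
the extractor's own offset constant, so localization error on real images
is *understated*), scanner point-spread, and true X-ray attenuation
physics. Passing end-to-end tests therefore demonstrates internal
consistency of the geometry, detection and scoring chain — not expected
performance on clinical scans, for which the published agreement figures
(r ≈ 0.67, MAE ≈ 1.27 against human readers) serve only as floors that the
much cleaner synthetic setting must beat.

## Score distribution and synthetic cohorts

The coverage sampler is sparse: with probability 0.36 a subject has no
calcification; otherwise `1 + Binomial(7, 0.10)` wall segments are affected
(L3/L4 favored 1.0 : 0.6 : 0.4 over L2 : L1, matching scores being driven
by the L3–L4 region) and each affected wall's coverage is Beta(0.8, 3.8).
These four constants were calibrated once, by grid search against the
published prevalence regime (mean ≈ 1.47, sd ≈ 1.49, ~11.6% of scores
above 3); the default cohort realizes mean ≈ 1.32, sd ≈ 1.30 and
P(score > 3) ≈ 0.117, matching the exceedance fraction and approximating
the moments.

Cohorts add, on top of the rule-scored base: a linear age effect (0.45
score units per SD of imaging age), smoking shifts (+0.12 previous, +0.20
current), and per-SD biomarker shifts (positive for HbA1c, glucose,
phosphate, triglycerides, systolic BP; negative for creatinine and HDL;
zero for LDL and cystatin C — the null associations the analyses must not
invent). Statin use follows confounding by indication,
`logit⁻¹(−2.15 + 1.0·z_LDL + 0.5·z_age)` (marginal ≈ 15%); users' measured
LDL is untreated LDL − 1.25 mmol/L (the exact inverse of adjustment
model 1, making the inverse-identity test exact) while triglycerides are
scaled by 0.85 — deliberately *not* the model-1 inverse, so triglyceride
adjustment is only approximate, as in reality. Event times are exponential
given the proportional-hazards linear predictor (defaults: MI with HR 1.4
per SD of AAC and 1.4 per SD of untreated LDL, plus representative
cardiovascular/respiratory outcomes and one null disease), censored
administratively at 12 years post-baseline. Times are stored from the
baseline visit; imaging-visit indexing treats pre-imaging events as prior
history and re-references the clock.

## Cohort analyses

- **Prevalence**: mean, sample sd, the mean+1sd threshold, the
  score > 3 exceedance fraction, and per-(age decade × sex) quantiles.
- **Statin adjustment** of measured lipids for users (non-users always pass
  through): model 1 adds 1.25 mmol/L; model 2 multiplies by
  1/(1 − 0.35) ≈ 1.54 (the stored constant is the 35% on-treatment
  reduction; the ~54% increase is derived); model 3 imputes untreated
  levels from blood pressure, pulse, age, sex and non-lipid biomarkers via
  a regression fitted on non-users.
- **eGFR** from cystatin C uses the CKD-EPI 2012 cystatin-C-only equation,
  pinned in one function so it can be swapped.
- **Biomarker associations**: OLS of standardized AAC on the standardized
  biomarker plus model-1 (age, sex) or model-2 (+BMI, socioeconomic index,
  smoking, ethnicity) covariates; effects read SD-of-AAC per
  SD-of-biomarker; Bonferroni across the tested set.
- **Prognosis screen**: per disease, prior-history exclusion, a
  more-than-`min_events` (default 25) post-index event filter, Cox
  proportional-hazards fit (lifelines; Efron tie handling) of the
  standardized AAC score with model-1/2 covariates, two-tailed p-values and
  Bonferroni correction across tested diseases. Default index is the
  imaging visit for prognosis and the baseline visit for the MI/lipid
  model (where lipids were measured).
- **Joint MI model**: Cox fit of MI on standardized AAC, adjusted LDL,
  adjusted triglycerides, age and sex, plus an AAC × LDL interaction term;
  available on the whole cohort (any statin model) and the non-user
  subgroup (measured lipids).

## Numerical and testing choices

- Scoring-rule boundaries are compared with a 1e-9 tolerance so that
  row-count ratios landing exactly on 1/3 or 2/3 classify stably.
- Collinear centroids under a quadratic fit fall back to a straight line
  with a warning; curve residuals above ¼ vertebral width warn.
- Problem sizes in the test suite: 300 noise-free and 300 noisy phantoms,
  a 1,000-image training set for the pipeline regressor (the published
  train/validation split sizes), 100 survival replicates at n = 2,000, and
  100 null screens of 50 diseases at n = 600 with a baseline rate giving
  ~50–100 events per disease — sizes chosen so the full suite runs in
  minutes on one CPU.
- The null-screen family-wise-error check asserts the empirical rate over
  100 seeded screens is consistent with the nominal 0.05 Bonferroni bound
  (binomial 99% envelope, ≤ 9 flagged screens), since the count itself is
  Binomial(100, ≈0.049).
- Known limitations: no DICOM ingestion; no intimal/medial distinction
  (below DEXA resolution); phantom realism limits above; hazard CIs are
  Wald-based and can undercover at very low event counts.
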