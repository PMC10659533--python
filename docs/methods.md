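# Methods

`neuroprog` implements a four-way prognostic model comparison for patients
presenting with subjective cognitive decline (SCD) or mild cognitive
impairment (MCI): who progresses to Alzheimer-type dementia within four
years, and how fast does global cognition (MMSE) decline?  The package
covers the whole protocol — outcome extraction, predictor sets, model
fitting, evaluation statistics, interpretability — plus a calibrated
synthetic cohort generator so that every stage is testable without access
to any clinical dataset.

## Outcomes

* **4-year progression** (binary): true iff an AD-dementia diagnosis is
  recorded at any visit with time ≤ 4 years.  The interval is closed: a
  diagnosis exactly at the 4-year visit counts.
* **4-year MMSE slope** (continuous, points/year): per-subject OLS slope of
  MMSE on time, over all visits within the horizon.  The baseline visit is
  included in the fit — it is the only thing anchoring the line at t = 0.
  Subjects with fewer than two usable visits keep the binary outcome but
  drop out of the continuous analysis (slope = NaN).

## Predictor sets and models

| set | features | learner (binary / continuous) |
|---|---|---|
| clinical | age, sex (F=1/M=0), education, baseline MMSE, ADAS delayed recall errors, APOE ε4 allele count | logistic / linear regression |
| hippocampus | clinical + hippocampal volume (L/R mean, mm³) + intracranial volume | logistic / linear regression |
| freesurfer | clinical + 68 Desikan–Killiany gray-matter volumes + intracranial volume | random forest, library defaults |
| deep | MRI volume + Jacobian-determinant (JD) volume + clinical vector | multi-task 3-D CNN |

Tabular features are z-scored with statistics fitted on the training rows
only.  The logistic fit is unpenalized maximum likelihood (`C=inf`,
tolerance 1e-10, so it agrees with a Newton–Raphson/IRLS solve to ~1e-6).
The random forest keeps the scikit-learn defaults with only the seed
fixed; the versions in effect are recorded in the run manifest.

## The multi-task CNN

Because no deep-learning framework is available in the target environment,
the network is implemented directly in NumPy (`neuroprog.nn`): grouped /
depthwise-separable 3-D convolutions by patch extraction + einsum, explicit
backward passes (finite-difference-checked in the test suite), and Adam.
Training is bit-deterministic given the seed.

Architecture: one branch per enabled image modality —
Conv(1→c0, 3³, stride 2) → [depthwise 3³ stride 2 + pointwise 1³] × 2 →
global average pooling — concatenated with the [0,1]-scaled clinical vector,
a shared dense layer, and three heads: sigmoid (progression), linear (MMSE
slope), linear (hippocampal volume).  Default widths (8, 16, 32), hidden 32:
about 3,200 parameters, deliberately parameter-efficient.  Three stride-2
stages require ≥ 8 voxels per axis.

The loss is `L = w1·L1 + w2·L2 + w3·L3` with L1 a class-weighted binary
cross-entropy (weights inversely proportional to training-fold class
frequencies; for two classes the sigmoid/binary form coincides with the
categorical one) and L2/L3 mean-squared errors.  Both regression targets
are min-max scaled to [0, 1] on the training fold so that small auxiliary
weights are comparable across tasks.  Defaults: `w1=1, w2=w3=0.025` when
progression is the main task, `w2=1, w1=w3=0.025` for the slope task.  The
auxiliary-weight grid searched on validation data is
{0, 0.025, 0.05, 0.075, 0.1}.

Input normalization: MRI volumes are affinely mapped so the training-set
global min/max land on [−1, +1]; a literal variant (`x/(0.5·max) − 1` after
subtracting the min) is available behind a switch but only reaches [−1, 1]
when the minimum is 0, so the exact affine map is the default.  JD volumes
pass through unchanged.  Clinical inputs are min-max scaled to [0, 1] with
held-out values clamped into the training range.  All statistics are fitted
on training data only; the "entire-set" alternative exists solely as a
compatibility option, because leakage-free evaluation is the point of the
protocol.  Geometric harmonization uses center-aligned crop (MRI) or
symmetric zero-pad (JD), with odd remainders assigned to the high-index
side.

Schedule: Adam, initial rate 1e-3, multiplicative per-epoch decay 0.97,
batch 32, 50 epochs at full scale.  Desk-scale runs (tests, acceptance
script) use 6–25 epochs and, where the scenario is noise-free, a 1e-2 rate;
these counts are config values, not protocol.  No early stopping, no
augmentation.

## Evaluation protocol

1. **Balance-tested 80/20 split.** The test set takes `floor(0.2·n)` from
   each outcome group (332 subjects → 65 test / 267 development, matching
   the published cohort arithmetic).  Draws are repeated (cap 10,000) until
   no balance test rejects at α = 0.05: Fisher's exact for sex, SCD/MCI
   diagnosis, and APOE ε4 carriership (the allele count is dichotomized
   because Fisher's test needs categories), Welch's t-test for age and
   education (robust to unequal variances).
2. **Stratified 10-fold CV** of the development set (class counts per fold
   differ by ≤ 1); one model per fold, each scored on the untouched test
   set.  The reported statistic is the mean of the 10 per-fold test
   metrics (AUC for progression, R² for slope), not the metric of averaged
   predictions (the alternative is a flag).
3. **Model comparison.** Pairwise two-sided Mann-Whitney U over the 10 fold
   scores; exact enumeration when both samples have n ≤ 10 with no ties,
   otherwise the normal approximation with tie and continuity correction.
   p-values are reported unadjusted at α = 0.05, a documented limitation.
4. **Bootstrap 95% CIs** of the fold-mean statistic by percentile over
   B = 2000 resamples of test subjects, stratified by class for AUC so the
   metric is defined on every resample.

## Occlusion interpretability

Blocks of the normalized input volumes (default: grid/8 per axis,
non-overlapping tiling; size, stride, and channel are config values since
no canonical choice exists) are set to 0 and the drop in the correct-class
progression probability is recorded — p for progressors, 1 − p otherwise —
because "performance" is undefined for a single subject; a signed-Δp mode
exists behind a flag.  Maps are averaged over 5 progressing + 5 stable test
subjects and all 10 fold models.  Occlusion happens after normalization:
the network literally sees zeros.

## Synthetic cohort generator

The generator states a world with the structure the analysis assumes:

* Two groups, 32.8% early-AD (109/332 at the default size), and a latent
  severity in [0, 1]: Beta(2,5) for non-AD, Beta(5,2) for early-AD —
  overlapping but separated, so predictors are realistically imperfect.
* Clinical features per group Gaussian (or categorical) calibrated to the
  published demographics table (e.g., MMSE 28.2 ± 1.7 vs 27.2 ± 1.7, ADAS
  4.1 ± 2.4 vs 6.5 ± 2.0, hippocampal volume 3327 ± 490 vs 2973 ± 401 mm³,
  APOE ε4 count 0.4 ± 0.6 vs 1.0 ± 0.7 via allele-count tables
  (0.65, 0.30, 0.05)/(0.27, 0.46, 0.27)).  Hippocampal volume is a linear
  function of severity whose slope reproduces the group means exactly, with
  residual noise topping within-group SD up to the calibration target.
  Effect sizes are overridable per feature (continuous: pooled-SD units;
  categorical: a multiplier on the default probability gap); zeroing all of
  them yields a null world in which group means differ only by sampling
  noise.
* MMSE trajectories: mmse(t) = baseline + slope(severity)·t + N(0, 1),
  slope = −1.5·severity points/year, rounded to integers and clipped to
  [0, 30] (rounding can be disabled for exact slope-recovery oracles; the
  pre-rounding slope is retained on the record).  Default visits at 0/2/4
  years with optional jitter — the visit schedule is a stated choice, as no
  canonical spacing exists.  Early-AD subjects receive a dementia flag from
  an onset time 0.5 + 3.5·(1 − severity) years, always within the 4-year
  horizon; non-AD subjects never do.
* Images: a smooth radial "brain" inside an ellipsoid on a 32³ grid (4 mm
  voxels — full 1 mm resolution is out of desk scale but the shape is
  configurable), JD ≡ 1 except inside configured atrophy blocks where
  JD = 1 − severity·coefficient and MRI intensity is reduced by the same
  factor; additive Gaussian voxel noise (SD 0.02 MRI, 0.01 JD).  Default
  blocks: two bilateral medial-temporal cubes (coefficient 0.35).  Blocks
  are specified in fractional coordinates so they are grid-shape-agnostic.
* 68 regional volumes around plausible per-region baselines (SD 8%), with
  the AD-signature subset (entorhinal, parahippocampal, temporal, inferior
  parietal, precuneus, fusiform) losing up to 15% at severity 1.

What the generator does **not** emulate: scanner physics, registration
error, segmentation noise, missing visits, informative dropout, site
effects, or CSF biomarkers.  Baseline clinical features carry group-level
signal only (per-group Gaussians; severity couples to hippocampal volume,
regional volumes and the images, not to the cognitive scores within group),
so the continuous slope outcome — driven by within-group severity — is
nearly unpredictable from clinical features at desk scale: test R² for the
linear slope models hovers around zero, unlike in real cohorts where
baseline cognition tracks subsequent decline.  A green test therefore
establishes that the pipeline recovers structure it injected — not clinical
performance; the published headline metrics come from a non-public cohort
and are directional context only.

## Numerical and design choices

* Sex F=1/M=0 and APOE as allele count: the encodings are arbitrary but
  fixed and documented.
* Held-out min-max values are clamped, keeping network inputs inside the
  trained range.
* Rejection-sampling split search is capped so an impossible constraint
  surfaces as an error naming the failing variables instead of looping.
* `k = n` folds degenerate to leave-one-out (stratification is vacuous
  there); otherwise k must not exceed the minority-class count.
* A model whose fold fit fails is marked failed in the report; the
  comparison proceeds for the remaining models.
* Determinism: every random draw traces to a seed recorded in the run
  manifest; CNN training is bit-reproducible on one CPU thread.

## Limitations

* The NumPy CNN is desk-scale: full-resolution volumes would need a GPU
  framework, and the architecture is a parameter-matched stand-in, not a
  reproduction of any published layer configuration.
* Percentile bootstrap CIs undercover slightly at small n (the calibration
  test brackets empirical coverage at 92–98% for n = 30 per class).
* Pairwise model-comparison p-values are not multiplicity-corrected, by
  design of the protocol being reproduced.
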