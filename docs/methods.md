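# Methods

`eyosvr` implements a transfer-learning analysis for Alzheimer's disease
(AD) progression: a support-vector-regression (SVR) ensemble is trained to
predict estimated years to symptom onset (EYO) from multimodal biomarkers
in an autosomal-dominant AD (ADAD)-like cohort, transferred blindly to a
sporadic amnestic-MCI-like cohort, validated against 1–4-year cognitive
decline, and used to quantify how score-based risk enrichment shrinks the
sample size a clinical trial needs. Because the cohorts this design targets
(mutation-carrier family studies and sporadic-MCI observational studies)
are controlled-access, a first-class synthetic-data module generates
cohorts with the statistical structure the analysis assumes; everything
downstream is tested against that generator's ground truth.

## Synthetic cohorts

**Biomarker trajectories.** Each feature (30 amyloid-PET ROI SUVRs, 30
FDG-PET ROI SUVRs, 30 gray-matter thickness/volume ROIs, 3 CSF analytes)
follows a logistic curve along a disease-time axis `t`:

    x(t) = healthy + direction · asymptote · expit(steepness · (t − midpoint))

plus a subject-level random offset and measurement noise. The sigmoid is
the simplest monotone saturating form consistent with the amyloid-cascade
literature; no functional form is dictated by the data sources this design
emulates, so the parameters are fully config-exposed. Modality anchors
encode the canonical ordering of biomarker change — amyloid accumulates
early (midpoints ≈ −15 EYO years), CSF p-tau/t-tau intermediate, FDG
hypometabolism and atrophy late (≈ −5 to 0). Healthy reference subjects
sit at the pre-disease asymptote with the same noise.

**Disease clocks.** Mutation carriers carry an explicit EYO drawn from a
truncated normal; the parent mean/SD are solved numerically so the
*truncated* sample matches the published carrier moments (−7.10 ± 11.23
years) — naive truncation would shrink the SD by ~15%. Sporadic subjects
carry a latent burden expressed on the same axis, making the trained
model's output interpretable as a disease-stage estimate; a shared latent
factor is the only cross-modality coupling (the empirical covariance
between modalities is not published, and this is the minimal structure
supporting the transfer).

**Instruments.** The sporadic cohort's raw features pass through a
per-modality affine transform (default: amyloid scale 0.85 / offset 0.12,
AV45-like versus PiB-like; CSF scale 1.4, different immunoassay
platforms). This is exactly the nuisance structure reference-group
harmonization must remove, and tests verify that it does.

**Amyloid stratification.** Amyloid status is the realized raw-scale
global amyloid composite thresholded at an AV45-like SUVR of 1.11. Burden
candidates are rejection-sampled from N(−22, 12²) until the positive and
negative strata hold exactly the requested counts (216 / 175 by default),
because published stratum sizes are the only constraint available.

**Cognition.** Each MCI subject's memory composite and global-cognition
score are linear in time over annual visits (baseline through year 4),
with measurement noise per visit (mem SD 0.15, global 1.8). True annual
slopes are linked to the burden excess over the amyloid threshold in the
amyloid-positive stratum only (`slope = −0.006 · excess-burden + N(0,
0.04)` for memory) and unlinked in the negative stratum, encoding the
amyloid-dependence the validation analysis is designed to detect. Default
link and noise values were chosen so that unselected amyloid-positive
memory decline is ≈ −0.05 to −0.07 points/year with between-subject slope
SD ≈ 0.06 — the regime the published validation cohort occupies — and are
not revisited per test. Visit dropout is off by default; an optional
per-visit dropout rate reproduces shrinking follow-up Ns.

**What the generator does not emulate.** No voxel-level images, no
APOE/genetic substructure, no practice effects or non-linear cognitive
trajectories, no site effects beyond the single per-modality affine, and a
single latent factor rather than a full biomarker covariance. Passing
tests therefore demonstrate correctness of the pipeline's machinery and
the internal consistency of the analysis — not that real cohorts would
yield the published effect sizes.

## Harmonization

Each cohort's features are z-scored against that cohort's own healthy
reference group (non-carrier siblings; cognitively normal amyloid-negative
subjects), fitted once per cohort before any cross-validation, with the
sample (n−1) SD by default (config-switchable to population SD). A
zero-variance reference feature is an error, not a silent drop. No
statistic crosses cohorts, which is what keeps the external validation
blind. "Standardized and variance normalized" is interpreted as
mean-centering plus unit variance; no further transform is applied.

## Nested double cross-validation

Training subjects are split into K2 = 10 outer folds; each outer training
pool is split into K1 = 10 inner folds; both levels are repeated under
random permutations (P2, P1). Per inner fold: features are ranked by
|Spearman ρ| with EYO on the inner-training subjects only and the top 35%
retained (ceil(fraction · p); ties broken by feature name; a constant
feature counts as ρ = 0 and never outranks a defined ρ), then an SVR grid
(C ∈ 2⁻⁶…2⁴, ε ∈ {0.01, 0.1, 1}) is fitted on the inner-training portion
and the grid point with minimum held-out inner MSE becomes that fold's
optimal model (ties: smaller C, then smaller ε). Feature selection runs
once per inner fold, before tuning. Each outer test fold is predicted by
the unweighted mean of its pool's P1·K1 optimal models; performance is the
pooled Pearson r over all held-out predictions (R² = r² by convention),
pooled across outer permutations.

The kernel and grid are declared defaults, not inferred: a linear kernel
keeps weights interpretable for selection-probability maps and is the
standard choice at n ≈ 121, p ≈ 93. The linear path is solved with
liblinear (`LinearSVR`, ε-insensitive loss, tol 1e-3, max 2000 iterations,
target centered before fitting because liblinear penalizes the intercept);
non-linear kernels fall back to the kernelized solver. Fold assignments
derive from per-(permutation, fold) counter-based substreams of one master
seed, so any subset of the design reproduces identical folds.

The full design holds P2·K2·P1·K1 = 10,000 optimal models; the package
default for pipelines and tests is the reduced 2·10·2·10 = 400-model
design (the model count is bookkeeping, not a statistical requirement).
Every model records the subject ids it touched, and an audit asserting
disjointness from its inner and outer test folds runs after every nested
run, aborting on any violation.

**A caveat on the pooled null.** Pooled K-fold correlation is biased
negative under a null signal: a near-constant tuned predictor equals
(approximately) its training-pool mean, which anti-correlates with the
held-out fold mean, giving pooled r ≈ −1/√(fold size) (≈ −0.26 at fold
size 15) whenever tuning collapses to a constant predictor. Across seeds
the tuned ensemble only sometimes collapses, so the average |r| under
permuted targets sits just below 0.1 rather than at the ~0.08 sampling
level a naive reading would expect. This is a property of the pooled
statistic itself, not of this implementation.

## Transfer and validation

The frozen ensemble scores external subjects as the arithmetic mean of all
member predictions (per-model SD reported as spread); no refitting,
recalibration, or pooling across cohorts. Missing registry features are a
hard error (no imputation); surplus features are dropped with a warning.
Scores stay on the EYO scale and are also emitted z-scored within cohort.

Validation is two-step: (1) per-subject OLS slopes per follow-up window,
computed in closed form, with a window-k slope requiring complete annual
visits 0..k (this literal completeness rule is what produces monotonically
shrinking Ns over longer windows when dropout is on); (2) the slope (or
baseline score) regressed on the SVR score with age, sex (0/1), and
education as covariates, outcome and score z-scored so the score β is
standardized, optionally adding baseline cognition. The score effect size
is partial R² = t²/(t² + df); a semi-partial variant is available by
switch because the partial identity does not exactly reproduce some
published partial-R² values from their printed t and df, and the formula
used there is not recoverable.

## Enrichment and power

At-risk selection keeps subjects with scores strictly above the
within-stratum median (amyloid-positive stratum by default; an exact
median tie is excluded). The group time effect is estimated with a
random-intercept linear mixed model (REML; fixed effects time + age + sex
+ education; optimizer falls back lbfgs → Powell → CG before raising).
Required N per arm for a fractional intervention effect f uses
d = f·|mean annual change| / SD(annual change) in the analyzed group and
the exact noncentral-t power of a two-sided two-sample t test (α = 0.05,
power 0.8), returning the smallest sufficient integer (and an explicit
infinite sentinel at d = 0). The SD denominator is the observed
between-subject SD of the subject-level changes; published enrichment Ns
scale with f as roughly 1/f^2.2 rather than the 1/f² any d-proportional
construction implies, so the exact published construction is not
recoverable — the standard construction is implemented and the discrepancy
noted rather than reverse-engineered. Percent reduction is
round(100·(1 − N_selected/N_none)) against the matching no-selection cell.

## Problem sizes used in tests and the acceptance script

Unit and acceptance tests run the reduced designs: 400-model ensembles for
the leakage audit (n = 150 carriers), 50-fold (10×5) single-permutation
runs for signal-recovery and null calibration (20 seeds each), 25-fold
ensembles for the 10-seed qualitative-pattern suite, and 200 reduced
cohorts for type-I calibration. The acceptance script runs one 100-model
(10×10, single-permutation) sweep over the G/AG/AGC/AFGC subsets at the
default cohort sizes, then the full transfer → validation → enrichment
chain. These sizes were chosen so the whole analysis replays comfortably
on a single CPU while preserving every structural property of the full
10,000-model design.

## Known limitations

* The synthetic generator's effect sizes are calibrated to the published
  regime but are not fits to real data; absolute βs and required Ns from
  synthetic runs characterize the machinery, not the cohorts.
* Pooled CV2 r carries the structural null bias described above.
* Persistence of trained ensembles is implemented for the linear kernel
  only (flat text weight tables).
* No survival/conversion modelling, no multiple-testing correction, no
  dropout or cost modelling in the power analysis, and no tau-PET
  modality.
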