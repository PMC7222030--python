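# eyosvr

Machine-learning prediction of Alzheimer's disease (AD) progression by
transfer from inherited AD: train a support-vector-regression (SVR)
ensemble to predict **estimated years to symptom onset** (EYO = age at
examination − parental age at symptom onset) from multimodal biomarkers in
an autosomal-dominant AD (ADAD)-like cohort, apply the frozen ensemble
blindly to a sporadic amnestic-MCI-like cohort, test whether the resulting
per-subject **SVR score** predicts baseline cognition and 1–4-year
cognitive decline, and translate score-based **risk enrichment** into the
sample size a clinical trial needs per arm.

The package is aimed at biostatisticians and trial methodologists working
with multimodal biomarker panels (amyloid-PET **A**, FDG-PET **F**,
gray-matter structure **G**, CSF analytes **C**). Because the cohorts the
design targets are controlled-access, a first-class synthetic-data module
generates ADAD-like and MCI-like cohorts with the assumed statistical
structure (sigmoid biomarker trajectories on a common disease-time axis,
cohort-specific instrument offsets, amyloid stratification at an SUVR-1.11
cutoff, burden-linked cognitive slopes) so the entire analysis is
reproducible and testable offline.

## The model

Within the training cohort, repeated nested double cross-validation
(outer CV2 folds for unbiased performance, inner CV1 folds for tuning):

1. per inner fold, retain the top 35% of features by |Spearman ρ| with
   EYO, computed on the inner-training subjects only;
2. fit linear-kernel SVRs over a C × ε grid and keep the grid point with
   minimum held-out inner-fold MSE (the "optimal CV1 model");
3. predict each outer test fold with the unweighted mean of its pool's
   optimal CV1 models; performance is the pooled Pearson r between
   observed and predicted EYO (R² = r²).

With 10 outer folds × 10 inner folds × 10 permutations at each level the
ensemble holds 10,000 optimal models (the package defaults to a reduced
2·10·2·10 = 400-model design; all counts are configurable). The frozen
ensemble's mean prediction for an external, reference-harmonized subject
is that subject's SVR score — an estimated disease stage in EYO-scale
years. Validation regresses per-subject OLS cognitive-change slopes on the
score (covariates age, sex, education; standardized β; partial
R² = t²/(t²+df)), stratified by amyloid status. Enrichment selects
above-median-score amyloid-positive subjects and computes the required N
per arm for a fractional intervention effect f from
d = f·|mean annual change|/SD(annual change) with exact noncentral-t
two-sample power (α = 0.05, power 0.8).

## Worked example

```python
from eyosvr.synthetic_data import CohortSpec, generate_adad_cohort, generate_sporadic_cohort
from eyosvr.harmonize import fit_reference_scaler, apply_scaler
from eyosvr.cv_engine import CVConfig, run_nested_cv
from eyosvr.transfer import score_external
from eyosvr.outcome_models import stratified_validation
from eyosvr.enrichment_power import enrichment_table

adad = generate_adad_cohort(CohortSpec.adad_default(seed=11))      # 121 carriers + 54 ref
mci  = generate_sporadic_cohort(CohortSpec.sporadic_default(seed=12))  # 216 Abeta+ / 175 Abeta- / 49 ref

# scale each cohort to its own healthy reference group
ref_nc = adad.cohort.query("group == 'NC'").id
ref_cn = mci.cohort.query("group == 'CN'").id
x_adad = apply_scaler(adad.features, fit_reference_scaler(adad.features, ref_nc, "NC"))
x_mci  = apply_scaler(mci.features,  fit_reference_scaler(mci.features,  ref_cn, "CN"))

# small nested-CV design for the example (5x5 folds, one permutation)
cfg = CVConfig(k_outer=5, k_inner=5, n_outer_perms=1, n_inner_perms=1, seed=3)
res = run_nested_cv(adad.cohort, x_adad, config=cfg)
print(f"CV2 EYO prediction: r = {res.performance.r:.3f}, R2 = {res.performance.r2:.3f}")

scores = score_external(res.ensemble, x_mci)   # blind transfer, no refitting
val = stratified_validation(scores, mci.cognition, mci.cohort, include_baseline_adjusted=False)
print(val[(val.stratum == "pos") & (val.outcome == "mem")]
      [["window", "n", "beta", "t", "p", "partial_r2"]].round(3).to_string(index=False))

grid = enrichment_table({"AFGC": scores}, mci.cognition, mci.cohort, windows=(1,))
```

Output:

```
CV2 EYO prediction: r = 0.944, R2 = 0.892
  window   n   beta       t   p  partial_r2
baseline 216 -0.571 -10.136 0.0       0.327
       1 216 -0.250  -3.803 0.0       0.064
       2 216 -0.280  -4.248 0.0       0.079
       3 216 -0.421  -6.743 0.0       0.177
       4 216 -0.516  -8.840 0.0       0.270
```

Reading: the nested CV recovers the synthetic carriers' EYO almost
perfectly (the generator's biomarker noise is modest), and the transferred
score predicts memory decline in the amyloid-positive stratum with a
standardized β that strengthens from −0.25 (1-year slope, noisiest) to
−0.52 (4-year slope) — longer windows average out visit noise. The
1-year enrichment rows of `grid` show the same mechanism in trial terms: a
10% intervention effect needs 16,941 subjects per arm with no selection
but 6,220 per arm among above-median-score subjects (a 63% reduction).

## Command line

```bash
eyosvr all --out run/ --seed 7          # simulate -> harmonize -> train ->
                                        # sweep -> score -> validate -> enrich
eyosvr simulate --out sim/ --seed 7
eyosvr harmonize --features sim/adad/features.csv --cohort sim/adad/cohort.csv \
                 --reference-group NC --out scaled.csv
eyosvr train --features scaled.csv --cohort sim/adad/cohort.csv --out model/
eyosvr score --model model/ensemble --features scaled_mci.csv --out scores.csv
```

`all` writes `sweep.csv` (performance per modality subset),
`selection_probabilities.csv` (fraction of optimal CV1 models retaining
each feature), `table2_like.csv` (stratified validation regressions:
N, β, T, P, partial R²), and `table3_like.csv` (required N per arm by
strategy × window × intervention fraction, with % reduction), plus the
resolved config and a run log. Pipeline parameters live in a YAML config
(`eyosvr all --config cfg.yaml`); unknown keys are rejected.

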