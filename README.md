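# ghrspipe

A reusable pipeline for characterizing a pediatric clinical syndrome —
gastrointestinal heat retention syndrome (GHRS), a Traditional Chinese
Medicine diagnosis — from expert consensus through a diagnostic model to a
symptom–gene–pathway network.  It is written for methodologists who want
each stage of such a study as tested, composable functions rather than a
one-off analysis script:

1. **Delphi consensus screening** (`ghrspipe.delphi`).  Experts score
   candidate symptoms on a 5-point Likert scale (0–4).  Per item the
   pipeline computes the mean score x̄ⱼ, the full-mark rate fⱼ (% of
   experts giving 4), and the coefficient of variation cvⱼ = sⱼ/x̄ⱼ.  An
   item is deleted if it meets any of
   x̄ⱼ < mean(x̄) − sd(x̄), fⱼ < mean(f) − sd(f), or cvⱼ > mean(cv) + sd(cv)
   (strict inequalities).  Cronbach's α = k/(k−1)·(1 − Σσ²ⱼ/σ²ₜₒₜ)
   summarises panel consistency.
2. **Cohort description** (`ghrspipe.cohort`).  2×2 cross-tabulations of
   diagnosis against gender and age group, compared by the uncorrected
   Pearson χ² (Yates correction available behind a flag).
3. **Core-symptom selection** (`ghrspipe.lasso`).  L1-penalized logistic
   regression min −(1/n)ℓ(β₀,β) + λ‖β‖₁ (intercept unpenalized) along a
   100-point log-spaced λ grid; 10-fold stratified cross-validated
   binomial deviance; selection at **λ.1se**, the largest λ within one
   standard error of the deviance minimum.  The path solver is a
   warm-started proximal-Newton coordinate descent that certifies KKT
   stationarity at every grid point.
4. **Diagnostic model** (`ghrspipe.boost`).  A gradient-boosted tree
   ensemble (XGBoost, binary logistic) with a 70/30 stratified split,
   optional exhaustive 5-fold grid search scored by CV accuracy, an
   error-minimizing probability threshold, the five named rates
   (accuracy, sensitivity, omission diagnostic rate = FNR, specificity,
   mistake diagnosis rate = FPR), a threshold-swept ROC curve with
   trapezoid AUC, and gain-share feature importance.
5. **Network biology** (`ghrspipe.netbio`, `ghrspipe.tripartite`).  Core
   symptoms → phenotype-ontology terms (flat HPO-style lookup) → annotated
   genes → the induced STRING-style interaction subgraph (combined score
   ≥ 0.4).  Hub genes have degree ≥ 2× the median degree.  Gene-set
   enrichment uses the hypergeometric upper tail with Benjamini–Hochberg
   q-values, and the final tripartite symptom–gene–pathway network
   (inter-layer edges only) exports to GraphML/SIF/CSV.

The study's clinical and survey data are not publicly deposited, so
`ghrspipe.simulate` generates every input under known ground truth —
ordinal expert scores with planted weak items, a 660-subject cohort with a
planted 19-symptom informative support at prevalence 453/660, and
knowledge-base snapshots with planted hub genes and enriched pathways —
while `ghrspipe.fixtures` ships the published summary tables (per-item
Delphi statistics, symptom→HPO map, cohort contingency counts) for exact
reproduction tests.

## Worked example

Generate a synthetic cohort and run the selection and modelling stages:

```bash
ghrs simulate-inputs --n 660 --seed 7 --out inputs
ghrs describe --data inputs/cohort.csv
ghrs select   --data inputs/cohort.csv --seed 7 --out select_out
ghrs diagnose --data inputs/cohort.csv --seed 7 --out model_out
```

which prints

```
n=660 prevalence=0.6833
gender: counts=[[226, 225], [81, 128]] chi2=7.401 p=0.00652
age_group: counts=[[236, 215], [76, 133]] chi2=14.603 p=0.000133
lambda.1se=0.00311442: selected 24 symptoms
{
  "accuracy": 0.8585858585858586,
  "sensitivity": 0.9333333333333333,
  "omission_rate": 0.06666666666666665,
  "specificity": 0.6984126984126984,
  "mistake_rate": 0.3015873015873016,
  "auc": 0.9248677248677248,
  "tp": 126, "fn": 9, "tn": 44, "fp": 19
}
```

Reading the output: the simulated cohort has 68.3% positive diagnoses and
shows the expected enrichment of the younger age group among positives
(χ² = 14.6).  Cross-validated Lasso at λ.1se keeps 24 of 37 symptoms —
all 19 planted informative ones (the first rows of
`select_out/core_symptoms.csv` are the strongest planted effects: thick
fur, dry stool, abnormal appetite, …) plus a handful of false selections,
the known cost of the 1-SE rule when symptoms are highly predictive.  On
the held-out 30%, the boosted model reaches AUC 0.925 and 85.9% accuracy
with sensitivity 93.3%.

The full six-stage pipeline (consensus screening through the tripartite
network) runs from one configuration:

```bash
ghrs run --seed 7 --out run_dir           # or: ghrs run --config config.yaml --out run_dir
```

Each stage writes its report under `run_dir/<stage>/`, and
`run_dir/manifest.json` records every tunable and derived seed, so a rerun
is byte-identical.

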