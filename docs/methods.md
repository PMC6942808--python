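# Methods

This note documents the models and procedures implemented in `ghrspipe`,
the parameters that matter, the design decisions taken where the design
was genuinely open, and what the synthetic-data generator does and does
not emulate.

## Delphi consensus screening

Experts score each candidate symptom on the 5-point Likert scale 0–4.
Three statistics are computed per item: mean score, full-mark rate (% of
experts awarding 4), and the coefficient of variation (sample sd / mean).
Deletion cutoffs are derived across items: `score_min = mean − sd` of the
mean scores, `fullmark_min = mean − sd` of the full-mark rates, and
`cv_max = mean + sd` of the CVs.  An item is deleted when it fails any
rule, with **strict** inequalities ("lower than" / "higher than").

Conventions, chosen where either option was defensible:

- **Sample sd (n−1) everywhere**, per item and across items, matching the
  default of common statistical software.  Both denominators reproduce
  the packaged reference table's rounded summary rows.
- An item with mean 0 has an undefined CV; it is reported as NaN, never a
  silent division by zero.  Such an item always fails the mean-score rule
  whenever the cutoff is positive, so the CV rule is simply skipped.
- The packaged reference table's printed full-mark threshold (2.94)
  differs from mean − sd of its own printed summary rows (24.59 − 21.64 =
  2.95), an artifact of rounding unrounded intermediates.  Thresholds are
  therefore computed at full precision but can also be supplied directly,
  and the printed values are what the reproduction test feeds in.

Cronbach's α = k/(k−1) · (1 − Σ item variances / variance of rater
totals), variances with the n−1 denominator; a zero total variance flags
α as undefined.

## Cohort comparisons

Group comparisons are uncorrected Pearson χ² on 2×2 tables.  The
continuity correction is exposed as a flag but **off by default**:
recomputing the published statistics from their printed counts matches
0.157 (gender) and 30.918 (age) at 3 d.p. only without correction.

## Core-symptom selection (L1 logistic path, λ.1se)

The selector minimizes the penalized average negative log-likelihood

    −(1/n) Σᵢ [ yᵢηᵢ − log(1 + e^{ηᵢ}) ] + λ‖β‖₁,   ηᵢ = β₀ + xᵢᵀβ,

with the intercept unpenalized.  The default grid is 100 log-spaced
points from the analytic λ_max = maxⱼ |xⱼᵀ(y − ȳ)|/n down to λ_max·10⁻³.
Binary symptom indicators share a scale, so standardization is **off by
default**; a flag provides the standardized variant (the common default
of penalized-regression software), with coefficients always returned on
the original scale.

The solver is warm-started proximal-Newton coordinate descent (IRLS
re-weighting around cyclic soft-thresholding).  Numerical choices:

- Convergence is declared on the **true-objective KKT conditions**
  (default tolerance 5×10⁻⁷): |gradient| ≤ λ for every zero coefficient
  and gradient = −λ·sign(β) for every active one.  The inner quadratic
  subproblem is deliberately solved inexactly (10 sweeps); only the KKT
  check gates the exit, so the certificate is unconditional.
- IRLS weights are floored at 10⁻⁵ and the working response clipped
  accordingly (the glmnet convention) for stability under saturated
  probabilities.
- In the near-separable small-λ tail the optimum has very large
  coefficients and certificate-grade convergence is slow; the
  cross-validation refits and the convenience selection chain therefore
  use a looser tolerance (10⁻⁵) with capped iterations.  Selection at
  λ.1se sits mid-grid, where both settings give identical supports.
- Soft-threshold residues below 10⁻¹⁰ (possible at exactly λ_max) are
  snapped to exact zeros.

Cross-validation: 10-fold, stratified by label, seeded; per λ, held-out
per-observation binomial deviances are averaged within folds, and the
curve reports the across-fold mean and standard error.  λ_min minimizes
the mean curve; **λ.1se** is the largest λ with mean ≤ min + SE(min).
k = n falls back to leave-one-out.  A class too small to stratify raises.

## Diagnostic model

The classifier is a gradient-boosted tree ensemble (binary logistic
objective, base score 0.5, exact tree method); the ensemble fit is the
one stage delegated to xgboost — everything around it is implemented
here.  Protocol:

- **70/30 stratified train/test split**, seeded.  The split proportion is
  this package's choice; the source protocol does not state one.
- Optional exhaustive grid search over nrounds {20,40,60,80,100}, eta
  {0.1,0.2,0.3}, gamma {0,0.5,1}, max_depth {3..6}, min_child_weight
  {1,3,5}, subsample and colsample_bytree {0.55,0.75,1.0}, scored by
  5-fold stratified CV accuracy at threshold 0.5; ties prefer fewer
  rounds, then shallower trees, then grid order.  The default fitting
  parameters are the reference optimum (nrounds 60, eta 0.2, gamma 0.5,
  depth 4, min_child_weight 1, subsample 0.55, colsample 1).
- The decision threshold scans {0.01,…,0.99} for minimum
  misclassification error **on the training set** (whether the source
  tuned on train or test is unstated; train is implemented); ties resolve
  toward 0.5, then smaller.  Score ≥ threshold ⇒ positive.
- Metrics: accuracy, sensitivity (TPR), omission diagnostic rate (FNR),
  specificity (TNR), mistake diagnosis rate (FPR); the identities
  sensitivity + omission = 1 and specificity + mistake = 1 hold exactly.
  The ROC curve sweeps all unique score thresholds; the trapezoid AUC
  equals the tie-corrected Mann–Whitney concordance probability.
- Gain importance: per-feature **total** split gain, normalized to
  shares.

## Network biology

Symptom→term mapping is a flat lookup (no ontology propagation); an empty
term list is the explicit "no ontology counterpart" marker (tongue, fur
and pulse findings), while a missing symptom is a data error.  Genes are
the union over mapped terms.  The interaction subgraph is induced on the
retrieved genes keeping edges with combined score ≥ 0.4 (the
medium-confidence convention for STRING-style scores; the source states
no cutoff); isolated query genes stay as degree-0 nodes.

Topology: average degree 2E/N; average local clustering with 0 for
degree < 2 nodes; **lower median** for even node counts.  Hub rule:
degree ≥ 2 × median degree — the non-strict reading of "two times
greater", with a strict flag.  Hub selection operates on the full
retrieved-gene subgraph; the hub-induced subgraph is then re-analyzed.

Enrichment: hypergeometric upper tail P(X ≥ overlap) with population =
universe (all genes in the annotation + interaction snapshot, by
default), successes = set ∩ universe, draws = query.  Results are sorted
by raw p, filtered at p < 0.05 and truncated to the top 20, mirroring the
source's reporting; Benjamini–Hochberg q-values are computed over all
sets and reported alongside (the source applies no correction).  An
EASE-style conservative variant (overlap − 1 in the tail) is available,
off by default.

## Tripartite network

Three layers (symptom, gene, pathway), inter-layer edges only:
symptom–gene when the gene is a hub annotated to a term mapped from the
symptom; gene–pathway when the hub gene belongs to an enriched set.
Pruning order is fixed: genes lacking either side first, then edgeless
symptoms and pathways.  An empty hub set yields an empty network with a
warning.  Node/edge insertion is lexicographic, so assembly is
deterministic and idempotent.  Exports: GraphML (round-trips exactly),
SIF (`maps_to` / `member_of`), node-attribute CSV.

## Synthetic-data generator

The generator defines the study conditions; the original data are not
deposited.

**Expert scores.**  Score ~ (1−w)·Binomial(4, p) + w·Uniform{0..4} with
w = 1/(1+κ); p is solved so the mixture mean hits the per-item target μ
(clipped near the scale ends, where an exact mean is unattainable under
mixing).  The default 47-item panel uses the packaged reference means,
with the ten deleted items planted weak (κ = 2).  Rater-specific bias
(strict vs lenient experts) is deliberately not modelled — consequently
Cronbach's α of simulated panels is near 0, not the ~0.98 of real panels
whose raters differ systematically.  Passing screening tests therefore
shows the deletion rules work, not that panel consistency is emulated.

**Clinical cohort.**  n = 660 subjects; 37 binary symptoms with marginal
prevalences linearly spaced 0.6→0.2; gender ~ Bernoulli(340/660); age
group 3–6 ~ Bernoulli(316/660).  Diagnosis follows
P(positive) = σ(β₀ + Σⱼβⱼxⱼ + 1.0·1[age 3–6]) with the intercept β₀
calibrated by root-finding on the realized covariates so the expected
prevalence equals 453/660.  The planted support is the 19 core symptoms
with log-odds linearly spaced **4.0 down to 2.0** in the importance
order.  These magnitudes are large by epidemiological standards but
correct here: the reference standard being emulated is a clinician's
diagnosis made from the same symptom list, so the label is close to a
deterministic function of the informative symptoms (intrinsic AUC ≈
0.98, the regime in which a fitted model can reach the observed test AUC
of ~0.97).  The younger group carries a +5% relative symptom burden
(older group compensated), which reproduces the observed marginal
age–diagnosis association (~55% vs ~32% young among positives/negatives)
that the direct age effect alone cannot produce once symptoms saturate
the label.

What this cohort does **not** emulate: symptom–symptom correlation beyond
the age-driven burden shift, symptom severity grading, missing data, and
rater disagreement in diagnosis.  Recovery and performance results on it
demonstrate the pipeline's statistical machinery under a known truth, not
clinical generalization.

**Knowledge base.**  300 genes, 20 terms, 12 pathways by default.  The
interaction graph plants hubs (10% of genes) attached to ~30% of the
universe over a sparse Poisson(3) background, giving a heavy-tailed
degree distribution in which the 2×-median rule recovers exactly the
planted hubs.  Edge scores ~ U(0.15, 1).  Term annotations over-weight
hubs threefold so symptom queries reach them.  Half the pathways are
planted enriched: the `enrichment` parameter is the expected hub-overlap
**factor** relative to a uniform draw (default 4 ⇒ enriched sets are
~40% hub genes when hubs are 10% of the universe); sets average ~30
genes, large enough that the planted sets occupy the top significant
ranks in ≈96% of seeded runs.  Seven core symptoms map to no term,
mirroring the unmappable tongue/fur/pulse findings.

## Pipeline

Stages run in order delphi → cohort → select → model → network →
multilayer from a single YAML-able config; every tunable and seed lands
in `manifest.json`.  One master seed fans out as `seed + stage offset`
(offsets 1–6 in stage order).  Stage outputs persist under
`run/<stage>/`, and reruns with the same config are byte-identical.

## Problem sizes and runtime

The simulation studies use the study-scale defaults: 20 seeds for the
boosted-model evaluation and 50 seeds for the Lasso recovery study (each
seed = one n = 660 cohort, a full 100-λ path and a 10-fold CV curve),
about 3 minutes on one CPU; the prevalence-calibration check uses 2000
replicates (~5 s).  The full test suite runs in roughly 6 minutes.

## Known limitations

- Under the calibrated near-deterministic label regime, λ.1se admits a
  median false-selection rate of ≈0.27 across 50 seeds (sensitivity
  median 1.0): highly predictive symptoms shrink the CV-optimal penalty,
  and the 1-SE margin no longer excludes all noise features.  A bound of
  0.25 holds only under weaker effect sizes, where in turn the boosted
  model cannot reach the reference performance regime.  The recovery
  tests assert the sensitivity property and guard FSR loosely.
- The published 905-gene / 145-hub network and the specific enrichment
  term lists depend on 2019 database snapshots and are treated as
  recorded constants, not reproduction targets; only scale-free summary
  identities (e.g. average degree 2E/N = 27.1 at N = 145, E = 1964) are
  recomputed.
- No external validation cohort exists, matching the source study's own
  limitation; all performance statements are internal to the synthetic
  conditions above.
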