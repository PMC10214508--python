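# Methods

`crankms` implements an interpretable classification workflow for whole
untargeted-metabolomics feature tables: no a-priori feature selection, a
repeated-random-split benchmark of six classifier families, Shapley-value
feature ranking, and adduct-aware m/z annotation. This note records the
models, the defaults that matter, and the numerical and design choices, in
the package's own terms.

## Evaluation protocol

The cohort (n subjects × p features, binary labels with 1 = disease) is
split `n_iterations` times (default **100**) into **60 % training / 40 %
test** partitions drawn *without replacement* (Monte-Carlo cross-validation;
the field often calls the repetitions "bootstraps" even though no resampling
with replacement occurs, and we keep that vocabulary). The training size is
`floor(0.6 · n)`; the rounding rule is fixed so runs are reproducible.
Splits are unstratified by default — faithful to the protocol this package
operationalizes — with a stratified option; an unstratified split can
occasionally produce a single-class test fold, in which case class-
conditional metrics for that iteration are recorded as undefined and
excluded (with a count) from aggregation rather than poisoning the summary.

Each iteration fits the preprocessing and the classifier on the training
fold only and scores the held-out fold. Reported performance is the mean ±
one sample standard deviation (ddof = 1) of each metric over iterations.
The pooled relative standard deviation is the mean over metrics of
`sd/mean × 100 %`, skipping undefined or zero-mean metrics.

Two caveats of this protocol worth knowing:

* Iterations share subjects, so they are not independent samples; the
  spread of the 100 measurements is an honest variability band, but
  `sd/sqrt(100)` would overstate the precision of the mean.
* On label-permuted (null) data, classifiers tend to predict the training
  fold's majority class, which is *anti*-correlated with the test fold's
  majority under sampling without replacement. Mean null accuracy therefore
  sits slightly **below** 0.5 (we measure ≈ 0.45–0.48 at n = 74), even
  though the 95 % percentile interval of the per-iteration accuracies
  comfortably covers 0.5. The label-permutation control in this package is
  judged by that percentile interval.

## Preprocessing

Per training fold, in order: (1) per-feature median imputation of missing
cells (all-missing features impute to 0); (2) inverse hyperbolic sine
(`asinh`) variance stabilization; (3) per-feature standardization, with
zero-variance scales clamped to 1. The fitted state travels with the model;
test folds are transformed with training-fold statistics only, so no
information leaks (asserted by a mutation test).

`asinh` rather than plain z-scoring: MS abundances are approximately
log-normal and span decades; z-scoring the raw scale leaves extreme right
tails that dominate gradient-based learners and inflate attribution
magnitudes for high-variance null features. `asinh(x) ≈ log(2x)` for large
`x` but is defined at zero and for negative values (tables that were
already log-scaled or batch-corrected), so it needs no pseudocount.

## Classifier families

Six families behind one `train`/`predict_scores` contract, positive class =
label 1: multilayer perceptron (NN), extreme gradient boosting (XGB),
random forest (RF), logistic regression (LR), support vector machine (SVM),
and linear discriminant analysis (LDA). NN default architecture: two hidden
layers (64, 32), ReLU, Adam with learning rate 1e-3, L2 weight decay 1e-4,
at most 200 seeded epochs. The MLP regularizes with weight decay; dropout is
not part of the hyperparameter space. SVM scores are a logistic squashing of
the signed margin (PR/ROC curves need continuous scores); all other
families expose a class-1 probability. Training is seeded and
bit-reproducible for every family.

Packaged default tuning grids enumerate 120 hyperparameter combinations per
family (12 for LDA, which has few meaningful knobs). Grid search runs the
full bootstrap protocol for every candidate **on the identical split
sequence** (variance reduction, fair comparison) and selects the candidate
with the highest mean MCC; ties go to the first-enumerated candidate so
selection is total and reproducible. MCC is the selection metric because it
uses all four confusion-matrix cells and is robust to class imbalance.

## Metrics

Confusion counts use `score ≥ 0.5 ⇒ positive` (ties predict positive —
fixed convention). Accuracy, precision, sensitivity, specificity, F1 and
MCC follow the standard formulas; a zero denominator makes the metric
undefined, except MCC which is 0 by convention (keeping grid search total).
ROC AUC is the trapezoidal area under the full threshold sweep and equals
the Mann–Whitney pair statistic with ties counted ½ (property-tested
against a brute-force pair-counting oracle). PR AUC is the trapezoid over
recall of the threshold-swept curve, anchored at recall 0 with the first
swept precision — so a constant-score classifier scores the class
prevalence and a perfect one scores 1; this matches the ROC treatment and
is oracle-testable, unlike interpolated average precision.

## Shapley attribution

Attributions are interventional Shapley values of the model score: the
value of a coalition S is the expected score with features in S at the
explained subject's values and the rest drawn from a background sample
(the iteration's training fold, subsampled to `background_size`, default 8
rows). Two estimators:

* **Exact** (p ≤ 12 by default): enumerate all 2^p coalitions with full
  background averaging. Satisfies local accuracy, symmetry and the null-
  player axiom to machine precision; recovers `w_i (x_i − E[x_i])` exactly
  for linear models. This is the oracle for the sampled path.
* **Sampled**: permutation sampling. For each random feature ordering,
  features switch one by one from the background draw to the subject's
  value and each feature is credited its marginal score change. The budget
  counts model-evaluated coalitions per subject; one ordering costs p + 1
  evaluations, so `n_permutations = max(1, budget // (p + 1))` (default
  budget 128). The estimate is unbiased and *exactly* locally accurate
  (credits telescope to `f(x) − f(background draw)`), and its RMSE against
  the exact oracle decreases monotonically with budget (property-tested).

Because the preprocessing is feature-wise and monotone, coordinate masking
commutes with it; the implementation standardizes background and subjects
once and masks in the standardized space, which changes nothing
mathematically and removes the dominant constant cost.

Attributions are computed on each iteration's **test fold** (explaining
memorized training points would reward overfitting) with that iteration's
training fold as background. A feature's global SHAP score is the mean of
|attribution| over all subjects of all iterations (`mean_abs`); the
alternative |mean| reduction is exposed as `abs_mean` but cancels opposing
effects and is not the default. Regulation direction (up/down in disease)
is the sign of the abundance–label Pearson correlation, computed pairwise
over observed cells — deliberately independent of attribution sign.
Ranking is by descending score with ties broken by feature index.

## Annotation

Monoisotopic masses come from a fixed table of most-abundant-isotope masses
(C = 12 exactly, H = 1.00782503, O = 15.99491462, F = 18.99840316, …).
Supported adducts and their electron-corrected deltas: [M+H]⁺ +1.007276,
[M+Na]⁺ +22.989221, [M+H−H₂O]⁺ −17.003289, [M−H]⁻ −1.007276 Da. The
electron mass (0.000549 Da) is included because at ±20 ppm on small ions it
is borderline-material and exactness is cheap. ppm error is computed on the
m/z scale (observed vs theoretical ion m/z); matching keeps every
(compound, adduct) pair within the tolerance (default ±20 ppm), sorted by
|ppm| then compound id. The compound table is a local TSV snapshot
(id, name, formula) — no network access; a five-compound table of reported
Parkinson's-disease plasma markers ships with the package.

Mass defect is `m/z − round(m/z)`; the exogenous-compound flag fires when
the defect is more negative than −0.001 Da per 100 Da of m/z. Heavily
fluorinated synthetics (PFAS) sit far below this line (e.g. the sodiated
C21H8F28O8 ion at m/z 942.98 has defect −0.018, nine times the threshold),
while CHNO metabolites have positive defects. The constant is a documented
heuristic and is configurable.

## Synthetic cohorts

The generator emulates the shapes of small case/control metabolomics
studies: 72 subjects × 500 features by default (study tables in this regime
run ~72–274 subjects and 60–6502 features), log-normal abundances
(baseline log-mean N(7, 1.5²), log-scale noise σ = 1.0, i.e. a geometric
CV above 100 % — deliberately noisy), blocks of 50 co-regulated features
sharing a latent factor with loading √ρ (default ρ = 0.3 within blocks),
planted two-fold effects on 10 features with alternating up/down
directions, configurable class balance and uniform missingness, and one
global seed. A separate XOR-style generator plants a pure two-feature
interaction (label = sign agreement of two latent log-abundances) to probe
nonlinear learners: no single feature carries marginal signal there.

What the generator does **not** emulate: retention-time structure, isotope
and adduct peak families derived from the same analyte, batch effects and
instrument drift, intensity-dependent missingness (real MS missingness is
left-censored, not uniform), and heavy-tailed contamination. Passing the
recovery and null tests here shows the pipeline's statistical machinery is
sound under the stated model, not that any particular real cohort is
separable.

A consequence worth stating plainly: with n = 80, p = 500, two-fold
effects and σ = 1.0 (standardized per-feature effect ≈ 0.69), the planted-
biomarker recovery task is information-limited. A univariate t-test on the
true log scale — which no model-based pipeline should be expected to beat
by much at this sample size — places only about 4–8 of the 10 planted
features in its top ten across seeds, and classifiers reach bootstrap AUC
≈ 0.6–0.7. Feature recovery through a trained model degrades further,
since a weakly fitting network spreads sensitivity over memorized noise
features. The recovery suite therefore reports what the conditions allow;
near-complete recovery requires either larger cohorts, lower noise, or
larger effects.

## Problem sizes used in the shipped checks

The packaged test and acceptance runs use the cohort sizes stated above
(n = 74–80, p = 200–500, 100 iterations; attribution budget 128 with
background 8). These are the study-shaped conditions the generator
defaults encode; the XOR benchmark uses n = 160 with 8 nuisance features.

## Known limitations

* Attribution assumes feature independence in the background (interventional
  masking); strongly dependent features share credit in ways conditional
  estimators would resolve differently. Interaction (pairwise) Shapley
  values are out of scope.
* The MCC-maximizing grid search reuses one split sequence; model selection
  and performance estimation are not nested, so selected-model summaries
  carry mild selection optimism.
* Curves are per-iteration; no confidence bands or curve-level tests.
* The annotation stage resolves neither positional isomers nor
  isotope-pattern evidence; co-matching compounds are reported side by side.
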