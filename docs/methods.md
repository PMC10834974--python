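# Methods

`metabodx` implements a case-control metabolomic biomarker workflow for
targeted plasma panels: synthetic cohort generation with known ground truth,
an age-confound correction anchored on control-group stratum medians,
univariate screening with rank statistics and derived amino-acid ratios, and
a five-classifier diagnostic stage with consensus feature selection. This
note records the models, the parameters that matter, and the design choices
made where the procedure was genuinely open.

## Synthetic cohort model

Each metabolite `m` is described by a `MetaboliteSpec` with a baseline
concentration `b_m` (µmol/L, at the reference age), a linear age slope `s_m`
(µmol/L per year), a case/control effect `e_m` (log2 fold change) and a
noise coefficient of variation `cv_m`. Subject `i` of age `a_i` receives

    conc_im = max(1e-9, (b_m + s_m (a_i - a_ref)) * 2^(e_m * I_i) * nu_im)

where `I_i` = 1 for case subjects when `m` is in the configured affected
set, and `nu_im` is log-normal noise. The floor prevents non-positive
concentrations under steep negative trends; `a_ref` defaults to 40 and is
recorded in the ground-truth object.

Design choices:

* **Noise has median 1, not mean 1** (`mu = 0`,
  `sigma = sqrt(ln(1 + cv^2))`). The whole downstream pipeline summarises
  groups by medians; with median-1 noise the conditional median of a
  concentration lies exactly on the age line, which is the quantity the
  stratified-median correction estimates. (With mean-1 noise every median
  sits a factor `1/sqrt(1+cv^2)` below the line, which leaks a small
  spurious group difference into median-based statistics after correction.)
* **Ages** are drawn from a normal distribution matched by moments to the
  target (median, [Q1, Q3]) summary — mean = median, sd = IQR/1.349 —
  truncated to [18, 95]. This is the simplest family reproducing a
  median/IQR summary. Defaults: controls 34 [26–44] (n = 36), cases
  64 [58–71] (n = 76), i.e. a strong age confound between groups.
* **Group effects are multiplicative** on the age-detrended mean, keeping
  concentrations positive; additive effects would not.
* The default 87-analyte panel spans acylcarnitines, tryptophan catabolites,
  NO/urea-cycle intermediates, amino acids and methionine/cystathionine-cycle
  metabolites, with order-of-magnitude plasma baselines and small
  (0–0.8 %/yr of baseline) age slopes. Analytes known to discriminate in
  this assay carry a built-in ground-truth effect of |log2FC| = 1 with the
  observed direction; all others carry 0. Which analytes actually receive
  their effect is controlled per cohort by `CohortConfig.affected_metabolites`
  (default: the 11-analyte consensus signature).

The generator does **not** emulate: batch effects or instrument drift,
limit-of-detection censoring, between-metabolite correlation (noise is
independent across analytes), sex- or BMI-linked variation, or non-linear
age trends. Tests passing on this generator therefore demonstrate the
statistical machinery under an idealised linear-trend, independent-noise
regime, not robustness to those real-data features.

## Age-confound correction

The correction removes age-associated trends using the control group as the
reference population:

1. bin controls into 5-year age strata anchored at multiples of the width;
2. take the median concentration per metabolite per stratum;
3. fit an ordinary least-squares line through the (stratum midpoint,
   stratum median) points;
4. compute each subject's delta, `slope * (age - a_ref)`;
5. subtract the delta from the subject's absolute concentration (both
   groups).

Open parameters and our choices:

* **Reference age** (where the delta vanishes): the control group's median
  age rounded to the nearest year (`"auto"`), configurable. This anchors
  corrected values to the reference population's centre.
* **Representative age of a stratum**: the bin midpoint.
* **Minimum stratum size** 2; singleton strata are dropped with a logged
  warning (a median of one subject is noise). Metabolites left with fewer
  than two usable strata pass through uncorrected, flagged in the model.
* **Unweighted OLS** over stratum points by default — each stratum is one
  observation regardless of its membership; weighting by stratum size is
  available (`weight_by_size=True`).
* **Negative adjusted values are kept** (and counted in the log): the
  output is a statistical transform, not a concentration estimate. A
  `clip_at_zero` flag exists for consumers that need positivity.

### Known limitation: extrapolation variance

When case and control age ranges do not overlap (here: 26–44 vs 58–71), the
fitted control line must be extrapolated ~30 years. Any slope-estimation
error `e` then reappears as a spurious between-group shift of roughly
`30 * e` after correction. The stratified-median estimator on `n` controls
has slope standard error on the order of `sigma_noise / (sd_age * sqrt(n))`
(somewhat worse than subject-level OLS because sparse tail strata carry high
leverage), so with 200 controls and 20 % noise the injected spurious shift
is about 0.15–0.2 standard deviations per metabolite. In Monte-Carlo
experiments this leaves roughly a third to a half of truly null metabolites
nominally significant at alpha = 0.05 after correction — far above the
nominal level, although the correction does eliminate the systematic trend
itself (mean residual slope ~0 across replicates, and the pre-correction
false-positive rate of ~100 % collapses). Conclusion: the correction
removes the *bias* of the age confound but cannot remove the *variance* of
estimating it from a modest, age-disjoint control group; claims of
per-metabolite nominal-level false-positive control after correction do not
hold in this regime for any control-anchored linear estimator (verified
against a subject-level OLS oracle). Cohorts with overlapping age ranges or
substantially larger control groups do not have this problem.

## Univariate screen

Per metabolite (and derived ratio), on the age-adjusted table:

* **Test routing**: Student t-test iff Shapiro–Wilk p >= 0.05 in *both*
  groups, otherwise Mann–Whitney U (two-sided). Groups smaller than 3 or
  degenerate route non-parametrically with a warning.
* **Direction**: sign of (case median - control median).
* **AUC**: rank-based, `U/(n1*n2)` with midrank ties, reported
  direction-agnostically as `max(a, 1-a)` — the direction column carries
  orientation. Equivalent to a brute-force concordant-pair count (tested).
* **Youden statistic**: exhaustive scan over midpoints of adjacent sorted
  unique pooled values plus open end cutoffs, both orientations; ties in J
  broken toward higher specificity. Both `J = sens + spec - 1` (in [0, 1])
  and `sens + spec` (in [1, 2], the form some clinical reports print) are
  returned.
* **log2FC**: `log2(case median / control median)`, computed on the raw
  (pre-correction) scale because adjusted values can be negative; undefined
  medians yield NaN and are excluded from the bubble-plot file.
* **Ratios**: Fisher ratio `(Val+Ile+Leu)/(Phe+Tyr)` and GSG ratio
  `Glu/(Ser+Gly)` are appended before screening; non-positive denominators
  give missing values, logged. (The GSG numerator is glutamate, per the
  ratio's definition; glutamine is screened as an ordinary analyte.)
* **Significance filter**: p < 0.05 AND AUC > 0.65, both configurable. No
  multiple-testing correction by default — the screen reports raw
  per-metabolite p-values; Benjamini–Hochberg is available (`bh_adjust`).
* **PCA overview**: columns z-scored (concentrations span orders of
  magnitude), 2 components, Mahalanobis outliers beyond the chi-square 0.99
  quantile flagged but never removed.

## Classifier stage

Five families: logistic regression, linear SVM, decision tree, random
forest, gradient boosting (scikit-learn). Protocol:

* Stratified outer 5-fold CV (seeded). Within each training fold an
  exhaustive grid search (inner stratified 3-fold, ROC-AUC scoring) picks
  hyperparameters; the tuned model refits on the training fold and predicts
  the held-out fold. Pooled out-of-fold predictions over the whole cohort
  yield a single confusion matrix per algorithm, a cross-validated ROC and
  its AUC. This interpretation produces one full-cohort confusion matrix
  per model from a cohort of ~108 subjects without a held-out set.
* Hard calls use the model's native decision rule (0.5 on predicted
  probability; zero margin for the SVM). A Youden-optimal threshold is not
  applied by default.
* Linear models see z-scored features (scaler fitted inside each training
  fold); tree ensembles take raw features. Default grids are modest
  (4–6 combinations per family).
* Positive class: the case (IHD) label, configurable.
* No class reweighting by default (36 vs 76 imbalance left as-is).

**Feature sets**: top 15 features by |standardized coefficient| (linear
families) or impurity importance (tree families) from a tuned full-data
refit. **Consensus panel**: features ranked highly by at least 3 of the 5
models that also pass the univariate filter, ordered by model support then
univariate AUC. Importance rankings on all-noise features are unstable
across seeds; the consensus rule is only meaningful when real signal exists.

## Metrics

Closed-form confusion-matrix metrics with the identities
`recall = sensitivity`, `f1 = 2PR/(P+R)`, `youden = sens + spec - 1` held
exactly; undefined metrics (zero denominators) are reported as missing,
never as 0. Score-based AUC uses midranks and is invariant under strictly
monotone score transforms. Display rounding is half-up to 2 decimals; raw
values are kept internally.

## Problem sizes used by the test suite and acceptance script

Chosen to exercise the stated study conditions at desk scale: cohorts of
36/76 (study-sized) for pipeline and classifier checks; 200-control cohorts
for slope-recovery and confound experiments; 500 metabolite replicates for
false-positive fractions; 20 seeded replicates for consensus-recovery rates;
grid-search runs use the default modest grids.

## Numerical notes

* Degenerate inputs: identical constant groups give p = 1 and direction
  "unchanged"; constant columns min-max-normalise to zeros with a warning;
  metabolites with fewer than two usable strata bypass correction; degenerate
  PC covariance flags no outliers.
* All randomness flows from explicit integer seeds (NumPy `Generator`,
  scikit-learn `random_state`); identical inputs and seeds give bit-identical
  outputs.
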