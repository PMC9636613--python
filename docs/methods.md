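# Methods

This note records the statistical model, the estimator choices, the defaults
and their rationale, and the numerical conventions used throughout
`ordiscore`.

## 1. Model and notation

The outcome `Y` takes ordered categories `1, …, J` (1 = best, J = worst). All
predictors are categorical at modeling time (continuous variables are
discretized first). The proportional odds (cumulative logit) model is

```
logit P(Y ≤ j | x) = θ_j − η(x),    η(x) = Σ_v β_v[level_v(x)],
```

for `j = 1, …, J−1`, with `θ_1 < … < θ_{J−1}` and one coefficient per
non-reference level of each predictor (reference levels are pinned at 0). The
minus sign puts the model in the "higher η → worse outcome" orientation:
category probabilities are `P(Y = j) = F(θ_j − η) − F(θ_{j−1} − η)` with `F`
the logistic CDF, `θ_0 = −∞`, `θ_J = +∞`.

**Key assumption (proportional odds):** one coefficient vector for all J−1
cumulative splits. The per-dichotomy AUCs reported at evaluation time are the
practical check — grossly unequal AUCs across dichotomies suggest the
assumption is strained.

### Fitting

Maximum likelihood via `statsmodels` `OrderedModel(distr="logit")`, BFGS with
`gtol=1e-8`, `maxiter=500`. Monotone intercepts are enforced by the
log-increment reparameterization; starting values are the exact intercept-only
MLE (`θ_j = logit` of the cumulative outcome proportions) with zero slopes.
The package's own `pom_loglik` recomputes the log-likelihood independently of
the backend and is cross-checked in the tests against closed forms, a
Nelder-Mead grid oracle, and (for J = 2) scikit-learn's logistic regression.
Non-convergence (including separation) is reported through the `converged`
flag, never raised mid-pipeline silently: score derivation refuses a
non-converged fit.

## 2. Data preparation

- **Split:** stratified by outcome category with largest-remainder
  apportionment, so each part's category count is within one row of
  `n_category × ratio`. Default ratios 0.7/0.1/0.2. Categories with fewer
  rows than split parts are rejected with an explicit error.
- **Imputation:** continuous predictors get the **training-set** median;
  categorical predictors get an explicit `"missing"` level (missingness is
  allowed to be informative). The reference set is switchable
  (`impute_reference="validation"`) because one source describes taking
  medians on the validation set; training-set medians are the default since
  test-time imputation must not peek at evaluation data. Explicit clinical
  fill values (e.g. "0 prior visits") can be supplied per column via
  `fill_rules` and take precedence.
- **Discretization:** each continuous predictor is cut at its training-set
  quantiles, default ranks (0.05, 0.20, 0.80, 0.95) — a coarse-tail/wide-middle
  scheme that isolates the extreme ranges where risk concentrates. Quantiles
  use the linear interpolation convention `h = (n−1)p + 1`. Duplicate cutoffs
  (mass points, e.g. zero-inflated counts) are deduplicated, and any cutoff
  whose left interval is empty on the training set is dropped (merged
  rightward), so every interval is populated. Intervals are half-open:
  `"< a"`, `"[a, b)"`, `">= b"`. Numeric level names are canonicalized
  (`1` and `1.0` share a level) to keep CSV round-trips stable.

## 3. Variable ranking

A multiclass random forest (scikit-learn, `n_trees=100`) on the categorized
training set; predictors are ranked by mean-decrease-in-impurity (Gini)
importance, ties broken by column order via a stable sort. Interval-categorized
variables enter as their interval index (preserving order); other categoricals
are one-hot encoded with dummy importances summed per source variable.

**`min_leaf_fraction=0.005` (minimum leaf size = 0.5% of the sample).** With
fully grown trees at cohort sizes of 10³–10⁴, most of the total impurity
reduction happens in deep, essentially random splits and is spread almost
uniformly over all candidates, drowning real but modest signals (single-variable
mAUC ≈ 0.6). A small minimum leaf keeps importance driven by population-level
structure; with it, the preset's three signal variables rank on top from
n ≈ 5000. Set it to `1` to recover fully grown trees. `max_features=None`
additionally makes importances exactly invariant to predictor column order
(per-tree feature subsampling consumes the RNG in column order otherwise).

The forest is never used for prediction — interpretability comes from the
parametric score.

## 4. Parsimony and selection

For each k (default: all sizes up to `max_k`), the top-k ranked variables go
through the full derivation (categorize → fit → relevel → integer scores,
**unrescaled** — rank metrics are invariant to the rescaling) and the rounded
total score is evaluated on the validation set by mAUC. The `ks` argument
evaluates only chosen sizes (e.g. `[3, 22]`) when the full sweep is not
needed. The final k is the argmax of validation mAUC by default, overridable
(`final_k`, `include`, `exclude`) because the whole point of the parsimony
table is to let a human trade performance for sparsity.

## 5. Score derivation

1. **Relevel:** each predictor's reference is moved to its minimum-coefficient
   level; coefficients shift by that minimum, and the sum of the per-variable
   minima is absorbed into the intercepts. This is an **exact**
   reparameterization — identical likelihood and predicted probabilities
   (asserted to 1e-8 in tests; a literal-refit route is kept behind
   `method="refit"` and asserted to agree).
2. **Normalize and round:** all coefficients are divided by the smallest
   strictly positive coefficient across **all** selected predictors, then
   rounded half-away-from-zero. The weakest real effect therefore scores
   exactly 1 point and references score 0. Rounding half-away (not bankers')
   keeps printed tables stable and conventional.
3. **Rescale:** points are multiplied by `target / max_total` (default target
   100) and re-rounded. Rounding happens before and after rescaling — the
   first rounding defines the integer score the parsimony sweep evaluates, the
   second keeps the printed table integer; a warning is issued if rescaling
   zeroes out an entire predictor (target too small).
4. **Fine-tune:** user-supplied cutoffs (e.g. 10-year age bands) re-categorize
   the chosen variables, refit and re-derive. Overrides must be strictly
   increasing and leave no empty training interval; violations name the
   variable and interval.

## 6. Lookup table and calibration

Total scores on the training set are grouped into intervals (default: 10
equal-frequency bins, rounded up to integer cutpoints; or explicit cutpoints).
Bins left empty in training are merged rightward. Each interval stores the
training proportions of the J categories; prediction for a new case is the row
of its interval. The calibration report compares those stored (predicted)
proportions against observed proportions in a held-out set, per interval and
category. The lookup is deliberately a frequency table, not a model: it is
readable, monotone in risk when the score works, and makes no smoothness
claim.

## 7. Evaluation

- **mAUC:** the mean of the J−1 dichotomized AUCs (`Y > j` vs `Y ≤ j`),
  each computed by the tie-aware rank-sum (midrank) formula; equivalent to
  pair counting with ties worth 1/2.
- **Generalized c-index:** concordant pairs among all pairs with different
  outcome categories (ties worth 1/2), computed per category pair by rank
  sums in O(J² n log n). For J = 2 both metrics reduce to the binary AUC —
  asserted to 1e-12 in tests, alongside exact equivalence with O(n²)
  brute-force pair enumeration on 500 random instances.
- **Confidence intervals:** 95% BCa bootstrap, default B = 100 (the
  conventional budget for this application; raise `n_boot` for publication
  use). Bias correction `z0` uses the fraction of bootstrap replicates below
  the point estimate (+½ the ties), clipped to `[1/(B+1), 1−1/(B+1)]`;
  acceleration comes from the jackknife skewness (skipped if any outcome
  category has fewer than 2 cases). Resamples missing an outcome category are
  redrawn (cap 1000 attempts; >50% failures aborts with an error). A
  degenerate bootstrap distribution collapses the interval to the point with a
  warning. Coverage is verified empirically in the acceptance suite (95%
  observed over 200 simulations against a Monte-Carlo truth).

## 8. Synthetic cohort generator

`gen_cohort(GeneratorSpec)` draws covariates first (normal with optional
clipping, lognormal, zero-inflated Poisson, Bernoulli, categorical), then the
outcome from the proportional odds model with known `(θ, β)` via the inverse
cumulative-logit, then MCAR missingness. The ground truth is exportable
(`truth_json`) so recovery can be tested.

The shipped `"ehr"` preset emulates the *shape* of an ED-admission cohort:
~20 predictors styled as vitals, labs, utilization and comorbidity flags, an
~0.80/0.12/0.08 outcome mix (intercepts θ = (4.02, 5.22) fixed once by
Monte-Carlo calibration), and exactly **3 signal variables** — prior-year
inpatient visits (zero-inflated), creatinine (lognormal), age — with all other
coefficients zero. What it does **not** emulate: real between-predictor
correlation, informative missingness, non-proportional effects, or the
magnitude of real-world discrimination; it exists so that pipeline behavior
(ranking, sparsity, recovery) can be tested against a known truth, not to
imitate any particular dataset.

## 9. Numerical conventions

- All RNG is `numpy.random.default_rng` from explicit integer seeds; the
  pipeline derives stage seeds deterministically from the config seed.
- Quantiles: linear interpolation (`numpy` default).
- Rounding: half-away-from-zero everywhere a score is printed.
- Probabilities: cumulative probabilities via `expit(θ_j − η)`; category
  probabilities by first differences, clipped at [0, 1] machine boundaries
  only through the logistic form (no explicit clipping needed).
- Plots use the Agg backend; plotting failures never abort a completed run.
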