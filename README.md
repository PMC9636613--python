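# ordiscore

Automated, interpretable point-based risk scores for **ordinal outcomes**.

Clinical risk models are most useful at the bedside when they are sparse
integer checklists: a handful of variables, a few points each, summed to a
total score that maps to a predicted risk. `ordiscore` automates the
construction of such scores for outcomes with more than two **ordered**
categories (e.g. alive-discharge / prolonged stay / death), turning a raw
tabular cohort into

1. a printed scoring table (variable intervals → integer points),
2. a lookup table (total-score intervals → predicted category probabilities),
3. an honest test-set evaluation with bootstrap confidence intervals.

## The model

Let the outcome take ordered categories `1, …, J` and let `x` be the (fully
categorical, after discretization) predictor vector. The workhorse is the
**proportional odds model** (cumulative logit):

```
logit P(Y ≤ j | x) = θ_j − x'β,   j = 1, …, J−1,
```

with strictly increasing intercepts `θ_1 < … < θ_{J−1}`. Positive
coefficients push probability mass toward **higher** (worse) categories. The
pipeline is:

1. **Split** — stratified train/validation/test split (default 70/10/20),
   preserving the outcome mix in each part within one row per category.
2. **Prepare** — median imputation of continuous predictors (medians taken on
   the training set), an explicit `"missing"` level for categoricals, and
   discretization of each continuous predictor into half-open intervals at its
   training-set 5th/20th/80th/95th percentiles (duplicates and empty intervals
   pruned).
3. **Rank** — a multiclass random forest (100 trees) orders candidate
   predictors by Gini importance. The forest is only used for ranking, never
   for prediction.
4. **Parsimony** — for k = 1, 2, … the top-k variables are turned into a full
   scoring model and scored on the validation set by mAUC; the resulting
   "performance vs sparsity" table is how you pick the final variable count.
5. **Score** — fit the proportional odds model on the selected variables,
   re-reference each predictor so all coefficients are ≥ 0 (an exact
   reparameterization), divide by the smallest positive coefficient, round to
   integers, and rescale so the maximum attainable total is ≈ 100. Cutoffs can
   be fine-tuned to clinically natural values (e.g. 10-year age bands) and the
   score is re-derived.
6. **Evaluate** — test-set mean AUC over the J−1 outcome dichotomizations
   (mAUC) and Harrell's generalized c-index, each with a 95% BCa bootstrap
   interval, plus a predicted-vs-observed calibration table.

## Worked example

The package ships a synthetic EHR-like cohort generator with a known
generating model (3 true signal variables — prior-year inpatient visits,
creatinine, age — among ~20 realistic noise variables; 3-category outcome with
an ~80/12/8 mix):

```python
from ordiscore import OrdinalScoreModel, RunConfig, ehr_preset

data = ehr_preset(10000, seed=7)
config = RunConfig(seed=7, max_k=8, n_boot=100)
results = OrdinalScoreModel(data, config).fit()
print(results.summary())
```

Output (verbatim):

```
Ordinal risk score — workflow summary
====================================================
cohort: n=10000, J=3 | split (0.7, 0.1, 0.2) (seed 7)
selected variables (4): n_visits_1y, age, creatinine, triage

Variable                        Interval            Partial score
n_visits_1y                     < 2                             0
                                [2, 4)                         16
                                >= 4                           27
age                             < 31.9576                       0
                                [31.9576, 46.8752)              4
                                [46.8752, 77.2091)             18
                                [77.2091, 91.6847)             29
                                >= 91.6847                     41
creatinine                      < 44.6691                       0
                                [44.6691, 70.3988)              7
                                [70.3988, 172.999)              9
                                [172.999, 269.889)             16
                                >= 269.889                     29
triage                          P1                              4
                                P2                              0
                                P3_P4                           2
Maximum total score                                           101

Lookup table (training-set category proportions):
interval    n   p_1   p_2   p_3
    < 17  689 0.932 0.044 0.025
[17, 25)  403 0.913 0.077 0.010
[25, 27)  309 0.883 0.078 0.039
[27, 29) 1185 0.853 0.094 0.053
[29, 31)  661 0.874 0.080 0.045
[31, 36)  729 0.824 0.114 0.062
[36, 42)  916 0.791 0.142 0.067
[42, 47)  667 0.748 0.142 0.109
[47, 54)  664 0.676 0.208 0.116
   >= 54  778 0.589 0.228 0.184

Test-set evaluation:
mAUC (95% CI): 0.670 (0.645, 0.705)
Generalized c-index (95% CI): 0.660 (0.640, 0.696)
Per-dichotomy: AUC(Y>1)=0.666, AUC(Y>2)=0.674
Bootstrap: B=100, seed=7
```

The three true signal variables are recovered (plus one borderline noise
variable, `triage`, whose validation contribution is nil — drop it with
`final_k=3` or `exclude=["triage"]`). New records are scored with
`results.predict(df)` (integer totals) and `results.predict_proba(df)`
(per-category probabilities read off the lookup table);
`results.save_artifacts("outdir")` writes every table, plot and a JSON run
log.

## Command line

Every stage is also a CLI subcommand driven by a YAML config:

```bash
ordiscore generate -n 10000 --seed 7 -o cohort.csv --truth truth.json
ordiscore run -c config.yaml        # full pipeline, prints the summary above
ordiscore rank -c config.yaml       # variable ranking only
ordiscore parsimony -c config.yaml  # sparsity sweep + plot
ordiscore predict --table out/scoring_table.json --lookup out/lookup.json \
                  --cohort new_patients.csv -o predictions.csv
```

A minimal `config.yaml`:

```yaml
cohort: cohort.csv
output_dir: out
outcome: outcome
seed: 7
max_k: 8
n_boot: 100
```

Exit codes: 0 success, 1 usage/data error (bad config, missing columns),
2 unexpected internal error.

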