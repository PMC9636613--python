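# Versioned parameters of the named synthetic cohort presets.
#
# The "ehr" preset is an illustrative emergency-department-flavored cohort:
# marginals are loosely styled on typical adult ED vitals/labs/utilization, an
# imbalanced 3-category ordinal outcome (~0.80 / 0.12 / 0.08), exactly three
# signal predictors (n_visits_1y, creatinine, age), and MCAR missingness on lab
# columns. The intercepts were fixed once by Monte-Carlo calibration of the
# marginal outcome mix and are not tied to any real dataset.
ehr:
  theta: [4.02, 5.22]
  predictors:
    # --- signal ---
    - {name: n_visits_1y, kind: zip_count, params: {pi: 0.55, lam: 2.0}, coef: 0.30}
    - {name: creatinine, kind: lognormal, params: {mu: 4.70, sigma: 0.55}, coef: 0.004}
    - {name: age, kind: normal, params: {mu: 62.0, sd: 18.0, lo: 18.0, hi: 105.0}, coef: 0.028}
    # --- noise (true coefficient exactly 0) ---
    - {name: pulse, kind: normal, params: {mu: 83.0, sd: 17.0, lo: 30.0, hi: 220.0}}
    - {name: respiration, kind: normal, params: {mu: 17.8, sd: 1.8, lo: 8.0, hi: 60.0}}
    - {name: spo2, kind: normal, params: {mu: 98.0, sd: 2.5, lo: 60.0, hi: 100.0}}
    - {name: sbp, kind: normal, params: {mu: 134.0, sd: 25.0, lo: 50.0, hi: 260.0}}
    - {name: dbp, kind: normal, params: {mu: 71.0, sd: 13.0, lo: 20.0, hi: 160.0}}
    - {name: bicarbonate, kind: normal, params: {mu: 22.8, sd: 3.8, lo: 5.0, hi: 45.0}}
    - {name: sodium, kind: normal, params: {mu: 135.0, sd: 5.0, lo: 100.0, hi: 170.0}}
    - {name: potassium, kind: normal, params: {mu: 4.16, sd: 0.7, lo: 1.5, hi: 9.0}}
    - {name: ed_los, kind: lognormal, params: {mu: 0.92, sigma: 0.55}}
    - {name: boarding_time, kind: lognormal, params: {mu: 1.35, sigma: 0.7}}
    - {name: consult_wait, kind: lognormal, params: {mu: -0.5, sigma: 0.7}}
    - {name: prev_los, kind: zip_count, params: {pi: 0.5, lam: 4.0}}
    - {name: n_surgery, kind: zip_count, params: {pi: 0.85, lam: 1.2}}
    - {name: n_icu, kind: zip_count, params: {pi: 0.97, lam: 1.0}}
    - {name: mi, kind: bernoulli, params: {p: 0.06}}
    - {name: chf, kind: bernoulli, params: {p: 0.11}}
    - {name: renal, kind: bernoulli, params: {p: 0.20}}
    - {name: metastatic_cancer, kind: bernoulli, params: {p: 0.08}}
    - {name: triage, kind: categorical, params: {levels: [P1, P2, P3_P4], probs: [0.19, 0.56, 0.25]},
       coef: {P1: 0.0, P2: 0.0, P3_P4: 0.0}}
  missing_rate:
    creatinine: 0.05
    bicarbonate: 0.05
    sodium: 0.05
    potassium: 0.05
    spo2: 0.02
    pulse: 0.02
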