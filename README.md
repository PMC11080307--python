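# parasurv

Parametric Weibull survival modelling for right-censored cohort data, with
companion Cox diagnostics and censoring-aware prediction metrics.

## Who this is for

Biostatisticians and clinical researchers analysing overall survival in
cohorts like endometrial cancer — follow-up time in days, a death
indicator, and a handful of clinical (age, tumour grade) plus continuous
imaging/radiomic covariates — who want more than a Cox hazard ratio: a
fully parametric model that also reports how much a covariate *stretches
or compresses survival time*, and an honest out-of-sample comparison of
the two modelling strategies.

## The model

The Weibull regression model is written two equivalent ways. On the
accelerated-failure-time (AFT) scale,

    log T = mu + alpha' z + sigma * eps,     eps ~ standard extreme value,

and on the proportional-hazards (PH) scale the same model has hazard

    h(t | z) = gamma * lambda * t^(gamma-1) * exp(beta' z),

with the exact correspondences `gamma = 1/sigma`, `lambda = exp(-mu/sigma)`,
`beta = -alpha/sigma`. The Weibull family is the only survival model that
is simultaneously PH and AFT, so each coefficient yields both

* a **hazard ratio** `HR = exp(beta_i)` — relative instantaneous event
  rate per unit covariate increase, and
* an **event time ratio** `ETR = exp(-beta_i / gamma)` (the acceleration
  factor) — the multiplicative change in the time at which any fixed
  survival percentile is reached. `ETR < 1` exactly when `HR > 1`.

Fitting maximizes the right-censored log-likelihood
`sum_events log h(t_i|z_i) - sum_all H(t_i|z_i)` over the unconstrained
parameterization `(log gamma, log lambda, beta)`; the inverse observed
information feeds delta-method confidence intervals on every scale.

Around the core model the package provides:

* `cox`: the semiparametric Cox fit (Efron/Breslow ties, Newton-Raphson),
  Schoenfeld and martingale residuals, and the Grambsch-Therneau score
  test of proportional hazards (the statistic behind R's `cox.zph`);
* `distfit`: two-parameter Weibull / lognormal / log-logistic maximum
  likelihood on the uncensored death times, Kolmogorov-Smirnov statistic,
  Q-Q and P-P plot coordinates;
* `metrics`: IPCW (reverse-Kaplan-Meier weighted) Brier score and
  cumulative/dynamic time-dependent AUC curves, null-model reference, and
  subject-level bootstrap bands;
* `simulate`: a seeded generator of synthetic cohorts with the study's
  structure (age, grade 1-3, correlated radiomic-like features, Weibull
  event times, administrative + dropout censoring), so the entire pipeline
  is testable without any patient data;
* `pipeline` / CLI: the end-to-end train/test analysis with z-score
  normalization by training statistics and a structured, reproducible
  report.

## Worked example

```python
import parasurv as ps

config = ps.PipelineConfig(
    simulation=ps.study_spec(n_subjects=491),   # 411/80 train/test split
    simulation_seed=11, bootstrap_seed=5, bootstrap_B=10,
)
report = ps.run_pipeline(config)
w = report.report["weibull"]
print(f"shape gamma = {w['gamma']:.4f}   scale lambda = {w['lambda']:.4e}")
print(report.effects[["covariate", "weibull_coef", "weibull_hr",
                      "weibull_etr", "cox_coef", "cox_hr"]].round(4))
```

prints

```
shape gamma = 1.1372   scale lambda = 5.8677e-06
covariate  weibull_coef  weibull_hr  weibull_etr  cox_coef  cox_hr
      age        0.7780      2.1772       0.5045    0.7725  2.1652
   grade2        0.5262      1.6925       0.6296    0.5152  1.6740
   grade3        2.3279     10.2567       0.1291    2.3054 10.0283
    rad_1        0.1708      1.1863       0.8605    0.1615  1.1753
    rad_2        0.6425      1.9012       0.5684    0.6423  1.9008
    rad_3        0.3101      1.3636       0.7613    0.3108  1.3645
PH global chi2 = 7.19 (df=6), p = 0.304
test-set mean Brier: weibull 0.1169  cox 0.1170  null 0.1215
test-set mean AUC:   weibull 0.7796  cox 0.7796
```

Reading the output: grade 3 disease multiplies the hazard by ~10 and
shrinks survival time to ~13% of the grade-1 reference (ETR 0.129); the
Weibull and Cox coefficient columns agree closely because the generative
model satisfies proportional hazards; the PH test finds no violation
(p = 0.30); and on the held-out 80 subjects the parametric model matches
or slightly beats the Cox model on both metrics while both clearly beat
the covariate-free null.

The same analysis runs from the shell:

```bash
parasurv simulate --config spec.yaml --out cohort.csv --seed 17
parasurv distfit  --in cohort.csv --out fits.json
parasurv run      --config analysis.yaml
```

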