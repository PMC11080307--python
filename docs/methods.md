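# Methods

## Model and likelihood

The core model is Weibull regression for right-censored survival times,
used in its proportional-hazards form

    h(t | z) = gamma * lambda * t^(gamma-1) * exp(beta' z),
    H(t | z) = lambda * exp(beta' z) * t^gamma,
    S(t | z) = exp(-H(t | z)),

with shape `gamma > 0`, scale `lambda > 0` (units day^-gamma; all times
are in days), and PH-scale coefficients `beta`. The equivalent AFT form
`log T = mu + alpha'z + sigma*eps` (extreme-value error) is maintained on
every fitted model through the exact maps `gamma = 1/sigma`,
`lambda = exp(-mu/sigma)`, `beta = -alpha/sigma`; both parameterizations
are populated and the round trip is an identity.

The fit maximizes the censored log-likelihood
`sum_i d_i log h(t_i|z_i) - sum_i H(t_i|z_i)` over the unconstrained
internal parameterization `(log gamma, log lambda, beta)`. Starting values
are the exponential warm start (`gamma = 1`,
`lambda = events / total follow-up`, `beta = 0`); optimization is BFGS with
the analytic gradient followed by Newton polishing (numeric Hessian of the
analytic gradient) until the gradient max-norm falls below 1e-8, with a
hard failure above 1e-6. The covariance is the inverse observed
information at the optimum, on the internal scale.

### Effect scales

* Hazard ratio `HR = exp(beta_i)`; Wald CI on the log scale.
* Event time ratio `ETR = exp(-beta_i / gamma)`; the CI uses the delta
  method on `(log gamma, beta_i)` with the joint covariance block. When
  `gamma = 1` the ETR is exactly `1/HR`.
* Percentile times `t_p = [-log(p) / (lambda e^{beta'z})]^(1/gamma)`.
  Here `p` is a **survival probability**: `t_p` satisfies `S(t_p|z) = p`
  (conventions vary between sources, so the implementation asserts this
  identity). Ratios of percentile times between covariate vectors equal
  `exp(beta'(z0 - z1)/gamma)` and are independent of `p`.

Confidence level defaults to 0.95 everywhere.

## Cox model and diagnostics

The companion Cox model is fitted by Newton-Raphson on the partial
likelihood, Efron tie handling by default (Breslow available; the two
coincide on tie-free data). Convergence requires score max-norm < 1e-8;
step-halving uses a slack proportional to |loglik| so floating-point
rounding near the optimum cannot stall the iteration. The baseline
cumulative hazard is the Breslow estimator centered at covariate means
(Efron-adjusted denominators when ties are handled by Efron).

Schoenfeld residuals are the event-wise differences between the observed
covariate and the (Efron-weighted, within tied groups) risk-set mean;
their columns sum to zero at the MLE by the score equation. Scaled
residuals follow the `n_events * cov(beta) * r + beta` convention. The
proportional-hazards test is the Grambsch-Therneau score test for zero
slope of the scaled residuals on a transform of event time
(KM transform `g(t) = 1 - KM(t)` by default; identity and rank offered):

    chi2_j      = d * (V S)_j^2 / (V_jj * sum x^2)        (df 1)
    chi2_global = d * S' V S / sum x^2                    (df p)

with `S = sum_k x_k s_k`, `x` the centered transform, `V = cov(beta)`,
`d` the event count. This matches lifelines' implementation to seven
decimals in the tests; its calibration (type-I error near 0.05, high
power against a sign-flipping coefficient) is verified by simulation
rather than asserted.

Martingale residuals use Breslow baseline increments even under Efron tie
handling: that choice makes the residuals sum to exactly zero at the MLE
(the documented invariant), and the two estimators agree whenever times
are tie-free.

## Marginal distribution assessment

The deaths-only subset (censored rows excluded by design) is fitted with
two-parameter Weibull, lognormal and log-logistic MLEs; the lognormal MLE
is closed form with the n-denominator standard deviation, so a degenerate
point-mass sample yields scale 0. Agreement is summarized by the
Kolmogorov-Smirnov statistic with the asymptotic p-value. Because the
parameters were estimated from the same sample, that p-value is
anti-conservative (the Lilliefors effect); a parametric-bootstrap mode
(refit per resample) is provided for calibrated inference. Plotting
positions for Q-Q/P-P coordinates are `(i - 0.5)/n`.

## Prediction metrics

Censoring is handled by inverse-probability-of-censoring weighting with
the reverse Kaplan-Meier estimate `G(t)` (censorings as events; at a tied
time the death precedes the censoring, so deaths at `t` remain at risk for
the censoring process). The Brier curve uses case weights `1/G(T_i-)`
(left limit) and control weights `1/G(t)`; the AUC is the
cumulative-cases/dynamic-controls weighted concordance with ties in the
risk score counted 1/2. Grid times where `G` has reached zero raise an
error instructing truncation; grid times with no cases or no controls are
flagged undefined rather than dropped. The default evaluation grid is the
0.05-0.95 event-time quantiles in 20 steps, truncated where `G <= 0.1`.

The null reference model predicts the marginal KM curve for every subject
(its AUC is undefined: a constant score carries no ranking). Bootstrap
bands resample subjects with replacement, refit per replicate, and report
pointwise mean +/- sd; zero-event resamples are redrawn (capped at 10B).
The default B = 10 keeps the report cheap; for real inference B >= 200 is
recommended.

## Synthetic cohort generator

The generator emulates the structure of the endometrial-cancer cohort the
defaults are modelled on: 491 subjects (411 train / 80 test), age at
diagnosis 66.72 +/- 11.43 years (normal truncated to [18, 100]), tumour
grade 1/2/3 with probabilities 123/130/158 out of 411, and three
radiomic-like features drawn from a standard multivariate normal with
exchangeable correlation 0.3 (a plausibility choice; real radiomic
features are correlated but no correlation is published). Event times are
drawn by inverse transform from the Weibull PH hazard with the published
training estimates as generative truth: shape 0.9929, scale 3.0447e-05
per day^gamma, coefficients (0.5620, 0.2038, 1.9327, 0.2676, 0.4012,
0.1636) for (age, grade2, grade3, rad_1..rad_3).

Two scale conventions matter:

* The **linear predictor** uses age standardized by the spec's own
  mean/sd, so coefficients are per-SD — the scale on which such models
  are reported after z-score normalization. `to_model_scale()` returns a
  cohort on exactly this scale for parameter-recovery checks.
* The **emitted covariate table** stays raw (years, grade levels), because
  normalization with training statistics is the pipeline's job.

Censoring is the minimum of an administrative cutoff and an (off by
default) exponential dropout time, independent of the event time — the
source cohort describes censoring as "alive at end of study", i.e.
administrative, but the true mechanism is unknown; this is an assumption.
The default cutoff of 2559.1 days was solved once by bisection
(`calibrate_admin_time`, common-random-numbers Monte-Carlo at n = 2e6) so
that the expected event fraction matches the reported 95/411 ≈ 23.1%
deaths.

Randomness flows from a single integer seed through named sub-streams
(covariates / event times / censoring), so adding covariates never
perturbs event-time draws and identical specs give bitwise-identical
cohorts.

What the generator does **not** emulate: real radiomic feature
distributions (heavy tails, blockwise correlation), covariate-dependent
censoring, non-Weibull baseline hazards, measurement error, or cohort
heterogeneity over the accrual period. Passing recovery and calibration
tests therefore demonstrates correctness of the estimators under the
assumed model, not robustness on real clinical data.

## Pipeline

Order of operations: drop rows with any missing value (logged) →
encode grade as two indicators (grade 1 reference) → z-score every
numeric covariate with training mean/sd (n-1 denominator) and apply the
same statistics to the test set → Cox fit + PH test + residuals →
Weibull fit + HR/ETR + parametric-vs-Nelson-Aalen cumulative-hazard check
(compared through the covariate-averaged parametric survival, up to the
0.9 follow-up quantile) → marginal distribution fits on training deaths →
Brier/AUC curves for Weibull, Cox and null on train and test → JSON/CSV
report. The report contains no timestamps and serializes with sorted
keys, so a rerun with the same config and seeds is byte-identical.

## Problem sizes and test design

Simulation-based checks use sizes chosen to keep the full suite fast while
leaving comfortable statistical margins: one shared n = 5000 cohort for
point recovery (3-SE criterion), 200 replicates at n = 800 for CI
coverage (pooled over the six coefficients; the pooled estimate has ~0.7%
Monte-Carlo error versus ~1.5% per-coefficient), 500 replicates at
n = 400 for PH-test type-I error, 200 replicates at n = 800 for power,
and 100 replicates of the 411/80 split for the out-of-sample Brier
comparison. Brute-force oracles (grid-search partial likelihood,
risk-set loops, double-loop IPCW sums, product-limit products) are
re-implemented independently inside the tests and compared at 1e-12 or
grid resolution.

## Known limitations

* Single-event right-censored data only: no recurrent events, competing
  risks, stratification, time-varying covariates, or penalized fits
  (covariate selection is deliberately out of scope — the pipeline takes
  an explicit covariate list).
* Only the Weibull family is implemented for covariate-adjusted fitting;
  Gamma/normal/modified-Weibull alternatives are not.
* The plain KS p-value ignores parameter estimation (see above).
* Cox survival predictions are carried flat beyond the last event time
  (with a warning); parametric predictions extrapolate smoothly and
  should be preferred out of range.
* The PH test relies on the average-information approximation of the
  classic score statistic; strongly non-proportional censoring patterns
  can make it conservative.
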