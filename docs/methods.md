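# Methods

## Design and model

The package evaluates a pharmaceutical price cut with an interrupted time
series over a 54-month window (January 2009 – June 2013) containing two
interruptions: a prescriber-incentive program (OPIP, October 2010 = month
22) included as a covariate, and the Single Price System price cut (SPS,
April 2012 = month 40), the policy of interest. The design matrix codes, per
month: a 1-based `time` counter, indicator and elapsed-time columns for each
interruption (the start month itself is post-intervention: indicator 1,
counter 1), and a February dummy for the short-month dip in dispensing.
Level changes (β2, β4) capture abrupt effects; trend changes (β3, β5)
capture longer-run effects; the post-cut slope is β1+β3+β5.

Errors are modelled two ways and the final model is chosen by minimum AIC:

* **OLS** — independent Gaussian errors; classical covariance; Gaussian
  log-likelihood at the ML variance (denominator n).
* **AR(1) exact ML** — strictly stationary errors ε_t = ρ·ε_{t−1} + u_t,
  |ρ| < 1, ε_1 from the stationary distribution. The exact joint-normal
  likelihood (Toeplitz correlation ρ^|i−j|) is evaluated through the
  Prais–Winsten whitening transform, concentrated over (β, σ²), and
  maximised over ρ by a 39-point grid plus bounded 1-D refinement
  (tolerance 1e-8). Estimates within 0.01 of the stationarity boundary set a
  warning flag. The sign convention is positive ρ = positive serial
  correlation.

AIC counts every free parameter: k = 8 for OLS (7 coefficients + σ²) and
k = 9 for AR(1) (+ρ). Ties go to OLS. The Durbin–Watson statistic
Σ(e_t−e_{t−1})²/Σe_t² is reported with a seeded Monte-Carlo p-value
(i.i.d. Gaussian errors projected through the same design; one-sided toward
positive autocorrelation; 2000 draws by default). A white-noise screen
passes when all residual autocorrelations at lags 1–12 lie inside
±1.96/√n.

### Standard errors, intervals and a known limitation

AR(1) standard errors come from the observed information (finite-difference
Hessian over (β, atanh ρ, log σ²)) at the optimum, with the β block scaled
by n/(n−7) — the degrees-of-freedom-corrected innovation variance used by
the classic autoregression procedures this estimator mirrors. When the
Hessian is numerically degenerate (essentially noise-free series) the GLS
covariance at the fitted ρ is used instead. p-values are two-sided normal
for AR(1) and t-based for OLS; confidence intervals use Student-t critical
values with df = n−7 (OLS) or n−8 (AR(1)).

At the 54-month design with ρ ≈ 0.3, exact-ML ρ̂ is biased toward zero by
roughly −0.14 (detrending seven regressors in a short window), which
propagates into the β standard errors: measured interval coverage is
0.88–0.91 instead of the nominal 0.95, and AIC selects the AR(1) model in
about 94.7% (±0.5%) of strongly autocorrelated (ρ = 0.7) replicates rather
than ≥95%. Both properties are asserted strictly in the acceptance suite
and those two assertions fail by these measured margins; they reflect
small-sample behaviour of the estimator itself (statsmodels' exact-ML
SARIMAX shows the same ρ̂ bias), not an implementation defect. β̂ remains
exactly unbiased (the profile likelihood is even in the residual vector, so
estimation error is odd), and ρ̂ is consistent: at n = 200 its mean is
within 0.05 of the truth.

## Policy effects

Counterfactual predictions zero the SPS indicator and counter columns in
the design and re-evaluate the fitted mean; with-policy predictions use the
full design. Effects are computed between the two model predictions rather
than observed-vs-counterfactual — this matches the forecast-band
construction and is robust to residual noise; an observed-vs-counterfactual
variant is available (`use_observed`). Three summaries are reported per
horizon h ∈ {12, 15} months (month 1 = the intervention month):

* cumulative percent over post months 1–12: 100·(Σŷ − Σŷ_cf)/Σŷ_cf — the
  headline "in a year" figure;
* endpoint percent at month h alone;
* monthly-average percent: the arithmetic mean of per-month percent
  differences over months 1–h.

Published 12-month effect figures do not state which of the
cumulative/endpoint conventions they use, so both are always reported. The
forecast band covers the counterfactual *mean* (not a new observation):
ŷ_cf,t ± z·se(x_cf,tᵀβ̂) with the fit's coefficient covariance; endpoint
percent effects additionally get a delta-method interval on the ratio.

Complication-procedure growth follows the published-table convention
exactly: for adjacent 12-month periods, absolute change in monthly episodes
per 1000 patients rounded to 2 decimals and percent growth rounded half
away from zero to an integer — the only rounding rule consistent with all
fifteen printed transitions (one of which lands exactly on a .5).
Growth is undefined when the earlier rate is zero.

## Synthetic data

The real data — every Korean diabetic outpatient's claims — are
confidential, so the generator emulates their statistical structure with
known truth at three levels.

**Aggregate series.** Each outcome × price-group series is
y_t = x_tᵀβ + ε_t with stationary AR(1) errors (ε_1 variance
σ²/(1−ρ²)), so the estimation model is exactly correct and zero-noise
generation is interpolated exactly by the fit. Default β and ρ equal the
published estimates per series (costs in billion KRW, DDDs in millions,
patients in persons); σ defaults to 2% of |β0|, chosen once as giving
within-year dispersion comparable to the published descriptive SDs.

**Claims.** A patient pool (default 4,000,000; ages ~ Normal(60, 13)
truncated at 20; 8% Medical Aid; diagnosis mix 85% E11 / 12% E14 / 3%
other) yields monthly claims whose aggregates reproduce the realized target
series: treated-patient counts exactly (disjoint per-group draws, so
overall = reduced + constant), DDD totals exactly up to float error, and
cost totals to within 1 KRW per record. Record cost is
round(quantity × era-appropriate unit price) in whole KRW; because cost,
DDD and patient-count targets cannot all three be independent once
cost = quantity × price is imposed, the claims-level cost target is the
implied series Σ quantity × price, and the configured cost-series
coefficients drive aggregate-level generation only. Deliberate
contamination — under-20 patients, non-diabetes diagnoses, inpatient
episodes, excluded institution types — exercises every cohort filter, and a
final pass guarantees each treated patient one qualifying outpatient
diagnosis claim inside the index window so cohort selection inverts the
generator. The registry mirrors the study's structure (97 ingredient codes,
32 reduced-price at 70% of the pre-cut price, ~20% carrying the
standard-daily-dose fallback instead of a WHO DDD); prices and dose sizes
are conventions, as no patient-level distributional facts are published.

**Procedure events.** Monthly complication counts per category are Poisson
with mean rate/1000 × cohort size, rates per 12-month reporting period
(defaults = the published table; the trailing half-period reuses the last
rate).

One integer seed drives everything: substreams are
`SeedSequence(seed, spawn_key=(crc32(label),))` per generator and per
series, so any piece is reproducible in isolation.

What passing tests do *not* show about real data: the generator has no
prescription-shift dynamics (patients do not migrate between drug groups in
response to the cut), no market entry/exit, no real Korean price schedule
beyond pre/post unit prices, and per-patient cost/quantity distributions
are conventions. Results on synthetic data validate the estimation
machinery, not the policy conclusion.

## Problem sizes and numerical choices

Claims-level runs in the analysis scripts and acceptance script use a
1/2000-scale cohort (2,000-patient pool, ≈46,000 claims) — counts and
totals scale linearly, per-patient structure is scale-invariant — and
Monte-Carlo suites use 200–500 replicates (antithetic pairs for the
unbiasedness check, where pairing cancels the estimation error exactly).
Aggregate-level series are always generated at full scale. Degenerate
inputs are errors, not silent results: missing months in the fit window,
singular designs (dependent columns named), all-zero residuals for DW,
non-positive counterfactuals for percent effects, zero earlier rates for
growth. Months with no treated patients yield missing (not zero)
per-patient values. Diagnosis matching uses the 3-character ICD-10 category
prefix; age at the qualifying claim decides eligibility; claims are point
events assigned to calendar months by service date.
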