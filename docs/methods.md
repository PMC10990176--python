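# Methods

## The scientific question and the models

After cardiac hospitalization, does fear of movement (kinesiophobia) drive
down physical activity, does low activity feed fear, or are the two simply
different kinds of processes?  The package frames this as a two-process
panel problem: kinesiophobia measured by the TSK-NL Heart questionnaire
(13 items scored 1–4, totals 13–52) and total physical activity (PA,
minutes/day across light/moderate/heavy MET categories), each observed at
4 waves — weeks 1, 3, 6 and 12 after discharge.

**Random-intercept cross-lagged panel model (RI-CLPM).**  Each observed
score is decomposed as

    y_it = mu_t + b_i + w_it

where `mu_t` is the wave-specific grand mean, `b_i` a time-invariant
random intercept (stable between-person difference, modelled as a latent
variable whose loadings on the repeated measures are all fixed to 1) and
`w_it` the within-person deviation.  The within components follow a lagged
structure between consecutive waves,

    w_i,t+1 = A_t w_it + e_i,t+1,

with the diagonal of `A_t` the autoregressive (carry-over) effects and the
off-diagonal the cross-lagged (cross-over) effects; `e` is multivariate
normal.  The default free-parameter inventory — 2 random-intercept
variances + their covariance, wave-1 within (co)variances (3), per
transition 4 lagged paths and 2 residual variances (18 in all over 3
transitions), and 8 means — totals 32 free parameters against
8·11/2 = 44 sample moments, hence **df = 12**.  The within-wave dynamic
residual covariances are fixed to zero by default; this is the unique
standard variant consistent with df = 12 (the textbook variant with those
3 covariances free gives df = 9 and is available via
`RiclpmOptions(dynamic_residual_covariances=True)`).

**Trait + autoregressive alternative.**  Kinesiophobia as a pure random
intercept (trait: latent variable with loadings 1, free per-wave residual
variances, no autoregression) and PA as an observed AR(1) chain (free
wave-1 variance, 3 autoregressive paths, 3 residual variances, no random
intercept), plus a free concurrent TSK-residual–PA covariance at each wave
so that an association, if any, has a parameter to show up in.  24 free
parameters, hence **df = 20**.  The concurrent covariances are the
reconstruction consistent with that df; removing them
(`RiclpmOptions(ri_covariance=False)`) raises df to 24.

The free-parameter inventories behind both df values are reverse-engineered
reconstructions: the published tables print only the df, not the parameter
list.  `riclpm models list` prints each builder's inventory.

## Estimation

Models are expressed in the reticular action model (RAM) form: directed
coefficient matrix `A`, exogenous covariance `S`, intercepts `M`,
selection `F`; implied moments are `Sigma = F T S T' F'` and
`mu = F T M` with `T = (I − A)^{-1}`.  Maximum likelihood minimizes the
Wishart discrepancy

    F_ML = ln|Sigma| − ln|S_obs| + tr(S_obs Sigma^{-1}) − p
           + (xbar − mu)' Sigma^{-1} (xbar − mu)

and reports `T = (n − 1) F_ML` against chi-square (an `n` multiplier is
switchable for other software conventions; the sample covariance uses the
unbiased n−1 divisor).  Numerical choices:

- **Start values**: observed means for free means; 0 for paths and
  covariances; each free variance loading on an observed node receives an
  equal share of that node's sample variance.
- **Optimizer**: BFGS on scale-normalized parameters with 3-point numeric
  gradients; convergence at gradient norm < 1e-6 (accepted below 1e-5).
  Non-positive-definite implied covariances return a penalty value, which
  the line search treats as a rejected step.
- **Boundary (Heywood) handling**: unconstrained quasi-Newton can diverge
  along a ridge where a latent variance goes negative without bound.  On a
  stall the fit is retried under variance ≥ 0 bounds (L-BFGS-B).  Boundary
  solutions are reported with the variance at 0, flagged non-converged
  rather than chased: SEs are then computed from the Hessian restricted to
  the non-boundary directions (conditional on the constraint; the bounded
  variance's own SE is undefined).  Up to 5 seeded, jittered restarts
  (1 within multiple-imputation loops, where boundary cases do not recover
  by jittering).
- **SEs** from the inverse central-difference Hessian of `(n−1)F/2`,
  eigenvalue-clipped against indefiniteness.
- **Fit indices**: baseline = independence model (closed form,
  `Sigma = diag(S)`, df = p(p+3)/2 − 2p = 28 for p = 8);
  CFI = 1 − max(T−df,0)/max(T_b−df_b, T−df, 0) and
  TLI = ((T_b/df_b) − (T/df))/((T_b/df_b) − 1), reported raw and
  truncated; df = 0 flags them undefined.
- **Standardization**: each path is scaled by implied SD(source)/SD(target)
  with SDs extended to latent nodes; 95% CIs by the delta method through
  the full parameter covariance.  Standardized betas are labelled small
  (< 0.30), moderate (0.30–0.49) or large (≥ 0.50) on absolute value; the
  conventional printed bands leave a gap at (0.29, 0.30), closed here by
  assigning [0, 0.30) to "small".

## Missing data

- **Little's MCAR test**: EM estimates of the joint mean/covariance
  (convergence at log-likelihood change < 1e-8 or 500 sweeps; singular
  pattern blocks ridge-regularized with a warning), then
  `d² = Σ_j n_j (ȳ_j − μ̂_j)' Σ̂_j^{-1} (ȳ_j − μ̂_j)` over missingness
  patterns, df = Σ_j p_j − p.  One pattern (complete data) flags the test
  undefined.
- **FCS-MI**: chained equations with a Bayesian normal linear kernel
  (residual variance from the scaled inverse chi-square posterior,
  coefficients from their normal posterior, posterior-predictive draws for
  the missing cells), m = 20 imputations × 10 cycle iterations by default.
  The published analysis names only "FCS-MI in SPSS"; m, iterations and
  the predictor set are not stated anywhere, so these defaults are package
  choices, printed into every run log.
- **Rubin pooling**: pooled estimate = mean; total variance
  `W̄ + (1 + 1/m)B`; small-sample df `(m−1)(1 + W̄/((1+1/m)B))²`;
  t-based intervals (normal when B = 0).
- **MI model fits**: the model is fitted to each completed dataset and
  coefficient rows are pooled by Rubin's rules; chi-square/CFI/TLI are
  reported as the across-imputation mean with spread, explicitly labelled —
  there is no consensus pooling rule for ML fit statistics.  Raw-data input
  uses complete rows only; full-information ML for partially missing rows
  is out of scope (the workflow imputes first).

## Measurement construction

MET cut-points: sedentary ≤ 1.5 < light < 3 ≤ moderate ≤ 6 < heavy.  The
printed category labels ("<3", "3–6", ">6") do not state boundary
ownership; moderate is taken as the closed interval so the three labels
partition the line.  The sedentary cut (default 1.5 MET, configurable)
exists because otherwise sleep would count as light activity; whether the
original device counts sub-sedentary time inside "light" is unknowable
from the published material, so it is a config default, not a fact.
Daily minutes per category = epoch count × epoch length; weekly value =
mean over available days of the 7-day window (week w = days 7(w−1)+1..7w
after discharge — the window arithmetic is a package choice); waves take
weeks 1, 3, 6, 12; a week with zero wearable days is missing, never zero.
The PA variable entering the models is the total
(light + moderate + heavy) minutes/day.

## The synthetic cohort

No patient data were ever deposited, so every analysis runs on synthetic
cohorts whose generating truth mirrors the published summary statistics:

- Cohort flow 188 assessed → 2 died → 37 non-completers → 149 completers →
  33 non-wearers → **116 analysis patients**.
- Grand means: TSK 27.43 → 25.00 (middle waves interpolated: 26.6, 25.8 —
  unprinted); total PA 82.09 / 127.50 / 127.00 / 123.85 min/day.
- Spreads matched to the printed IQRs (SD ≈ IQR/1.349), split between
  random intercept and within component (TSK 50/50, PA 40/60) in rough
  agreement with the published standardized loadings.
- Lagged coefficients: the published standardized estimates converted to
  the unstandardized scale at stationary within variances; residual
  variances then chosen to hold the within variances stationary.
- Wave-level TSK missingness 22.8 / 24.8 / 28.2 / 36.2% (MCAR);
  accelerometer missingness 14.4% applied at epoch level — the published
  figure does not say whether it is epoch-, day- or week-level, so the
  rate is exposed at epoch level and flagged as a choice.
- TSK totals are generated continuously, rounded and clamped to 13..52,
  then disaggregated into 13 items (1..4) that sum exactly to the total;
  PA totals are floored at 0.  Both truncations are part of the synthetic
  measurement model and slightly compress the tails.
- Epoch streams: day targets interpolate the wave targets across weeks and
  are quantized to the epoch grid (1-minute default), so
  aggregation recovers them exactly at epoch resolution; per-category
  splits follow per-wave Dirichlet draws centred on the published category
  medians.  Wear period 90 days by default; a 14-day desk preset keeps
  tests fast.

What the generator does **not** emulate: covariate effects (age, sex,
cardiac-rehabilitation initiation) on the latent processes, non-normal or
skewed activity distributions (real heavy-PA minutes are strongly
right-skewed), wear-time compliance patterns, and MAR/MNAR dropout.
Passing tests therefore certify the estimators' behaviour under the
model's own assumptions — calibration, coverage, recovery — not the
robustness of the published findings to violations of those assumptions.

## Calibration studies (what the test suite computes)

Problem sizes are chosen to give each study adequate Monte-Carlo
resolution: moment-oracle equivalence at n = 200,000 for 5 random
admissible truths; parameter recovery at n = 10,000; chi-square
calibration over 200 replicates at n = 500; Little's-test type-I error
over 500 replicates at n = 300 and MAR power over 50 replicates at
n = 1000; imputation coverage over 200 replicates of a bivariate design at
n = 2000; and the no-cross-over replication property at the study's own
n = 116 over 100 replicates.  Entrywise 3-SE oracle comparisons use a
replication rule: an exceedance must reproduce with the same sign in an
independent draw, since with ~220 simultaneous 3-sigma comparisons
isolated exceedances are the expected behaviour of a correct
implementation, while a genuine mismatch is systematic.

## Known limitations

- At n = 116 with 23–36% questionnaire missingness the RI-CLPM is fragile:
  multiple-imputation refits regularly produce boundary (Heywood)
  solutions in which a random-intercept or within variance collapses to
  zero and paths out of the collapsed component become empirically
  unidentified (huge conditional SEs).  The package reports these honestly
  (non-convergence counts, flagged fits) rather than hiding them; this
  fragility is a documented property of the design, not of the optimizer.
- Waves are treated as discrete occasions; the unequal spacing (1→3→6→12
  weeks) is not reparameterized in continuous time.
- The imputation kernel is normal-linear only; categorical/ordinal kernels
  and predictive mean matching are out of scope.
- No robust/scaled chi-square variants, bootstrap CIs or multi-group
  models.
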