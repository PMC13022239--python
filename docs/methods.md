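# Methods

This note documents the statistical model, the synthetic-data generator, the
numerical choices, and the known limitations of `pigwater`. It states no
empirical result that the test suite or `scripts/acceptance.py` does not
itself compute.

## Model and parameterisation

The observable is hourly water consumption per pig, $X_t$ in mL/pig/h, on a
complete hourly grid per barn × batch. The model is **regression with
subset-ARMA errors**:

$$X_t = \mu + x_t'\eta + e_t, \qquad
\phi(B)\, e_t = \vartheta(B)\, \varepsilon_t, \qquad
\varepsilon_t \sim \text{i.i.d. } N(0, \sigma^2),$$

where $x_t$ stacks the four first harmonics of the 24-h cycle
($\sin/\cos(2\pi k h_t/24)$, $k = 1\ldots4$, phase 0 at local midnight),
outside temperature (°C), ammonia (ppm) and fattening day (integer days since
batch start, 1-based), and $\phi, \vartheta$ are lag polynomials whose
coefficients are non-zero only on the *active* lag sets of a `ModelSpec`
(the final model uses $\{1, 2, 22, 23, 24\}$ on both sides, i.e. a subset
ARMAX(24, 24) with all other lags fixed to zero).

An alternative convention puts $x_t'\eta$ inside the ARMA recursion, which
rescales $\eta$ by the rational lag transfer function $\vartheta(B)/\phi(B)$.
We implement regression-with-ARMA-errors because it is the contract of the
standard ARIMA-with-regressors routines practitioners use, and because the
coefficient tables are then directly interpretable as steady-state effects.
Exogenous terms enter contemporaneously only (one coefficient per covariate).

## Estimation

1. **Starting values (CSS).** $\mu, \eta$ start at OLS of $X_t$ on
   $(1, x_t)$; all ARMA coefficients start at zero. The conditional sum of
   squares — pre-sample innovations set to zero, the first $p$ observations
   conditioned on, hours with missing values (own or lagged) skipped — is
   minimised by L-BFGS-B. For a pure AR model this objective coincides with
   least squares on lagged values, which the tests exploit as an oracle.
2. **Exact likelihood.** The ARMA error is cast in the Harvey state-space
   form with state dimension $r = \max(p, q+1)$; the Gaussian likelihood is
   evaluated by the Kalman/innovations recursion started from the stationary
   state distribution (solved by a doubling iteration of the Lyapunov
   equation). The companion structure of the transition matrix makes each
   step $O(r^2)$; the recursion is compiled with numba. Missing hours take
   a prediction step without an update, so cleaned-to-missing records need no
   imputation. $\sigma^2$ is concentrated out of the likelihood.
3. **Optimisation.** The concentrated negative log-likelihood is minimised by
   L-BFGS-B with an explicit central-difference gradient (relative step
   1e-6), followed by a Nelder-Mead polish and, if the polish moved, a second
   quasi-Newton round; the best point wins and the reported log-likelihood is
   never below the CSS start. The accurate gradient matters: with near-unit
   roots the profile likelihood has extremely flat directions in which a
   forward-difference gradient is pure noise.
4. **Stationarity handling.** The search is unconstrained, with a penalty
   added whenever any AR or MA root modulus falls to ≤ 1.001; final estimates
   are validated by an explicit root check and flagged when within one part
   in $10^4$ of that margin.
5. **Standard errors.** Inverse of the central-difference observed
   information of the concentrated likelihood (relative step 1e-4). Wald
   $z = \hat\beta/\text{SE}$ with two-sided standard-normal p-values (the
   asymptotic test; no small-sample correction).
6. **Pruning and selection.** `prune_coefficients` drops all terms with
   $p > \alpha$ (default 0.05) in a single pass and the caller refits; an
   iterate-until-stable variant exists but is off by default.
   `information_criteria` uses $k$ = free coefficients + 1 (for $\sigma^2$)
   and $n$ = observations entering the likelihood; AICc is reported as
   undefined (NaN) when $n \le k+1$. `select_order` fits an arbitrary grid
   and breaks ties toward fewer parameters, then lower MA order.

## Forecasting and diagnostics

$h$-step forecasts propagate the filtered state without updates; the point
forecast is the regression mean plus the predicted error-process mean, the
variance is $\sigma^2 P_{11}$, and intervals are Gaussian
($\pm z_{0.975}\,\text{SE}$ at 95%), ignoring parameter-estimation
uncertainty as is standard for ARIMA-type prediction. Two modes are provided
for held-out series: rolling one-step-ahead (the default; its errors on the
training sample are exactly the model innovations) and fixed-origin
multi-step with known future covariates. The standardized forecast error is
(actual − forecast)/forecast SE. RMSE is computed over non-missing pairs.

Residual checks: Ljung-Box with df = number of lags (24 by default, matching
common reporting practice for this analysis; a `df_adjust` option subtracts
fitted ARMA parameters instead), Shapiro-Wilk on a seeded subsample of at
most 5000 residuals (the statistic's customary validity bound), residual
moments and residual-vs-fitted pairs exported for plotting. Descriptive
analyses: per-hour profiles, optionally split into hot (May–October) and cold
(November–April) calendar months; a one-way fixed-effects ANOVA of
consumption on hour of day; and the harmonic-overlay decomposition of the
fitted daily cycle.

## Synthetic-data generator

Real data of this kind are proprietary, so the generator is a first-class,
tested component with two deliberately separate modes. (The published
fattening-day coefficient is negative while the descriptive daily trend
rises; rather than force one generator to satisfy both, estimator validation
and farm realism are split.)

**Model-truth mode** simulates the exact model above with the published
coefficient tables as ground truth, unit innovation SD (the paper-scale
$\sigma^2$ was never published), an intercept of 5 (ditto), and a burn-in of
2000 steps. The AR polynomial of the published coefficients has minimum root
modulus 1.00205 — just outside the unit circle — so the generator verifies
all root moduli exceed 1.001 before trusting long simulations and reports the
offending modulus otherwise. Covariates are generated on natural scales
(°C, ppm, days). The linear predictor can go negative; this mode validates
the estimator and is not meant to look like a farm.

**Farm-realistic mode** builds hourly consumption as
*trend × diurnal shape × noise*:

- **Trend:** daily totals rise linearly from a solved day-1 level to a
  plateau of 8.05 L/pig/day at fattening day 75 and stay flat, with the
  day-1 level chosen so the mean over days 1–7 is exactly 2.35 L/pig/day;
  the final 3 days ramp linearly to zero as the barn empties.
- **Diurnal shape:** a fixed 24-vector (fraction of daily intake per clock
  hour) with a morning bump inside 8–12 h, a dominant peak at 16–17 h,
  drinking onset around 5–6 h and near-zero overnight flow.
- **Noise:** multiplicative lognormal AR(1) with unit mean (hourly log-SD
  0.10, persistence 0.6). The scale reflects a ~690-pig barn aggregate:
  individual-pig variation largely averages out, leaving ~10% hourly and a
  few percent day-to-day dispersion in the total.

Pig counts start at 660–730 animals and thin by independent uniform-in-time
deaths with total probability 3.39% per batch. The environment model is an
annual temperature sinusoid (daily resolution, peak mid-July) plus a diurnal
sinusoid (peak 15:00) plus AR(1) noise; ammonia couples negatively to
temperature (summer ventilation) with a floor at zero; humidity and CO₂ are
generated as simple noisy baselines and are deliberately not used by the
final model.

Raw readings split each hour into three exact 20-min sub-readings (Dirichlet
proportions; cadence jitter is out of scope) at barn-level volumes, plus
cooling/cleaning records at 7.4% of total observations. `corrupt_readings`
injects four fault kinds on disjoint sets of hours — negative spikes (hour
total made negative), extreme values (hour total pushed above 10 L/pig/h by
construction), consecutive-hour sums (one hour doubled into its predecessor
and zeroed) and missing sub-readings — and returns a ledger of every faulted
position, so cleaning can be scored exactly. Everything is deterministic
given the seed, which is recorded in the provenance of all outputs.

**What the generator does *not* emulate:** heat-wave excursions and other
non-sinusoidal weather; feeding-schedule effects; disease outbreaks or any
anomaly other than sensor faults; drift or miscalibration of flowmeters;
between-barn heterogeneity in the diurnal shape; covariate effects on
consumption in farm-realistic mode (the trend and shape are fixed). Tests
that pass on generator output therefore demonstrate correctness of the
algorithms under the stated model, not fitness of the model for any
particular real farm.

## Cleaning rules

Cooling/cleaning usage records are dropped first (reading level). Sub-hourly
drinking volumes are summed into left-closed clock-hour bins; an hour with a
missing sub-reading, or absent from the interior of the record, is flagged
missing. Hours without a positive pig count are dropped as unpaired. Barn
totals are divided by the pig count and converted to mL/pig/h. Values
strictly above 10,000 mL/pig/h ("exceeding 10 L/pig/h"; a value equal to the
threshold is retained) or below zero are set to missing. Removed records
become missing hours rather than being deleted, preserving the hourly grid
for the state-space likelihood, and the CleaningReport attributes every
record/hour to exactly one rule. The consecutive-hour-sum fault is *not*
detectable by these rules (the doubled hour stays far below 10 L/pig/h at
realistic consumption levels) and is knowingly left in the data; the fault
ledger lets tests quantify exactly this. Daylight-saving handling keeps
wall-clock labels; duplicated or absent clock hours surface as duplicates
(an error) or missing hours.

Train/test partitioning holds out the last batch per barn by default (one
batch per barn in the test set; 6 × 5 batches → 24 train / 6 test); an
all-train policy exists for single-batch barns.

## Numerical choices and degenerate inputs

- Root-margin 1.001 for both the simulator check and the optimisation
  penalty; the stationary covariance doubling iterates to a 1e-14 relative
  increment and diverges loudly for non-stationary inputs.
- Constant (zero-variance) series are rejected by `css_estimate`/`fit_ml`;
  constant residuals are rejected by the autocorrelation-based tests.
- ACF uses denominator $n$; PACF uses Durbin-Levinson; correlogram bands are
  $\pm 1.96/\sqrt{n}$.
- Ties in order selection break toward fewer free parameters, then lower
  MA order.
- Pruning everything returns a white-noise-with-intercept specification with
  a warning rather than an error.
- The pipeline concatenates training series with a 48-h missing gap between
  batches so the filter treats them as approximately independent segments;
  with strongly persistent errors the segments are not exactly independent,
  which is acceptable for the small pipeline runs this mode is meant for.
  (Estimator-validation tests always fit single series.)

## Problem sizes used by the test suite

Simulation-based checks are sized to be decisive yet cheap: parameter
recovery refits 6 series of 1512 h of the full subset model; the likelihood
oracle uses 20 random specifications at n = 40 against a dense
multivariate-normal density; coverage uses 500 simulated continuations;
test-calibration checks use 1000 replicates of length 500; pruning and order
selection majorities use 20–100 replicates of lengths 500–1000. The pipeline
tests run 1 barn × 2 batches of 4 weeks with a lag-1 model.

## Known limitations

- Identification near the unit circle: the published AR polynomial has roots
  of modulus ≈ 1.002–1.005 *at the diurnal harmonic frequencies* (periods
  ≈ 23.8, 12.0, 8.0 h). The error process then nearly annihilates exactly
  the harmonic regressors (and the low-frequency trend), so those
  coefficients are weakly identified: their reported standard errors are
  large, and at moderate series lengths joint maximum likelihood shows a
  visible finite-sample deviation for the 24-h sine amplitude and the
  fattening-day slope. This is a property of the model at those parameter
  values, not of the implementation — an independent state-space
  implementation (statsmodels SARIMAX with the same zero constraints)
  produces the same behaviour, with a likelihood no better than ours.
- Prediction intervals ignore parameter-estimation uncertainty and assume
  Gaussian innovations; on farm-realistic data (multiplicative lognormal
  noise) empirical coverage falls a few points below nominal and residual
  normality tests reject, as the worked example shows.
- Future covariates must be supplied for multi-step forecasting; forecasting
  the covariates themselves is out of scope, as are rolling re-estimation
  and alerting rules on standardized errors.
- One model is fitted per run; pooling across barns is by concatenation, not
  by hierarchical modelling.
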