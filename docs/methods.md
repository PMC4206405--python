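# Methods

## Model

The package fits a first-order multivariate autoregressive model to
natural-log abundances of p taxa with q contemporaneous environmental
covariates:

    X_t = A + B X_{t-1} + C U_t + E_t,   E_t ~ N(0, diag(sigma2)).

Assumptions: dynamics are locally linear on the log scale over the fitted
window; process errors are independent across taxa (diagonal Σ) and over
time; covariates act contemporaneously (C·U_t, not lagged); observation
error is not modelled (no state-space layer), so estimated interaction
strengths absorb sampling noise.  Elements of B and C are interpreted as
per-capita effects; the diagonal of B measures density dependence (values
nearer 0 = stronger density dependence, values near 1 = near-random-walk
dynamics).

## Estimation

Conditional least squares: each taxon's equation is an independent OLS
regression of x_{i,t} on an intercept, the mask-included lagged abundances
and the mask-included covariates, solved by `numpy.linalg.lstsq`.  The
inclusion mask pins a-priori excluded coefficients to exactly zero and
removes them from the design (they never consume degrees of freedom).
Missing values are handled by per-equation casewise deletion: a regression
row is dropped for an equation only when that equation's response or one
of its predictors is missing, which keeps the maximum usable data per
equation and is exact under CLS because the equations share no parameters.
Process-error variances default to SSE/n (maximum-likelihood flavour);
an SSE/(n−k) divisor is available via `sigma_divisor="n-k"`.

Degenerate designs (fewer usable rows than coefficients + 1, or rank
deficiency from a constant/collinear predictor — e.g. a taxon absent for a
whole window) raise an error naming the offending equation; the moving-
window driver records such windows as explicit failures rather than
dropping them or rescuing them with ridge penalties.

Stability is λ = the spectral radius of B (largest eigenvalue modulus,
complex pairs via their modulus, since the return rate to the stationary
distribution is governed by the modulus).  No stationarity constraint is
imposed during fitting: windows with λ̂ > 1 are reported as estimated.

## Moving windows

For a series of n steps and window size W, responses run over
[2, W+1], [3, W+2], …, [n−W+1, n] (1-based), each window also consuming
the observation before its first response for the lag; hence n − W windows
of W+1 observations each, advancing one step at a time, labelled by their
END time.  The default W = 84 suits monthly data (a whole number of years,
above the ~75-step threshold where estimation accuracy degrades sharply on
the 4-guild configuration; see the window-size experiment).  Covariates
are standardized once over the full series, never per window, so
coefficient trajectories reflect changing responses rather than changing
covariate scaling.

## Bootstrap intervals

Per window, a fixed-design parametric bootstrap: each replicate panel is
rebuilt by iterating the fitted recursion from the window's first fully
observed state with the observed covariates and random process errors,
then refitted by CLS; percentile bounds of the replicate coefficients at
(1−level)/2 and 1−(1−level)/2 form the interval (order statistics via the
inverted-CDF quantile).  Defaults: 2000 replicates, 95% level.

Error draws default to resampling whole rows of the window's fitted
residuals with replacement, rescaled by sqrt(n/(n−k)) per equation because
raw least-squares residuals understate the error variance by the fitted
degrees of freedom (Davison–Hinkley rescaling).  Row-wise resampling
preserves the cross-taxon error dependence seen in the data and is robust
to the heavy one-sided residual tails zero-inflated taxa produce; a
Gaussian mode (independent draws with the fitted variances) is available.
Intervals are plain percentile, not bias-corrected: the simplest
defensible choice, at a known cost — for strongly autocorrelated equations
(self-effect ≈ 0.8 at W = 84) the O(1/W) downward small-sample bias of the
autoregressive estimate propagates into the replicates, and measured
per-window coverage of a nominal 95% interval drops to roughly 78–80%
(it is 92–96% for moderate coefficients).  The regime-shift validation
therefore pools coverage across both regimes' windows.

A coefficient is called significant when its interval excludes zero.
Replicate fits that fail are counted and reported; a window whose
replicates fail more than half the time aborts with a run error.

## Preprocessing

Irregular raw samples are aggregated to monthly means on a contiguous
month index (unsampled months stay missing).  Abundances are
log-transformed; zeros (months when a taxon was not observed) are handled
by a recorded, switchable policy — default ln(x + δ) with per-taxon
δ = half the smallest positive observed value, applied only where zeros
occur; alternatives: treat zeros as missing, or a fixed δ.  Temperature is
split into a 12-level calendar-month climatology ("season", expanded over
time then standardized) and standardized anomalies, so seasonal forcing
and short-term/trend signals get separate coefficients; phosphorus enters
as the standardized raw series (not log-transformed).  Standardization
uses the sample SD (n−1) over observed entries of the full series.

## Diagnostics

Every window × taxon residual vector is screened with the Shapiro–Wilk
test (scipy's Royston implementation) at a Bonferroni-corrected level.
The multiplicity universe m is configurable and printed: windows × taxa
(pooled convention) or windows (per-taxon convention); rejection counts
are reported per taxon.  The residual–data screen correlates each
equation's residuals with that equation's own predictor series inside the
window — the natural CLS misfit check; because OLS residuals are
orthogonal to their own within-window predictors by construction, a
well-specified fit yields essentially 0% significant correlations, and any
excess flags structure the model missed (an all-pairs mode is available).
QQ exports use plotting positions (i − 0.5)/n.

## The synthetic lake fixture

`lake_washington_fixture` generates the 4-guild, 396-month panel used
throughout validation: diatoms/greens (DG), non-daphnid crustaceans (NDC),
*Daphnia* and *Oscillatoria*, with covariates season, temperature anomaly
and total phosphorus (phosphorus a-priori excluded from the zooplankton
equations; the NDC→DG link excluded; 29 coefficients per window).

Three phases with breakpoints at steps 120 and 180:

* **Eutrophic** (steps 0–119): *Oscillatoria* abundant, strong negative
  effects of *Oscillatoria* on *Daphnia* (−0.40) and on DG (−0.35);
  *Daphnia* rare.  Self-effects (0.70, 0.85, 0.60, 0.80) reflect the
  strong autocorrelation of monthly plankton guild data; λ = 0.85.
* **Transition** (120–179): weakest density dependence (NDC and
  *Oscillatoria* self-effects 1.0), λ = 1.0 — the least stable phase.
* **Clear-water** (180–395): *Daphnia* dominant with negative effects on
  DG (−0.30) and NDC (−0.20); *Oscillatoria* collapsed (self-effect 0.3);
  λ = 0.6.

Covariates: a sinusoidal temperature climatology (11 ± 6.5 °C) with unit-SD
anomalies and a slow warming drift, and an exponentially declining
phosphorus trend (65 → 20 µg/L) with noise.  Seasonal forcing coefficients
are O(0.3–0.5) in standardized units, making all guilds strongly seasonal.
Zero inflation is produced by censoring abundances below per-taxon
detection floors (Daphnia e^−0.8, Oscillatoria e^−0.3 organisms per unit
volume), after which the standard offset log policy applies; this makes
*Daphnia* mostly unobserved early and *Oscillatoria* mostly unobserved
late.

What the fixture does **not** emulate: observation/sampling error on
non-zero counts; zeros arise from dynamical censoring rather than
sampling, so censored months are well predicted by the fitted model and
the resulting residual non-normality is milder than real monitoring data
shows (Shapiro–Wilk rejections at strict Bonferroni levels are few and
seed-dependent, although uncorrected rejection rates for the zero-inflated
taxa are clearly elevated).  Passing tests on the fixture therefore
validate estimation, windowing, bootstrap and the qualitative
regime-shift signatures — not the full messiness of field data.

## Validation experiments and problem sizes

* **Estimator oracle**: on ~100 random small instances (p ≤ 3, T ≤ 12,
  random masks), CLS matches a brute-force BFGS minimizer of each
  equation's SSE to 1e-6.
* **Window-size experiment**: 50 replicate stationary panels from the
  fixture's eutrophic regime (T = 400, covariates regenerated per
  replicate), each fitted at the series end with W ∈ {48, 84}.  Worst
  per-coefficient median |error| at W = 84 is ≈ 0.07 (well under 0.15);
  mean off-diagonal RMSE at W = 48 exceeds W = 84 by ≈ 1.5–1.7×,
  reproducing the sharp accuracy loss below ~75 steps that motivates
  W = 84.
* **Bootstrap coverage**: 200 outer replicates × 500 bootstrap replicates
  on a 2-taxon model (T = 100): coverage of the nominal-95% interval for a
  moderate self-effect lands in the low 90s.
* **Regime shift**: 10 replicate two-regime series (T = 300, b11 switching
  0.8 → 0.3 at step 150, W = 84, every 4th window bootstrapped with 200
  replicates): pooled pre/post CI recovery ≥ 80%, and the λ̂ trajectory
  crosses the midpoint between the two regimes' analytic spectral radii.
* **Transition bias**: windows straddling a breakpoint estimate a value
  between the two regimes' truths, traversing monotonically on average —
  estimates during transitions should be read as regime mixtures.
* **Scalar closed forms**: simulated stationary mean and variance match
  a/(1−b) and σ²/(1−b²) within 2% at T = 50,000.

These sizes (50 replicates, 200×500 bootstrap, every-4th-window CI checks)
were chosen to keep Monte-Carlo error comfortably inside the asserted
margins while the whole suite stays desk-scale.

## Known limitations

* No observation-error (state-space) layer; no lags beyond one; diagonal Σ.
* Percentile bootstrap intervals undercover for near-unit-root
  self-effects at W ≈ 84 (see above); bias-corrected intervals were
  deliberately not implemented.
* Estimates from windows overlapping a regime transition are biased toward
  a mixture of regimes; the bias shrinks as W grows relative to the
  transition period, and users should interpret such windows accordingly.
* The window count n − W and the ≥ W+1-observation requirement mean short
  series support few windows; W below ~75 monthly steps trades accuracy
  for responsiveness on 4-guild problems.
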