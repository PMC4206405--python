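# mwmar — moving-window multivariate autoregressive community modelling

`mwmar` detects **time-varying species interactions, environmental effects
and community stability** in multispecies abundance time series.  It is
aimed at ecologists with long monitoring records (plankton counts, fish
surveys, rodent trapping grids) who suspect that the interaction structure
of their community — not just its abundances — changed over the record,
for example after a nutrient regime shift or a species invasion.

## The model

The community is described by a first-order multivariate autoregressive
(MAR(1), equivalently VAR(1)) model on natural-log abundances.  For *p*
interacting taxa and *q* environmental covariates,

```
X_t = A + B X_{t-1} + C U_t + E_t,      E_t ~ N(0, diag(Σ))
```

where **X**_t is the p-vector of log abundances, **A** the intrinsic
growth constants, **B** the p×p interaction matrix (diagonal entries =
density dependence; off-diagonal = inter-taxon per-capita effects), **C**
the p×q covariate-effect matrix, **U**_t the standardized covariates and
**E**_t independent process errors.  Coefficients are estimated by
**conditional least squares** (equation-by-equation OLS of each taxon on
its lagged predictors), with a-priori exclusion masks pinning biologically
impossible links to zero.  Community stability is summarised by
**λ = the spectral radius of B**: small λ means rapid return to the
stationary distribution after a perturbation; λ > 1 flags an unstable
system.

The *moving-window* extension refits the model in every length-W
contiguous window of the series (a series of n steps yields n − W
windows), turning every coefficient and λ into a time series of its own.
Percentile bootstrap confidence intervals (replicate panels rebuilt from
the fitted model with resampled residuals, then refitted) give per-window
significance calls.  Residual diagnostics — Shapiro–Wilk normality scans
with Bonferroni correction and residual–predictor correlation screens —
assess model adequacy window by window.

## Worked example

The built-in synthetic fixture emulates a deep temperate lake whose
plankton community flips from a cyanobacteria-dominated eutrophic regime
to a grazer-dominated clear-water regime (4 guilds × 396 monthly steps,
seasonal temperature forcing, declining phosphorus, detection-floor
zero-inflation):

```python
from mwmar import MovingWindowMAR
from mwmar.simulate import lake_washington_fixture

panel, covars, mask, truth = lake_washington_fixture(seed=42)
res = MovingWindowMAR(panel, covars, mask, window=84).fit()
print(res.summary())

ser = res.coefficient_series("Daphnia", "Oscillatoria")
print("Osc -> Daphnia, window ends 1969-1971: %.2f" % ser["1969-01":"1971-12"].mean())
print("Osc -> Daphnia, window ends 1990-1994: %.2f" % ser["1990-01":].mean())
```

prints

```
Moving-window MAR(1) trajectory
  window size: 84   windows: 312   failed: 0
  lambda range: 0.5696 .. 1.0013   (peak at 1975-10)
  windows with lambda > 1: 1
Osc -> Daphnia, window ends 1969-1971: -0.22
Osc -> Daphnia, window ends 1990-1994: 0.08
```

Reading this: 312 overlapping 7-year windows were fitted over the 33-year
record.  Stability was worst (λ ≈ 1.0, the edge of instability) in windows
ending in late 1975 — while the community was mid-transition — and best
(λ ≈ 0.57) once the clear-water regime settled.  The estimated inhibitory
effect of the cyanobacterium on the grazer is clearly negative (−0.22 per
unit log abundance) while the two overlap, and indistinguishable from
zero at the end of the record, after the cyanobacterium's collapse.

The same analysis runs from the shell on any wide monthly CSV:

```bash
mwmar simulate --seed 42 --out sim/          # write the fixture as CSV
mwmar mwfit sim/panel.csv --window 84 --nboot 2000 --out run/
mwmar diagnose sim/panel.csv --window 84 --out diag/
mwmar fit sim/panel.csv                      # whole-series baseline MAR
```

`mwfit` writes a long-format trajectory table (one row per estimated
coefficient per window, keyed by window end time, with bootstrap CI and
significance columns plus a λ row) and a metadata JSON capturing the full
configuration and seeds.

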