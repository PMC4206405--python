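"""Parametric bootstrap confidence intervals for MAR coefficients.

Each replicate rebuilds a synthetic panel from the fitted model — iterating
X_t = A + B X_{t-1} + C U_t + E_t forward from the window's first observed
state with the observed covariates (a fixed-design bootstrap, mirroring the
one-step conditional-least-squares structure) and random process errors —
then refits by CLS.  Intervals are percentile bounds of the replicate
coefficient sample.

Two error-draw modes are supported: resampling the fitted residual rows
with replacement (default; robust to the heavy one-sided residual tails
zero-inflated taxa produce) and independent Gaussian draws with the fitted
variances sigma2.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from .errors import InputError, RunError
from .model import MARFit, MARParams, _cls_fit
from .panels import AbundancePanel, CovariatePanel, MaskSpec

__all__ = ["CoefficientIntervals", "bootstrap_intervals", "is_significant"]


@dataclass
class CoefficientIntervals:
    """Percentile bootstrap bounds for the estimated coefficients.

    ``a_lo``/``a_hi`` etc. are shaped like the corresponding parameter
    arrays; mask-excluded cells are NaN (no interval exists for a pinned
    coefficient).
    """

    level: float
    a_lo: np.ndarray
    a_hi: np.ndarray
    b_lo: np.ndarray
    b_hi: np.ndarray
    c_lo: np.ndarray
    c_hi: np.ndarray
    n_boot: int
    seed: int
    n_failed: int = 0

    def contains_b(self, i: int, j: int, value: float) -> bool:
        return bool(self.b_lo[i, j] <= value <= self.b_hi[i, j])


def is_significant(lo: float, hi: float) -> bool:
    """A coefficient is significant iff its interval excludes zero."""
    if lo > hi:
        raise InputError(f"interval lower bound {lo} exceeds upper bound {hi}")
    return not (lo <= 0.0 <= hi)


def _simulate_fixed_design(
    params: MARParams,
    x0: np.ndarray,
    u: Optional[np.ndarray],
    errors: np.ndarray,
) -> np.ndarray:
    """Iterate the fitted recursion from x0 with supplied error rows."""
    T = errors.shape[0] + 1
    p = params.p
    x = np.empty((T, p))
    x[0] = x0
    for t in range(1, T):
        mu = params.a + params.b @ x[t - 1]
        if params.q:
            mu = mu + params.c @ u[t]
        x[t] = mu + errors[t - 1]
    return x


def bootstrap_intervals(
    fit: MARFit,
    y: AbundancePanel,
    u: Optional[CovariatePanel],
    mask: MaskSpec,
    n_boot: int = 2000,
    level: float = 0.95,
    seed: int = 0,
    error_draws: str = "resample",
) -> CoefficientIntervals:
    """Bootstrap CIs for every estimated coefficient of a window fit.

    Parameters
    ----------
    error_draws : {"resample", "gaussian"}
        "resample" draws whole residual rows with replacement (rows where
        any equation's residual is missing are excluded); "gaussian" draws
        independent normals with the fitted variances.

    Identical seeds give identical intervals.  Replicate fits that fail
    (degenerate resampled designs) are counted; more than 50% failures
    aborts with a run error.
    """
    if n_boot < 1:
        raise InputError("n_boot must be >= 1")
    if not 0 < level < 1:
        raise InputError("level must be in (0, 1)")
    if error_draws not in ("resample", "gaussian"):
        raise InputError(f"unknown error_draws mode {error_draws!r}")

    rng = np.random.default_rng(seed)
    params = fit.params
    p, q = params.p, params.q
    xobs = y.values
    uvals = None if u is None else u.values
    T = xobs.shape[0]

    # first fully observed state starts the recursion
    finite = np.all(np.isfinite(xobs), axis=1)
    if not finite.any():
        raise RunError("no fully observed state to start bootstrap replicates")
    x0 = xobs[np.argmax(finite)]

    resid = fit.residuals.to_numpy()
    complete = resid[np.all(np.isfinite(resid), axis=1)]
    if error_draws == "resample" and complete.shape[0] == 0:
        raise RunError("no complete residual rows available for resampling")
    # rescale raw least-squares residuals by sqrt(n / (n - k)) per equation:
    # they underestimate the process-error variance by the fitted degrees of
    # freedom, and resampling them unscaled gives too-narrow intervals
    k_per_eq = 1 + mask.b_mask.sum(axis=1) + mask.c_mask.sum(axis=1)
    infl = np.sqrt(fit.n_used / np.maximum(fit.n_used - k_per_eq, 1))
    complete = complete * infl

    a_s = np.empty((n_boot, p))
    b_s = np.empty((n_boot, p, p))
    c_s = np.empty((n_boot, p, q))
    n_failed = 0
    kept = 0
    for r in range(n_boot):
        if error_draws == "resample":
            rows = rng.integers(0, complete.shape[0], size=T - 1)
            errs = complete[rows]
        else:
            errs = rng.standard_normal((T - 1, p)) * np.sqrt(params.sigma2)
        x_rep = _simulate_fixed_design(params, x0, uvals, errs)
        try:
            rep_params, _, _ = _cls_fit(x_rep, uvals, mask, y.taxon_names)
        except Exception:
            n_failed += 1
            continue
        a_s[kept] = rep_params.a
        b_s[kept] = rep_params.b
        c_s[kept] = rep_params.c
        kept += 1

    if n_failed > n_boot / 2:
        raise RunError(
            f"{n_failed}/{n_boot} bootstrap replicates failed to fit"
        )

    lo_q = (1 - level) / 2
    hi_q = 1 - lo_q
    a_s, b_s, c_s = a_s[:kept], b_s[:kept], c_s[:kept]
    a_lo = np.quantile(a_s, lo_q, axis=0, method='inverted_cdf')
    a_hi = np.quantile(a_s, hi_q, axis=0, method='higher')
    b_lo = np.quantile(b_s, lo_q, axis=0, method='inverted_cdf')
    b_hi = np.quantile(b_s, hi_q, axis=0, method='higher')
    if q:
        c_lo = np.quantile(c_s, lo_q, axis=0, method='inverted_cdf')
        c_hi = np.quantile(c_s, hi_q, axis=0, method='higher')
    else:
        c_lo = np.zeros((p, 0))
        c_hi = np.zeros((p, 0))

    # masked coefficients carry no interval
    b_lo[~mask.b_mask] = np.nan
    b_hi[~mask.b_mask] = np.nan
    c_lo[~mask.c_mask] = np.nan
    c_hi[~mask.c_mask] = np.nan

    return CoefficientIntervals(
        level=level,
        a_lo=a_lo, a_hi=a_hi,
        b_lo=b_lo, b_hi=b_hi,
        c_lo=c_lo, c_hi=c_hi,
        n_boot=n_boot, seed=seed, n_failed=n_failed,
    )
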