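"""First-order multivariate autoregressive (MAR(1) / VAR(1)) community model.

The model for p interacting taxa and q environmental covariates is

    X_t = A + B X_{t-1} + C U_t + E_t,        E_t ~ N(0, diag(sigma2))

where X_t is the p-vector of natural-log abundances, A the intrinsic
growth constants, B the p x p interaction matrix (diagonal = density
dependence), C the p x q covariate-effect matrix and E_t independent
mean-zero process errors with a diagonal covariance.

Estimation is by conditional least squares (CLS): each taxon's equation is
an ordinary least-squares regression of x_{i,t} on an intercept, the
mask-included lagged abundances x_{j,t-1} and the mask-included
contemporaneous covariates u_{k,t}.  Equations are independent, so rows
with missing values are dropped per equation (casewise deletion) and a
rank-deficient design fails loudly, naming the equation.

Community stability is summarised by the spectral radius of B (written
lambda): the largest eigenvalue modulus, with complex pairs handled via
their modulus.  lambda > 1 flags an unstable system; values closer to 0
mean faster return to the stationary distribution after a perturbation.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .errors import DegenerateFitError, InputError
from .panels import AbundancePanel, CovariatePanel, MaskSpec

__all__ = [
    "MARParams",
    "MARFit",
    "MAR",
    "MARResults",
    "fit_mar",
    "stability_lambda",
    "predict_one_step",
]


# ---------------------------------------------------------------------------
# parameter containers
# ---------------------------------------------------------------------------

@dataclass
class MARParams:
    """Point estimates (or generating values) of a MAR(1) model.

    ``a``: p-vector of intrinsic growth constants; ``b``: p x p interaction
    matrix; ``c``: p x q covariate effects; ``sigma2``: p-vector of process
    error variances (the diagonal of Sigma).  Entries excluded by a mask are
    exactly zero.
    """

    a: np.ndarray
    b: np.ndarray
    c: np.ndarray = field(default=None)  # type: ignore[assignment]
    sigma2: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self):
        self.a = np.atleast_1d(np.asarray(self.a, dtype=float))
        self.b = np.atleast_2d(np.asarray(self.b, dtype=float))
        p = self.a.shape[0]
        if self.b.shape != (p, p):
            raise InputError(f"b must be {p}x{p}, got {self.b.shape}")
        if self.c is None:
            self.c = np.zeros((p, 0))
        else:
            self.c = np.atleast_2d(np.asarray(self.c, dtype=float))
            if self.c.shape[0] != p:
                raise InputError(f"c must have {p} rows, got {self.c.shape}")
        if self.sigma2 is None:
            self.sigma2 = np.zeros(p)
        else:
            self.sigma2 = np.atleast_1d(np.asarray(self.sigma2, dtype=float))
            if self.sigma2.shape != (p,):
                raise InputError("sigma2 must be a p-vector")
            if np.any(self.sigma2 < 0):
                raise InputError("sigma2 must be nonnegative")

    @property
    def p(self) -> int:
        return self.a.shape[0]

    @property
    def q(self) -> int:
        return self.c.shape[1]

    def check_mask(self, mask: MaskSpec, tol: float = 0.0) -> bool:
        """True iff every mask-excluded coefficient is (exactly) zero."""
        return bool(
            np.all(np.abs(self.b[~mask.b_mask]) <= tol)
            and np.all(np.abs(self.c[~mask.c_mask]) <= tol)
        )


@dataclass
class MARFit:
    """A fitted window: parameters, residuals and bookkeeping.

    ``residuals`` is (T-1) x p aligned to response times (the time of X_t,
    t = 2..T); rows dropped from an equation by casewise deletion are NaN
    in that column.  ``n_used`` counts the regression rows actually used
    per equation.
    """

    params: MARParams
    residuals: pd.DataFrame
    n_used: np.ndarray
    window_span: tuple

    @property
    def response_times(self) -> pd.Index:
        return self.residuals.index


# ---------------------------------------------------------------------------
# core operations
# ---------------------------------------------------------------------------

def stability_lambda(b: np.ndarray) -> float:
    """Spectral radius of an interaction matrix: max eigenvalue modulus.

    Complex conjugate pairs are handled through their modulus, which is the
    quantity governing the return rate to the stationary distribution.
    Values above 1 indicate an unstable system.
    """
    b = np.asarray(b, dtype=float)
    if b.ndim != 2 or b.shape[0] != b.shape[1]:
        raise InputError("stability_lambda requires a square matrix")
    return float(np.max(np.abs(np.linalg.eigvals(b))))


def predict_one_step(params: MARParams, x_prev, u_now=None) -> np.ndarray:
    """Deterministic one-step prediction A + B x_prev + C u_now."""
    x_prev = np.asarray(x_prev, dtype=float)
    if x_prev.shape != (params.p,):
        raise InputError(f"x_prev must be a {params.p}-vector, got {x_prev.shape}")
    out = params.a + params.b @ x_prev
    if params.q:
        u_now = np.asarray(u_now, dtype=float)
        if u_now.shape != (params.q,):
            raise InputError(f"u_now must be a {params.q}-vector, got {u_now.shape}")
        out = out + params.c @ u_now
    return out


def _cls_fit(
    x: np.ndarray,
    u: Optional[np.ndarray],
    mask: MaskSpec,
    taxon_names: list[str],
    sigma_divisor: str = "n",
) -> tuple[MARParams, np.ndarray, np.ndarray]:
    """Equation-by-equation conditional least squares on raw arrays.

    Returns (params, residual matrix (T-1) x p with NaN for dropped rows,
    n_used per equation).
    """
    T, p = x.shape
    resp = x[1:, :]            # X_t,     t = 2..T
    lag = x[:-1, :]            # X_{t-1}
    uu = u[1:, :] if u is not None and u.shape[1] else None

    a = np.zeros(p)
    b = np.zeros((p, p))
    c = np.zeros((p, mask.q))
    sigma2 = np.zeros(p)
    resid = np.full((T - 1, p), np.nan)
    n_used = np.zeros(p, dtype=int)

    for i in range(p):
        bj = np.flatnonzero(mask.b_mask[i])
        ck = np.flatnonzero(mask.c_mask[i]) if uu is not None else np.array([], int)
        design = np.column_stack([np.ones(T - 1), lag[:, bj]] + (
            [uu[:, ck]] if len(ck) else []
        ))
        y_i = resp[:, i]
        ok = np.isfinite(y_i) & np.all(np.isfinite(design), axis=1)
        k = design.shape[1]
        name = taxon_names[i]
        if ok.sum() < k + 1:
            raise DegenerateFitError(
                name, f"only {int(ok.sum())} usable rows for {k} coefficients"
            )
        D, yv = design[ok], y_i[ok]
        beta, _, rank, _ = np.linalg.lstsq(D, yv, rcond=None)
        if rank < k:
            raise DegenerateFitError(
                name, f"design matrix rank {rank} < {k} (constant or collinear predictor)"
            )
        a[i] = beta[0]
        b[i, bj] = beta[1 : 1 + len(bj)]
        if len(ck):
            c[i, ck] = beta[1 + len(bj) :]
        e = yv - D @ beta
        n_used[i] = int(ok.sum())
        div = n_used[i] if sigma_divisor == "n" else max(n_used[i] - k, 1)
        sigma2[i] = float(e @ e) / div
        resid[ok, i] = e

    return MARParams(a, b, c, sigma2), resid, n_used


def fit_mar(
    y: AbundancePanel,
    u: Optional[CovariatePanel] = None,
    mask: Optional[MaskSpec] = None,
    sigma_divisor: str = "n",
) -> MARFit:
    """Fit a MAR(1) model to one data window by conditional least squares.

    Each taxon's equation is estimated independently; regression rows with
    any missing value among that equation's response or predictors are
    dropped for that equation only.  ``sigma_divisor`` chooses the variance
    divisor: ``"n"`` (default, maximum-likelihood flavour) or ``"n-k"``.
    """
    if mask is None:
        mask = MaskSpec.full(y.n_taxa, 0 if u is None else u.n_covariates)
    mask.check_shapes(y, u)
    if u is not None:
        y.check_aligned(u)
    max_k = 1 + int(mask.b_mask.sum(axis=1).max()) + (
        int(mask.c_mask.sum(axis=1).max()) if mask.q else 0
    )
    if y.n_times < max_k + 2:
        raise InputError(
            f"series length {y.n_times} too short for {max_k} predictors per equation"
        )
    params, resid, n_used = _cls_fit(
        y.values,
        None if u is None else u.values,
        mask,
        y.taxon_names,
        sigma_divisor,
    )
    residuals = pd.DataFrame(resid, index=y.times[1:], columns=y.taxon_names)
    return MARFit(
        params=params,
        residuals=residuals,
        n_used=n_used,
        window_span=(y.times[0], y.times[-1]),
    )


# ---------------------------------------------------------------------------
# statsmodels-style model / results surface
# ---------------------------------------------------------------------------

class MAR:
    """MAR(1) community model bound to data.

    Parameters
    ----------
    endog : AbundancePanel or DataFrame
        Log-abundance panel (taxa in columns).
    exog : CovariatePanel or DataFrame, optional
        Standardized covariates on the same time index.
    mask : MaskSpec, optional
        A-priori inclusion masks; defaults to all coefficients estimated.

    Examples
    --------
    >>> res = MAR(panel, covars, mask).fit()
    >>> res.params.b          # interaction matrix estimate
    >>> res.stability         # spectral radius of B
    >>> print(res.summary())
    """

    def __init__(self, endog, exog=None, mask: Optional[MaskSpec] = None):
        self.endog = endog if isinstance(endog, AbundancePanel) else AbundancePanel(endog)
        if exog is None:
            self.exog = None
        else:
            self.exog = exog if isinstance(exog, CovariatePanel) else CovariatePanel(exog)
            self.endog.check_aligned(self.exog)
        q = 0 if self.exog is None else self.exog.n_covariates
        self.mask = mask if mask is not None else MaskSpec.full(self.endog.n_taxa, q)
        self.mask.check_shapes(self.endog, self.exog)

    @classmethod
    def from_dataframe(
        cls,
        frame: pd.DataFrame,
        taxa: list[str],
        covariates: Optional[list[str]] = None,
        mask: Optional[MaskSpec] = None,
    ) -> "MAR":
        """Build from one wide DataFrame by naming taxon / covariate columns."""
        y = AbundancePanel(frame[taxa])
        u = CovariatePanel(frame[list(covariates)]) if covariates else None
        return cls(y, u, mask)

    def fit(self, sigma_divisor: str = "n") -> "MARResults":
        fit = fit_mar(self.endog, self.exog, self.mask, sigma_divisor)
        return MARResults(self, fit)


class MARResults:
    """Results of a single-window MAR(1) fit."""

    def __init__(self, model: MAR, fit: MARFit, intervals=None):
        self.model = model
        self.fit = fit
        self.intervals = intervals

    @property
    def params(self) -> MARParams:
        return self.fit.params

    @property
    def resid(self) -> pd.DataFrame:
        return self.fit.residuals

    @property
    def sigma2(self) -> np.ndarray:
        return self.fit.params.sigma2

    @property
    def stability(self) -> float:
        """Spectral radius lambda of the estimated interaction matrix."""
        return stability_lambda(self.fit.params.b)

    def conf_int(self, n_boot: int = 2000, level: float = 0.95, seed: int = 0,
                 error_draws: str = "resample"):
        """Bootstrap confidence intervals for all estimated coefficients.

        Replicate panels are rebuilt from the fitted model (fixed design:
        observed initial state and covariates) with random process errors,
        then refitted by CLS; see :func:`mwmar.bootstrap.bootstrap_intervals`.
        """
        from .bootstrap import bootstrap_intervals

        self.intervals = bootstrap_intervals(
            self.fit, self.model.endog, self.model.exog, self.model.mask,
            n_boot=n_boot, level=level, seed=seed, error_draws=error_draws,
        )
        return self.intervals

    def predict(self, x_prev, u_now=None) -> np.ndarray:
        return predict_one_step(self.fit.params, x_prev, u_now)

    def summary(self) -> str:
        p = self.fit.params
        taxa = self.model.endog.taxon_names
        covs = [] if self.model.exog is None else self.model.exog.covariate_names
        lines = [
            "MAR(1) fit by conditional least squares",
            f"  window: {self.fit.window_span[0]} .. {self.fit.window_span[1]}",
            f"  taxa: {', '.join(taxa)}",
            f"  stability lambda = {self.stability:.4f}"
            + ("  (UNSTABLE: lambda > 1)" if self.stability > 1 else ""),
            "",
            "A (intrinsic growth):",
        ]
        for i, t in enumerate(taxa):
            lines.append(f"  {t:>14s}: {p.a[i]: .4f}   sigma2={p.sigma2[i]:.4f}"
                         f"   n_used={self.fit.n_used[i]}")
        lines.append("")
        lines.append("B (interactions, row = response):")
        head = " " * 16 + "".join(f"{t:>12s}" for t in taxa)
        lines.append(head)
        bm = self.model.mask.b_mask
        for i, t in enumerate(taxa):
            cells = [
                f"{p.b[i, j]: 12.4f}" if bm[i, j] else f"{'--':>12s}"
                for j in range(len(taxa))
            ]
            lines.append(f"  {t:>14s}" + "".join(cells))
        if covs:
            lines.append("")
            lines.append("C (covariate effects, row = response):")
            lines.append(" " * 16 + "".join(f"{c:>12s}" for c in covs))
            cm = self.model.mask.c_mask
            for i, t in enumerate(taxa):
                cells = [
                    f"{p.c[i, k]: 12.4f}" if cm[i, k] else f"{'n/a':>12s}"
                    for k in range(len(covs))
                ]
                lines.append(f"  {t:>14s}" + "".join(cells))
        return "\n".join(lines)
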