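"""Model-fit assessment for moving-window MAR runs.

The model assumes normally distributed process errors, so every window x
taxon residual vector is screened with the Shapiro-Wilk test at a
Bonferroni-corrected level (the multiplicity universe defaults to windows
x taxa and is configurable; the report records the m used).  Zero-inflated
taxa produce long one-sided residual tails and show up here as elevated
per-taxon rejection counts.

A second screen correlates each equation's residuals against that
equation's own predictor series (lagged abundances, covariates) within the
window — the standard misfit check for conditional least squares: under a
well-specified model the significant fraction should sit near the nominal
alpha, and a large fraction flags structure the model missed.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .errors import InputError
from .panels import AbundancePanel, CovariatePanel, MaskSpec
from .window import Trajectory

__all__ = [
    "NormalityReport",
    "shapiro_wilk",
    "bonferroni_alpha",
    "residual_normality_scan",
    "residual_data_correlation_scan",
    "qq_export",
]


def shapiro_wilk(sample) -> tuple[float, float]:
    """Shapiro-Wilk W statistic and p-value (Royston's approximation)."""
    x = np.asarray(sample, dtype=float)
    x = x[np.isfinite(x)]
    if not 3 <= len(x) <= 5000:
        raise InputError(
            f"Shapiro-Wilk needs 3 <= n <= 5000 observations, got {len(x)}"
        )
    w, p = stats.shapiro(x)
    return float(w), float(p)


def bonferroni_alpha(alpha: float, m: int) -> float:
    """Bonferroni-corrected per-test level alpha / m."""
    if not 0 < alpha < 1:
        raise InputError(f"alpha must be in (0, 1), got {alpha}")
    if m < 1:
        raise InputError(f"number of tests m must be >= 1, got {m}")
    return alpha / m


@dataclass
class NormalityReport:
    """Per-(window, taxon) Shapiro-Wilk results with multiplicity control.

    ``table`` columns: end_time, taxon, W, pvalue, reject.  ``m`` is the
    multiplicity universe the correction used.  ``rejections`` maps taxon
    -> number of windows rejected at ``corrected_alpha``.
    """

    table: pd.DataFrame
    alpha: float
    corrected_alpha: float
    m: int
    rejections: dict[str, int] = field(default_factory=dict)
    n_windows: int = 0


def residual_normality_scan(
    tr: Trajectory,
    alpha: float = 0.05,
    multiplicity: str = "windows_x_taxa",
) -> NormalityReport:
    """Shapiro-Wilk screen of every window x taxon residual vector.

    ``multiplicity`` sets the Bonferroni universe m: ``"windows_x_taxa"``
    (default; the pooled convention) or ``"windows"`` (per-taxon
    convention, m = number of windows).
    """
    ok_results = [r for r in tr.results if r.ok]
    if not ok_results:
        raise InputError("trajectory holds no successful fits")
    taxa = tr.taxon_names
    n_windows = len(ok_results)
    if multiplicity == "windows_x_taxa":
        m = n_windows * len(taxa)
    elif multiplicity == "windows":
        m = n_windows
    else:
        raise InputError(f"unknown multiplicity convention {multiplicity!r}")
    corrected = bonferroni_alpha(alpha, m)

    rows = []
    for r in ok_results:
        for taxon in taxa:
            res = r.fit.residuals[taxon].dropna().to_numpy()
            w, p = shapiro_wilk(res)
            rows.append({
                "end_time": r.end_time, "taxon": taxon,
                "W": w, "pvalue": p, "reject": p < corrected,
            })
    table = pd.DataFrame(rows)
    rejections = {
        t: int(table.loc[table.taxon == t, "reject"].sum()) for t in taxa
    }
    return NormalityReport(
        table=table, alpha=alpha, corrected_alpha=corrected, m=m,
        rejections=rejections, n_windows=n_windows,
    )


def residual_data_correlation_scan(
    tr: Trajectory,
    y: AbundancePanel,
    u: CovariatePanel | None = None,
    alpha: float = 0.05,
    pairs: str = "own_predictors",
) -> tuple[float, pd.DataFrame]:
    """Pearson correlations of residuals against data within each window.

    For every window and taxon, the residual series is correlated against
    each predictor series of that taxon's equation (its mask-included
    lagged abundances and covariates); ``pairs="all"`` instead tests every
    taxon/covariate series regardless of mask.  Two-sided tests at
    ``alpha``.  Returns (fraction significant, full table).  Pairs whose
    correlation is undefined (constant series) are flagged and counted as
    not significant.
    """
    ok_results = [(wi, r) for wi, r in enumerate(tr.results) if r.ok]
    if not ok_results:
        raise InputError("trajectory holds no successful fits")
    taxa = tr.taxon_names
    covs = tr.covariate_names
    mask = tr.mask if tr.mask is not None else MaskSpec.full(len(taxa), len(covs))
    times = list(y.times)
    rows = []
    for wi, r in ok_results:
        res_frame = r.fit.residuals
        resp_times = res_frame.index
        # positional range of the responses within the full series
        start = times.index(resp_times[0])
        stop = times.index(resp_times[-1]) + 1
        lag_block = y.values[start - 1:stop - 1, :]     # x_{t-1}
        cov_block = u.values[start:stop, :] if u is not None else None
        for i, taxon in enumerate(taxa):
            e = res_frame[taxon].to_numpy()
            preds: list[tuple[str, np.ndarray]] = []
            for j, other in enumerate(taxa):
                if pairs == "all" or mask.b_mask[i, j]:
                    preds.append((f"lag:{other}", lag_block[:, j]))
            for k, cname in enumerate(covs):
                if cov_block is not None and (pairs == "all" or mask.c_mask[i, k]):
                    preds.append((f"cov:{cname}", cov_block[:, k]))
            for pname, series in preds:
                okrows = np.isfinite(e) & np.isfinite(series)
                ev, sv = e[okrows], series[okrows]
                if len(ev) < 3 or np.std(ev) == 0 or np.std(sv) == 0:
                    rows.append({
                        "end_time": r.end_time, "taxon": taxon,
                        "predictor": pname, "r": np.nan, "pvalue": np.nan,
                        "significant": False, "degenerate": True,
                    })
                    continue
                rr, pp = stats.pearsonr(ev, sv)
                rows.append({
                    "end_time": r.end_time, "taxon": taxon,
                    "predictor": pname, "r": float(rr), "pvalue": float(pp),
                    "significant": bool(pp < alpha), "degenerate": False,
                })
    table = pd.DataFrame(rows)
    frac = float(table["significant"].mean()) if len(table) else 0.0
    return frac, table


def qq_export(residuals) -> pd.DataFrame:
    """Normal QQ pairs: order statistics vs N(0,1) quantiles at (i-0.5)/n."""
    x = np.asarray(residuals, dtype=float)
    x = x[np.isfinite(x)]
    n = len(x)
    if n < 3:
        raise InputError(f"QQ export needs at least 3 values, got {n}")
    obs = np.sort(x)
    probs = (np.arange(1, n + 1) - 0.5) / n
    theo = stats.norm.ppf(probs)
    return pd.DataFrame({"theoretical": theo, "observed": obs})
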