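"""Moving-window MAR: overlapping-window enumeration and trajectories.

Refitting the MAR(1) model on every length-W contiguous subset of the
series turns each coefficient into a time series of its own, exposing
non-stationarity (regime shifts, slowly drifting interactions) that a
single whole-series fit averages away.

Window bookkeeping follows the convention that the first response is the
second observation (the lag-1 effect consumes one observation): with n
time steps and window size W the response ranges are [2, W+1], [3, W+2],
..., [n-W+1, n] in 1-based inclusive labels, giving n - W windows, each
using W+1 consecutive observations.  Results are keyed by the window END
time.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .bootstrap import CoefficientIntervals, bootstrap_intervals, is_significant
from .errors import DegenerateFitError, InputError, RunError
from .model import MAR, MARFit, fit_mar, stability_lambda
from .panels import AbundancePanel, CovariatePanel, MaskSpec

__all__ = [
    "WindowResult",
    "Trajectory",
    "enumerate_windows",
    "moving_window_fit",
    "trajectory_to_table",
    "MovingWindowMAR",
    "MovingWindowResults",
]


def enumerate_windows(n: int, w: int) -> list[tuple[int, int]]:
    """Enumerate response index ranges for all windows of size ``w``.

    Returns 1-based inclusive (response_start, response_end) pairs:
    [2, w+1], [3, w+2], ..., [n-w+1, n].  Each window's regressions also
    consume the observation immediately before its first response, so a
    window spans w+1 raw observations.  The count is n - w.
    """
    if w < 2:
        raise InputError(f"window size {w} must be at least 2")
    if w >= n:
        raise InputError(f"window size {w} must be smaller than series length {n}")
    return [(s, s + w - 1) for s in range(2, n - w + 2)]


@dataclass
class WindowResult:
    """One window's fit: keyed by the time of its last observation."""

    end_time: object
    fit: Optional[MARFit]
    lambda_: Optional[float] = None
    intervals: Optional[CoefficientIntervals] = None
    failure: Optional[str] = None

    @property
    def ok(self) -> bool:
        return self.fit is not None


@dataclass
class Trajectory:
    """Ordered sequence of per-window fits — a time series of MAR parameters."""

    window_size: int
    results: list[WindowResult] = field(default_factory=list)
    taxon_names: list[str] = field(default_factory=list)
    covariate_names: list[str] = field(default_factory=list)
    mask: Optional[MaskSpec] = None

    def __len__(self) -> int:
        return len(self.results)

    def __iter__(self):
        return iter(self.results)

    @property
    def end_times(self) -> list:
        return [r.end_time for r in self.results]

    def lambda_series(self) -> pd.Series:
        """Stability trajectory indexed by window end time (NaN on failures)."""
        return pd.Series(
            [r.lambda_ if r.ok else np.nan for r in self.results],
            index=pd.Index(self.end_times, name="end_time"),
            name="lambda",
        )

    def coefficient_series(self, response: str, predictor: str) -> pd.Series:
        """Trajectory of one coefficient.

        ``predictor`` may be a taxon name (B entry), a covariate name
        (C entry) or ``"intercept"`` (A entry).
        """
        i = self.taxon_names.index(response)
        vals = []
        for r in self.results:
            if not r.ok:
                vals.append(np.nan)
            elif predictor == "intercept":
                vals.append(r.fit.params.a[i])
            elif predictor in self.taxon_names:
                vals.append(r.fit.params.b[i, self.taxon_names.index(predictor)])
            elif predictor in self.covariate_names:
                vals.append(r.fit.params.c[i, self.covariate_names.index(predictor)])
            else:
                raise InputError(f"unknown predictor {predictor!r}")
        return pd.Series(vals, index=pd.Index(self.end_times, name="end_time"),
                         name=f"{response}<-{predictor}")


def moving_window_fit(
    y: AbundancePanel,
    u: Optional[CovariatePanel] = None,
    mask: Optional[MaskSpec] = None,
    w: int = 84,
    n_boot: int = 0,
    level: float = 0.95,
    seed: int = 0,
    error_draws: str = "resample",
    progress: Optional[callable] = None,
) -> Trajectory:
    """Fit a MAR(1) model in every moving window of size ``w``.

    Covariates must be standardized over the FULL series before calling
    (trajectories then reflect changing responses, not changing covariate
    scaling).  Windows whose fit is degenerate are recorded with an
    explicit failure message, never dropped silently.  ``n_boot`` > 0
    attaches percentile bootstrap intervals to every window (the per-window
    bootstrap seed is derived from ``seed`` and the window position).
    """
    n = y.n_times
    windows = enumerate_windows(n, w)
    if u is not None:
        y.check_aligned(u)
    if mask is None:
        mask = MaskSpec.full(y.n_taxa, 0 if u is None else u.n_covariates)

    traj = Trajectory(
        window_size=w,
        taxon_names=y.taxon_names,
        covariate_names=[] if u is None else u.covariate_names,
        mask=mask,
    )
    n_ok = 0
    for wi, (rs, re) in enumerate(windows):
        # responses rs..re (1-based) use observations rs-1..re -> iloc slice
        lo, hi = rs - 2, re  # 0-based [lo, hi) over raw observations
        y_w = y.window(lo, hi)
        u_w = u.window(lo, hi) if u is not None else None
        end_time = y.times[hi - 1]
        try:
            fit = fit_mar(y_w, u_w, mask)
        except (DegenerateFitError, InputError) as exc:
            traj.results.append(WindowResult(end_time, None, failure=str(exc)))
            continue
        lam = stability_lambda(fit.params.b)
        intervals = None
        if n_boot > 0:
            intervals = bootstrap_intervals(
                fit, y_w, u_w, mask, n_boot=n_boot, level=level,
                seed=(seed * 100003 + wi) % (2**31 - 1), error_draws=error_draws,
            )
        traj.results.append(WindowResult(end_time, fit, lam, intervals))
        n_ok += 1
        if progress is not None:
            progress(wi, len(windows), end_time)
    if n_ok == 0:
        raise RunError("every window failed to fit")
    return traj


def trajectory_to_table(tr: Trajectory) -> pd.DataFrame:
    """Long-format records of a trajectory.

    One row per estimated (mask-included) coefficient per window, plus one
    stability row per window; columns (end_time, response, predictor,
    estimate, ci_lo, ci_hi, significant, lambda).  Masked coefficients are
    absent.  Failed windows contribute a single row with predictor
    ``"__failed__"`` and the failure reason in ``response``.
    """
    if len(tr) == 0:
        raise InputError("empty trajectory")
    taxa = tr.taxon_names
    covs = tr.covariate_names
    mask = tr.mask if tr.mask is not None else MaskSpec.full(len(taxa), len(covs))
    rows = []
    for r in tr.results:
        if not r.ok:
            rows.append({
                "end_time": r.end_time, "response": r.failure,
                "predictor": "__failed__", "estimate": np.nan,
                "ci_lo": np.nan, "ci_hi": np.nan, "significant": False,
                "lambda": np.nan,
            })
            continue
        p = r.fit.params
        iv = r.intervals

        def rec(resp, pred, est, lo, hi):
            sig = is_significant(lo, hi) if np.isfinite(lo) and np.isfinite(hi) else False
            rows.append({
                "end_time": r.end_time, "response": resp, "predictor": pred,
                "estimate": est, "ci_lo": lo, "ci_hi": hi,
                "significant": sig, "lambda": r.lambda_,
            })

        for i, t in enumerate(taxa):
            rec(t, "intercept", p.a[i],
                iv.a_lo[i] if iv else np.nan, iv.a_hi[i] if iv else np.nan)
        for i, t in enumerate(taxa):
            for j, s in enumerate(taxa):
                if mask.b_mask[i, j]:
                    rec(t, s, p.b[i, j],
                        iv.b_lo[i, j] if iv else np.nan,
                        iv.b_hi[i, j] if iv else np.nan)
        for i, t in enumerate(taxa):
            for k, cname in enumerate(covs):
                if mask.c_mask[i, k]:
                    rec(t, cname, p.c[i, k],
                        iv.c_lo[i, k] if iv else np.nan,
                        iv.c_hi[i, k] if iv else np.nan)
        rows.append({
            "end_time": r.end_time, "response": "__community__",
            "predictor": "lambda", "estimate": r.lambda_,
            "ci_lo": np.nan, "ci_hi": np.nan, "significant": False,
            "lambda": r.lambda_,
        })
    return pd.DataFrame(
        rows,
        columns=["end_time", "response", "predictor", "estimate",
                 "ci_lo", "ci_hi", "significant", "lambda"],
    )


class MovingWindowMAR:
    """Moving-window MAR(1) model: one MAR fit per overlapping window.

    Mirrors :class:`mwmar.model.MAR` but ``fit()`` returns a
    :class:`MovingWindowResults` holding the whole trajectory of parameter
    estimates, intervals and stability values.
    """

    def __init__(self, endog, exog=None, mask: Optional[MaskSpec] = None,
                 window: int = 84):
        base = MAR(endog, exog, mask)  # reuse validation
        self.endog = base.endog
        self.exog = base.exog
        self.mask = base.mask
        self.window = window

    def fit(self, n_boot: int = 0, level: float = 0.95, seed: int = 0,
            error_draws: str = "resample", progress=None) -> "MovingWindowResults":
        traj = moving_window_fit(
            self.endog, self.exog, self.mask, self.window,
            n_boot=n_boot, level=level, seed=seed,
            error_draws=error_draws, progress=progress,
        )
        return MovingWindowResults(self, traj)


class MovingWindowResults:
    """Trajectory of per-window MAR fits with tabular / series accessors."""

    def __init__(self, model: MovingWindowMAR, trajectory: Trajectory):
        self.model = model
        self.trajectory = trajectory

    def __len__(self) -> int:
        return len(self.trajectory)

    @property
    def lambda_series(self) -> pd.Series:
        return self.trajectory.lambda_series()

    def coefficient_series(self, response: str, predictor: str) -> pd.Series:
        return self.trajectory.coefficient_series(response, predictor)

    def to_frame(self) -> pd.DataFrame:
        return trajectory_to_table(self.trajectory)

    def summary(self) -> str:
        tr = self.trajectory
        n_fail = sum(1 for r in tr.results if not r.ok)
        lam = self.lambda_series.dropna()
        lines = [
            "Moving-window MAR(1) trajectory",
            f"  window size: {tr.window_size}   windows: {len(tr)}"
            f"   failed: {n_fail}",
            f"  lambda range: {lam.min():.4f} .. {lam.max():.4f}"
            f"   (peak at {lam.idxmax()})",
            f"  windows with lambda > 1: {(lam > 1).sum()}",
        ]
        return "\n".join(lines)

    def plot_coefficient(self, response: str, predictor: str, ax=None):
        """Trajectory plot of one coefficient with its CI band (if present)."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        ser = self.coefficient_series(response, predictor)
        x = np.arange(len(ser))
        ax.plot(x, ser.values, lw=1.5, label=f"{predictor} -> {response}")
        tab = self.to_frame()
        sub = tab[(tab.response == response) & (tab.predictor == predictor)]
        if sub.ci_lo.notna().any():
            ax.fill_between(x, sub.ci_lo.values, sub.ci_hi.values, alpha=0.25)
        ax.axhline(0.0, color="grey", ls=":")
        ax.set_xlabel("window end")
        ax.set_ylabel("coefficient")
        ax.legend()
        return ax
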