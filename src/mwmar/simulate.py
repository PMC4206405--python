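"""Synthetic MAR(1) panels and the window-size / transition-bias experiments.

Three layers:

* :func:`simulate_mar` — iterate X_t = A + B X_{t-1} + C U_t + E_t forward
  with independent Gaussian process errors (seeded, reproducible).
* :func:`simulate_regime_shift` — piecewise-constant parameters switching
  at breakpoints, the state carrying across; the generating parameter
  values at every step are returned for scoring.
* :func:`lake_washington_fixture` — a 4-guild, 396-month panel emulating a
  deep temperate lake that flips from a cyanobacteria-dominated eutrophic
  regime to a grazer-dominated clear-water regime: strong seasonal
  temperature forcing with anomalies, a declining phosphorus trend, a
  three-phase (eutrophic / transition / clear-water) parameter scheme with
  the transition phase least stable, and detection-floor censoring that
  zero-inflates the grazer early and the cyanobacterium late.

The experiments quantify what moving-window estimation can and cannot do:
:func:`window_size_experiment` measures estimation bias/RMSE per window
size on stationary data (precision-accuracy tradeoff of W), and
:func:`transition_bias_experiment` profiles the signed estimation error as
windows traverse a breakpoint, where estimates necessarily blend the two
regimes.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence

import numpy as np
import pandas as pd

from .errors import InputError
from .model import MARParams, fit_mar, stability_lambda
from .panels import AbundancePanel, CovariatePanel, MaskSpec
from .preprocess import build_covariate_panel, log_abundance
from .window import enumerate_windows, moving_window_fit

__all__ = [
    "RegimeConfig",
    "RegimeTruth",
    "AccuracyTable",
    "simulate_mar",
    "simulate_regime_shift",
    "lake_washington_fixture",
    "window_size_experiment",
    "transition_bias_experiment",
    "LW_TAXA",
    "LW_COVARIATES",
    "lake_washington_params",
]

LW_TAXA = ["DG", "NDC", "Daphnia", "Oscillatoria"]
LW_COVARIATES = ["season", "temp_anomaly", "total_phosphorus"]


# ---------------------------------------------------------------------------
# forward simulation
# ---------------------------------------------------------------------------

def simulate_mar(
    params: MARParams,
    T: int,
    x0=None,
    u: Optional[CovariatePanel] = None,
    seed: int = 0,
    times=None,
    taxon_names: Optional[list[str]] = None,
) -> AbundancePanel:
    """Simulate a log-abundance panel from known MAR(1) parameters.

    ``x0`` defaults to the stationary mean (I - B)^(-1) A when the system
    is stable, else zeros.  With covariates, ``u`` must already span T time
    steps; the recursion uses U_t contemporaneously.
    """
    if T < 2:
        raise InputError("T must be at least 2")
    p = params.p
    if params.q and (u is None or u.n_times != T or u.n_covariates != params.q):
        raise InputError("covariate panel must be T x q to match params")
    if x0 is None:
        lam = stability_lambda(params.b)
        if lam < 1:
            x0 = np.linalg.solve(np.eye(p) - params.b, params.a)
        else:
            x0 = np.zeros(p)
    x0 = np.asarray(x0, dtype=float)
    if x0.shape != (p,):
        raise InputError(f"x0 must be a {p}-vector")

    rng = np.random.default_rng(seed)
    sd = np.sqrt(params.sigma2)
    uvals = u.values if params.q else None
    x = np.empty((T, p))
    x[0] = x0
    for t in range(1, T):
        mu = params.a + params.b @ x[t - 1]
        if params.q:
            mu = mu + params.c @ uvals[t]
        x[t] = mu + rng.standard_normal(p) * sd
    if times is None:
        times = u.times if u is not None else pd.RangeIndex(T)
    names = taxon_names or [f"taxon{j}" for j in range(p)]
    return AbundancePanel(x, times=times, names=names)


@dataclass
class RegimeConfig:
    """Piecewise-constant MAR(1) generating scheme.

    ``breakpoints`` are 0-based step indices at which the NEXT regime takes
    over (strictly increasing, inside (1, T)); ``regimes`` has one
    MARParams per phase (len(breakpoints) + 1).
    """

    regimes: list[MARParams]
    breakpoints: list[int]
    T: int
    x0: Optional[np.ndarray] = None
    covariates: Optional[CovariatePanel] = None
    seed: int = 0
    taxon_names: Optional[list[str]] = None

    def __post_init__(self):
        if len(self.regimes) != len(self.breakpoints) + 1:
            raise InputError("need exactly one regime per phase (breakpoints + 1)")
        bp = list(self.breakpoints)
        if any(b2 <= b1 for b1, b2 in zip(bp, bp[1:])):
            raise InputError("breakpoints must be strictly increasing")
        if bp and (bp[0] <= 1 or bp[-1] >= self.T):
            raise InputError("breakpoints must lie strictly inside (1, T)")
        p0, q0 = self.regimes[0].p, self.regimes[0].q
        if any(r.p != p0 or r.q != q0 for r in self.regimes):
            raise InputError("all regime parameter sets must share dimensions")


@dataclass
class RegimeTruth:
    """Generating values per time step, for scoring estimates."""

    regimes: list[MARParams]
    breakpoints: list[int]
    T: int

    @property
    def regime_index(self) -> np.ndarray:
        idx = np.zeros(self.T, dtype=int)
        for b in self.breakpoints:
            idx[b:] += 1
        return idx

    def params_at(self, t: int) -> MARParams:
        return self.regimes[int(self.regime_index[t])]

    def lambda_by_regime(self) -> list[float]:
        return [stability_lambda(r.b) for r in self.regimes]

    def b_series(self, i: int, j: int) -> np.ndarray:
        """True b[i, j] at every step."""
        vals = np.array([r.b[i, j] for r in self.regimes])
        return vals[self.regime_index]


def simulate_regime_shift(
    cfg: RegimeConfig,
) -> tuple[AbundancePanel, Optional[CovariatePanel], RegimeTruth]:
    """Simulate a panel whose parameters switch at the config's breakpoints.

    The state carries across breakpoints (no reinitialisation), so the
    early post-break steps still reflect the old regime's state — exactly
    the transient the transition-bias experiment probes.
    """
    truth = RegimeTruth(cfg.regimes, list(cfg.breakpoints), cfg.T)
    reg_idx = truth.regime_index
    p = cfg.regimes[0].p
    q = cfg.regimes[0].q
    if q and (cfg.covariates is None or cfg.covariates.n_times != cfg.T):
        raise InputError("covariate panel must span T steps")
    uvals = cfg.covariates.values if q else None

    rng = np.random.default_rng(cfg.seed)
    if cfg.x0 is None:
        r0 = cfg.regimes[0]
        if stability_lambda(r0.b) < 1:
            x0 = np.linalg.solve(np.eye(p) - r0.b, r0.a)
        else:
            x0 = np.zeros(p)
    else:
        x0 = np.asarray(cfg.x0, dtype=float)

    x = np.empty((cfg.T, p))
    x[0] = x0
    for t in range(1, cfg.T):
        pars = cfg.regimes[reg_idx[t]]
        mu = pars.a + pars.b @ x[t - 1]
        if q:
            mu = mu + pars.c @ uvals[t]
        x[t] = mu + rng.standard_normal(p) * np.sqrt(pars.sigma2)
    times = cfg.covariates.times if cfg.covariates is not None else pd.RangeIndex(cfg.T)
    names = cfg.taxon_names or [f"taxon{j}" for j in range(p)]
    panel = AbundancePanel(x, times=times, names=names)
    return panel, cfg.covariates, truth


# ---------------------------------------------------------------------------
# the Lake-Washington-like fixture
# ---------------------------------------------------------------------------

def _lw_c_matrix() -> np.ndarray:
    # rows: DG, NDC, Daphnia, Oscillatoria; cols: season, anomaly, phosphorus
    # seasonal forcing dominates (standardized units), phosphorus boosts the
    # phytoplankton groups only — the grazer cells are a-priori zero.
    return np.array([
        [0.50, -0.15, 0.20],
        [0.30, 0.10, 0.00],
        [0.50, 0.20, 0.00],
        [0.50, -0.25, 0.30],
    ])


def lake_washington_params() -> tuple[list[MARParams], list[int]]:
    """Three-phase generating scheme: eutrophic / transition / clear-water.

    Phase 1 (steps 0-119): cyanobacterium dominant, weak grazer; strong
    negative Oscillatoria effects on Daphnia and on diatoms/greens.
    Phase 2 (120-179): nutrient decline underway; weakest density
    dependence, spectral radius at its maximum (the least stable phase).
    Phase 3 (180-395): grazer dominant; negative Daphnia effects on both
    phytoplankton prey groups, Oscillatoria nearly gone.
    """
    c = _lw_c_matrix()
    sigma2 = np.array([0.35, 0.25, 0.50, 0.50])

    # B rows = response [DG, NDC, Daphnia, Oscillatoria]
    b1 = np.array([
        [0.70, 0.00, 0.00, -0.35],
        [0.10, 0.85, 0.00, 0.00],
        [0.10, 0.00, 0.60, -0.40],
        [0.00, 0.00, 0.00, 0.80],
    ])
    mu1 = np.array([3.0, 2.0, 1.0, 3.0])
    b2 = np.array([
        [0.70, 0.00, -0.10, -0.20],
        [0.10, 1.00, -0.10, 0.00],
        [0.15, 0.00, 0.60, -0.20],
        [0.00, 0.00, 0.00, 1.00],
    ])
    mu2 = np.array([3.2, 2.0, 1.5, 2.0])
    b3 = np.array([
        [0.60, 0.00, -0.30, 0.00],
        [0.10, 0.60, -0.20, 0.00],
        [0.15, 0.00, 0.50, 0.00],
        [0.00, 0.00, 0.00, 0.30],
    ])
    mu3 = np.array([3.0, 2.2, 2.0, 0.0])

    regimes = []
    for b, mu in ((b1, mu1), (b2, mu2), (b3, mu3)):
        a = (np.eye(4) - b) @ mu
        regimes.append(MARParams(a=a, b=b, c=c, sigma2=sigma2))
    return regimes, [120, 180]


def _lw_covariates(T: int, rng: np.random.Generator):
    """Raw temperature and phosphorus series on a monthly 1962+ index."""
    times = pd.period_range("1962-01", periods=T, freq="M")
    month = times.month.to_numpy()
    # surface temperature (deg C): sinusoidal climatology + anomalies that
    # include a slow warming drift
    clim = 11.0 + 6.5 * np.sin(2 * np.pi * (month - 4) / 12.0)
    anomalies = rng.normal(0.0, 1.0, T) + np.linspace(-0.5, 0.5, T)
    temperature = pd.Series(clim + anomalies, index=times, name="temperature")
    # total phosphorus (ug/L): sewage-era high values decaying to low ones
    t = np.arange(T)
    phos = 20.0 + 45.0 * np.exp(-t / 60.0) + rng.normal(0.0, 2.0, T)
    phosphorus = pd.Series(np.clip(phos, 1.0, None), index=times,
                           name="total_phosphorus")
    return temperature, phosphorus


def lake_washington_covariate_factory(seed: int, T: int = 396) -> CovariatePanel:
    """Standardized (season, anomaly, phosphorus) panel like the fixture's."""
    rng = np.random.default_rng(seed)
    temperature, phosphorus = _lw_covariates(T, rng)
    return build_covariate_panel(temperature, phosphorus)[0]


# detection floors on the natural-abundance scale: below these a sample
# records a zero, mimicking months when a taxon was not observed
_LW_FLOORS = {"Daphnia": float(np.exp(-0.8)), "Oscillatoria": float(np.exp(-0.3))}


def lake_washington_fixture(
    seed: int = 0,
) -> tuple[AbundancePanel, CovariatePanel, "MaskSpec", dict]:
    """Generate the 4-guild, 396-month synthetic lake panel.

    Returns (abundance panel, covariate panel, default mask, truth dict).
    The truth dict carries the RegimeTruth, the raw (uncensored) log
    states, the detection floors and the log-transform metadata.
    """
    from .io import default_lake_washington_mask

    T = 396
    rng = np.random.default_rng(seed)
    temperature, phosphorus = _lw_covariates(T, rng)
    covars, decomposition = build_covariate_panel(temperature, phosphorus)

    regimes, breakpoints = lake_washington_params()
    cfg = RegimeConfig(
        regimes=regimes, breakpoints=breakpoints, T=T,
        covariates=covars, seed=int(rng.integers(0, 2**31 - 1)),
        taxon_names=LW_TAXA,
    )
    latent, _, truth = simulate_regime_shift(cfg)

    # censor below the detection floor, then apply the standard zero policy
    abundance = pd.DataFrame(
        np.exp(latent.values), index=latent.times, columns=LW_TAXA
    )
    for taxon, floor in _LW_FLOORS.items():
        col = abundance[taxon]
        abundance[taxon] = col.where(col >= floor, 0.0)
    panel, logmeta = log_abundance(abundance, zero_policy="offset")

    mask = default_lake_washington_mask()
    truth_info = {
        "regime_truth": truth,
        "latent_log_states": latent,
        "floors": dict(_LW_FLOORS),
        "log_meta": logmeta,
        "seasonal_decomposition": decomposition,
    }
    return panel, covars, mask, truth_info


# ---------------------------------------------------------------------------
# validation experiments
# ---------------------------------------------------------------------------

@dataclass
class AccuracyTable:
    """Bias and RMSE per (window size, coefficient), over replicates."""

    table: pd.DataFrame = field(default_factory=pd.DataFrame)

    def rmse(self, size: int, coefficient: str) -> float:
        sub = self.table[(self.table.window_size == size)
                         & (self.table.coefficient == coefficient)]
        return float(sub.rmse.iloc[0])

    def mean_rmse(self, size: int, coefficients: Sequence[str]) -> float:
        sub = self.table[(self.table.window_size == size)
                         & (self.table.coefficient.isin(list(coefficients)))]
        return float(sub.rmse.mean())


def _coefficient_errors(est: MARParams, truth: MARParams, mask: MaskSpec,
                        taxa: list[str], covs: list[str]) -> dict[str, float]:
    errs = {}
    for i, t in enumerate(taxa):
        errs[f"a:{t}"] = est.a[i] - truth.a[i]
        for j, s in enumerate(taxa):
            if mask.b_mask[i, j]:
                errs[f"b:{t}<-{s}"] = est.b[i, j] - truth.b[i, j]
        for k, cn in enumerate(covs):
            if mask.c_mask[i, k]:
                errs[f"c:{t}<-{cn}"] = est.c[i, k] - truth.c[i, k]
    return errs


def window_size_experiment(
    params: MARParams,
    sizes: Sequence[int],
    n_reps: int = 50,
    T: int = 400,
    seed: int = 0,
    mask: Optional[MaskSpec] = None,
    covariate_factory: Optional[Callable[[int], CovariatePanel]] = None,
    taxon_names: Optional[list[str]] = None,
    covariate_names: Optional[list[str]] = None,
) -> AccuracyTable:
    """Estimation accuracy versus window size on stationary data.

    Per replicate: simulate a length-T stationary panel, then fit each
    window size once at a fixed anchor (the series end).  Reports bias and
    RMSE of every estimated coefficient against the generating values.
    ``covariate_factory(seed)`` regenerates covariates per replicate when
    the generating model has environmental drivers.
    """
    sizes = sorted(int(s) for s in sizes)
    if any(s >= T for s in sizes):
        raise InputError("every window size must be smaller than T")
    p, q = params.p, params.q
    taxa = taxon_names or [f"taxon{j}" for j in range(p)]
    covs = covariate_names or [f"cov{k}" for k in range(q)]
    if mask is None:
        mask = MaskSpec.full(p, q)

    rng = np.random.default_rng(seed)
    records: dict[tuple[int, str], list[float]] = {}
    for _ in range(n_reps):
        rep_seed = int(rng.integers(0, 2**31 - 1))
        u = covariate_factory(rep_seed) if (q and covariate_factory) else None
        panel = simulate_mar(params, T, u=u, seed=rep_seed, taxon_names=taxa)
        for w in sizes:
            y_w = panel.window(T - w - 1, T)
            u_w = u.window(T - w - 1, T) if u is not None else None
            try:
                fit = fit_mar(y_w, u_w, mask)
            except Exception:
                continue
            for coef, err in _coefficient_errors(
                fit.params, params, mask, taxa, covs
            ).items():
                records.setdefault((w, coef), []).append(err)

    rows = []
    for (w, coef), errs in sorted(records.items()):
        e = np.asarray(errs)
        rows.append({
            "window_size": w, "coefficient": coef,
            "bias": float(e.mean()),
            "rmse": float(np.sqrt(np.mean(e**2))),
            "n_reps": len(e),
        })
    return AccuracyTable(pd.DataFrame(rows))


def transition_bias_experiment(
    cfg: RegimeConfig,
    w: int,
    n_reps: int = 20,
    seed: int = 0,
    mask: Optional[MaskSpec] = None,
    coefficients: Optional[Sequence[tuple[int, int]]] = None,
) -> pd.DataFrame:
    """Signed estimation error while windows traverse the first breakpoint.

    Runs the moving-window fit on ``n_reps`` regime-shift simulations and
    averages, per window-end offset from the breakpoint, the estimate and
    its signed error against the regime value in force at the window end.
    ``coefficients`` selects which (i, j) entries of B to track (default:
    every entry that differs between the first two regimes).
    """
    if not cfg.breakpoints:
        raise InputError("transition_bias_experiment needs at least one breakpoint")
    bp = cfg.breakpoints[0]
    p = cfg.regimes[0].p
    if mask is None:
        mask = MaskSpec.full(p, cfg.regimes[0].q)
    if coefficients is None:
        diff = ~np.isclose(cfg.regimes[0].b, cfg.regimes[1].b)
        coefficients = [tuple(ij) for ij in np.argwhere(diff)]
        if not coefficients:
            coefficients = [(i, i) for i in range(p)]

    rng = np.random.default_rng(seed)
    taxa = cfg.taxon_names or [f"taxon{j}" for j in range(p)]
    rows = []
    for _ in range(n_reps):
        rep_cfg = RegimeConfig(
            regimes=cfg.regimes, breakpoints=cfg.breakpoints, T=cfg.T,
            x0=cfg.x0, covariates=cfg.covariates,
            seed=int(rng.integers(0, 2**31 - 1)), taxon_names=cfg.taxon_names,
        )
        panel, covars, truth = simulate_regime_shift(rep_cfg)
        traj = moving_window_fit(panel, covars, mask, w)
        times = list(panel.times)
        for r in traj.results:
            if not r.ok:
                continue
            end_pos = times.index(r.end_time)
            for (i, j) in coefficients:
                true_now = truth.params_at(end_pos).b[i, j]
                est = r.fit.params.b[i, j]
                rows.append({
                    "offset": end_pos - bp,
                    "coefficient": f"b:{taxa[i]}<-{taxa[j]}",
                    "estimate": est,
                    "error": est - true_now,
                })
    raw = pd.DataFrame(rows)
    prof = (
        raw.groupby(["offset", "coefficient"], as_index=False)
        .agg(mean_estimate=("estimate", "mean"),
             mean_error=("error", "mean"),
             sd_error=("error", "std"),
             n=("error", "size"))
    )
    prof["se_error"] = prof.sd_error / np.sqrt(prof.n)
    return prof
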