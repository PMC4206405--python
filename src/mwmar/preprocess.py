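"""Raw observations -> model-ready monthly panels.

Field data arrive at irregular intervals and in native units.  The model
consumes (i) natural-log abundances on a contiguous monthly grid and
(ii) standardized covariates, with temperature split into a long-term
seasonal climatology ("season") and the deviations from it ("anomaly") so
that seasonal forcing and short-term/trend signals get separate
coefficients.

Zero abundances have no logarithm; the default policy adds a per-taxon
offset delta = half the smallest positive observed value before logging
(ln(x + delta)) only when zeros are present.  Alternatives: treat zero
months as missing, or a fixed user-supplied delta.  The chosen policy and
the delta actually used are recorded so a run is reproducible.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import InputError
from .panels import AbundancePanel, CovariatePanel, as_time_index

__all__ = [
    "SeasonalDecomposition",
    "aggregate_monthly",
    "log_abundance",
    "seasonal_decompose",
    "standardize",
    "build_covariate_panel",
]


def aggregate_monthly(raw: pd.DataFrame) -> pd.DataFrame:
    """Aggregate long-format samples into monthly means.

    ``raw`` has columns (timestamp, variable, value).  Each (year-month,
    variable) cell is the arithmetic mean of that month's samples; months
    with no samples are NaN, and the output index is contiguous from the
    first to the last observed month.
    """
    for col in ("timestamp", "variable", "value"):
        if col not in raw.columns:
            raise InputError(f"raw samples need a {col!r} column")
    try:
        ts = pd.to_datetime(raw["timestamp"])
    except (ValueError, TypeError) as exc:
        raise InputError(f"unparseable timestamps: {exc}") from exc
    months = ts.dt.to_period("M")
    wide = (
        raw.assign(_month=months)
        .pivot_table(index="_month", columns="variable", values="value",
                     aggfunc="mean")
    )
    full = pd.period_range(wide.index.min(), wide.index.max(), freq="M")
    wide = wide.reindex(full)
    wide.index.name = "month"
    wide.columns.name = None
    return wide


def log_abundance(
    x: pd.DataFrame,
    zero_policy: str = "offset",
    delta: float | None = None,
) -> tuple[AbundancePanel, dict]:
    """Natural-log transform a monthly abundance panel.

    zero_policy:
      * ``"offset"`` (default): per taxon, if zeros are present, use
        ln(x + delta) with delta = half the smallest positive observed
        value for that taxon; taxa without zeros are logged directly.
      * ``"missing"``: zero months become missing (casewise-deleted
        downstream).
      * ``"fixed"``: ln(x + delta) with the supplied delta, everywhere
        zeros occur (delta required).

    Returns the panel and a metadata dict recording the policy and the
    per-taxon deltas applied.
    """
    if (x.to_numpy() < 0).any():
        raise InputError("abundances must be nonnegative")
    if zero_policy not in ("offset", "missing", "fixed"):
        raise InputError(f"unknown zero_policy {zero_policy!r}")
    if zero_policy == "fixed" and (delta is None or delta <= 0):
        raise InputError("zero_policy='fixed' requires a positive delta")

    out = pd.DataFrame(index=x.index, columns=x.columns, dtype=float)
    deltas: dict[str, float] = {}
    for name in x.columns:
        col = x[name].astype(float)
        has_zero = (col == 0).any()
        if not has_zero:
            out[name] = np.log(col)
            continue
        if zero_policy == "missing":
            col = col.where(col > 0)
            out[name] = np.log(col)
        else:
            if zero_policy == "offset":
                pos = col[col > 0]
                if pos.empty:
                    raise InputError(f"taxon {name!r} has no positive observations")
                d = float(pos.min()) / 2.0
            else:
                d = float(delta)
            deltas[name] = d
            out[name] = np.log(col + d)
    meta = {"zero_policy": zero_policy, "deltas": deltas}
    return AbundancePanel(out), meta


@dataclass
class SeasonalDecomposition:
    """Calendar-month climatology and the per-observation anomalies.

    ``climatology[m]`` (m = 1..12) is the long-term mean of all
    observations in calendar month m (NaN and flagged if a month is never
    observed); ``anomalies`` are value - climatology[month], so within each
    calendar month the anomalies over the record sum to zero.
    """

    climatology: pd.Series          # index 1..12
    anomalies: pd.Series            # original monthly index
    missing_months: list[int] = field(default_factory=list)

    def expand_climatology(self) -> pd.Series:
        """Climatology value at every time step of the original index."""
        months = self.anomalies.index.month
        return pd.Series(
            self.climatology.reindex(months).to_numpy(),
            index=self.anomalies.index,
            name="climatology",
        )

    def reconstruct(self) -> pd.Series:
        """climatology expansion + anomalies == original series."""
        return self.expand_climatology() + self.anomalies


def seasonal_decompose(series: pd.Series) -> SeasonalDecomposition:
    """Split a monthly series into calendar-month means and deviations."""
    idx = as_time_index(series.index)
    if not isinstance(idx, pd.PeriodIndex):
        raise InputError("seasonal decomposition needs a monthly (year-month) index")
    s = pd.Series(series.to_numpy(dtype=float), index=idx)
    clim = s.groupby(s.index.month).mean()
    clim = clim.reindex(range(1, 13))
    missing = [int(m) for m in clim.index[clim.isna()]]
    anomalies = s - clim.reindex(s.index.month).to_numpy()
    return SeasonalDecomposition(
        climatology=clim, anomalies=anomalies, missing_months=missing
    )


def standardize(series: pd.Series, name: str | None = None) -> pd.Series:
    """Center and scale to sample SD 1 (n-1 divisor) over observed entries.

    Missing entries are preserved in place; the moments come from the
    observed values only.
    """
    label = name or series.name or "series"
    obs = series.dropna()
    if len(obs) < 2:
        raise InputError(f"covariate {label!r}: need at least 2 observed values")
    sd = obs.std(ddof=1)
    if sd == 0 or not np.isfinite(sd):
        raise InputError(f"covariate {label!r} has zero variance")
    return (series - obs.mean()) / sd


def build_covariate_panel(
    temperature: pd.Series,
    phosphorus: pd.Series,
) -> tuple[CovariatePanel, SeasonalDecomposition]:
    """Assemble the standard q=3 covariate panel.

    Columns, in order: ``season`` (the temperature climatology expanded
    over time, then standardized — a periodic 12-level seasonal-forcing
    signal), ``temp_anomaly`` (standardized deviations from the
    climatology) and ``total_phosphorus`` (standardized raw series).
    """
    if len(temperature) != len(phosphorus) or not (
        as_time_index(temperature.index) == as_time_index(phosphorus.index)
    ).all():
        raise InputError("temperature and phosphorus must share the month index")
    dec = seasonal_decompose(temperature)
    season = standardize(dec.expand_climatology(), "season")
    anom = standardize(dec.anomalies, "temp_anomaly")
    phos = standardize(
        pd.Series(phosphorus.to_numpy(dtype=float),
                  index=as_time_index(phosphorus.index)),
        "total_phosphorus",
    )
    frame = pd.DataFrame({
        "season": season,
        "temp_anomaly": anom,
        "total_phosphorus": phos,
    })
    return CovariatePanel(frame), dec
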