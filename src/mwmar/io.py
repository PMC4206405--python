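"""File I/O, run configuration and the default lake mask.

Input panels are wide monthly CSVs: a date column (YYYY-MM or any
parseable date) plus numeric columns, with a schema naming which columns
are taxa and which are covariates.  Blanks are missing values; a skipped
month becomes a missing row so the index stays contiguous.  Trajectories
are written long-format, keyed by window END time.

Masks are configured by NAME pairs (response, predictor) rather than by
index, so a reordered input file cannot silently flip an exclusion.
"""
from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from .errors import InputError
from .panels import AbundancePanel, CovariatePanel, MaskSpec
from .window import Trajectory, trajectory_to_table

__all__ = [
    "RunConfig",
    "read_panel_csv",
    "write_trajectory_csv",
    "read_trajectory_csv",
    "default_lake_washington_mask",
    "mask_from_names",
    "write_metadata",
]

LW_TAXA = ["DG", "NDC", "Daphnia", "Oscillatoria"]
LW_COVARIATES = ["season", "temp_anomaly", "total_phosphorus"]


def mask_from_names(
    taxa: list[str],
    covariates: list[str],
    exclude_b: list[tuple[str, str]] = (),
    exclude_c: list[tuple[str, str]] = (),
) -> MaskSpec:
    """Build a MaskSpec from (response, predictor) exclusion name pairs."""
    p, q = len(taxa), len(covariates)
    b = np.ones((p, p), dtype=bool)
    c = np.ones((p, q), dtype=bool)
    for resp, pred in exclude_b:
        if resp not in taxa or pred not in taxa:
            raise InputError(f"unknown taxon in B exclusion ({resp}, {pred})")
        i, j = taxa.index(resp), taxa.index(pred)
        if i == j:
            raise InputError("density dependence (diagonal of B) cannot be excluded")
        b[i, j] = False
    for resp, pred in exclude_c:
        if resp not in taxa:
            raise InputError(f"unknown taxon in C exclusion: {resp}")
        if pred not in covariates:
            raise InputError(f"unknown covariate in C exclusion: {pred}")
        c[taxa.index(resp), covariates.index(pred)] = False
    return MaskSpec(b, c)


def default_lake_washington_mask() -> MaskSpec:
    """The a-priori inclusion scheme for the 4-guild lake food web.

    Community matrix: every link estimated except the NDC effect on
    diatoms/greens (15 of 16 cells).  Covariates: season and temperature
    anomaly act on all four guilds; total phosphorus acts only on the
    phytoplankton groups (DG, Oscillatoria) — nutrients cannot directly
    affect zooplankton (10 of 12 cells).
    """
    return mask_from_names(
        LW_TAXA,
        LW_COVARIATES,
        exclude_b=[("DG", "NDC")],
        exclude_c=[("NDC", "total_phosphorus"), ("Daphnia", "total_phosphorus")],
    )


@dataclass
class RunConfig:
    """Everything needed to reproduce a run, serializable to YAML/JSON."""

    window: int = 84
    n_boot: int = 2000
    level: float = 0.95
    seed: int = 0
    error_draws: str = "resample"
    zero_policy: str = "offset"
    alpha: float = 0.05
    taxa: list[str] = field(default_factory=lambda: list(LW_TAXA))
    covariates: list[str] = field(default_factory=lambda: list(LW_COVARIATES))
    exclude_b: list = field(default_factory=lambda: [["DG", "NDC"]])
    exclude_c: list = field(default_factory=lambda: [
        ["NDC", "total_phosphorus"], ["Daphnia", "total_phosphorus"]])

    def mask(self) -> MaskSpec:
        return mask_from_names(
            self.taxa, self.covariates,
            [tuple(x) for x in self.exclude_b],
            [tuple(x) for x in self.exclude_c],
        )

    def to_dict(self) -> dict:
        return asdict(self)

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]

    @classmethod
    def from_file(cls, path) -> "RunConfig":
        import yaml

        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(data) - known
        if unknown:
            raise InputError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)


def read_panel_csv(
    path,
    taxa: list[str],
    covariates: Optional[list[str]] = None,
    date_column: str = "date",
) -> tuple[AbundancePanel, Optional[CovariatePanel]]:
    """Read a wide monthly CSV into abundance and covariate panels.

    The date column accepts YYYY-MM labels or any parseable date; months
    missing from the file are inserted as missing rows so the index is
    contiguous.  Unknown or missing declared columns, duplicate months and
    non-numeric cells are input errors carrying row numbers.
    """
    frame = pd.read_csv(path)
    if date_column not in frame.columns:
        raise InputError(f"missing date column {date_column!r} in {path}")
    covariates = list(covariates or [])
    for col in list(taxa) + covariates:
        if col not in frame.columns:
            raise InputError(f"declared column {col!r} not present in {path}")
    try:
        months = pd.PeriodIndex(
            pd.to_datetime(frame[date_column].astype(str)), freq="M"
        )
    except (ValueError, TypeError):
        try:
            months = pd.PeriodIndex(frame[date_column].astype(str), freq="M")
        except Exception as exc:
            raise InputError(f"unparseable dates in {date_column!r}: {exc}") from exc
    dup = months.duplicated()
    if dup.any():
        row = int(np.flatnonzero(dup)[0]) + 2  # header + 1-based
        raise InputError(f"duplicate month {months[dup][0]} at row {row}")
    body = frame[list(taxa) + covariates].copy()
    for col in body.columns:
        try:
            body[col] = pd.to_numeric(body[col])
        except (ValueError, TypeError):
            bad = pd.to_numeric(body[col], errors="coerce")
            row = int(np.flatnonzero(bad.isna() & body[col].notna())[0]) + 2
            raise InputError(f"non-numeric value in column {col!r} at row {row}")
    body.index = months
    full = pd.period_range(months.min(), months.max(), freq="M")
    body = body.reindex(full)
    y = AbundancePanel(body[list(taxa)])
    u = CovariatePanel(body[covariates]) if covariates else None
    return y, u


def write_panel_csv(path, y: AbundancePanel, u: Optional[CovariatePanel] = None,
                    date_column: str = "date") -> None:
    """Write panels back to the wide monthly CSV layout."""
    frame = y.frame.copy()
    if u is not None:
        y.check_aligned(u)
        frame = pd.concat([frame, u.frame], axis=1)
    out = frame.reset_index()
    out.columns = [date_column] + list(frame.columns)
    out[date_column] = out[date_column].astype(str)
    out.to_csv(path, index=False)


def write_trajectory_csv(tr: Trajectory, path) -> pd.DataFrame:
    """Write the long-format trajectory table (rows keyed by window end)."""
    table = trajectory_to_table(tr)
    out = table.copy()
    out["end_time"] = out["end_time"].astype(str)
    out.to_csv(path, index=False)
    return table


def read_trajectory_csv(path) -> pd.DataFrame:
    return pd.read_csv(path)


def write_metadata(path, config: RunConfig, extra: Optional[dict] = None) -> dict:
    """Write the reproducibility metadata JSON next to a run's outputs."""
    import mwmar

    meta = {
        "package": "mwmar",
        "version": mwmar.__version__,
        "config": config.to_dict(),
        "config_hash": config.config_hash(),
    }
    if extra:
        meta.update(extra)
    Path(path).write_text(json.dumps(meta, indent=2, default=str))
    return meta
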