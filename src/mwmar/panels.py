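"""Time-indexed data containers for community MAR modelling.

An :class:`AbundancePanel` holds a T x p matrix of natural-log abundances,
one column per taxon, on a strictly increasing, equally spaced time index
(monthly ``pandas.PeriodIndex`` or plain integer steps).  Missing
observations are NaN and stay NaN — they are never silently zeroed; the
estimator decides per equation which regression rows to drop.

A :class:`CovariatePanel` holds the standardized environmental drivers
(T x q) on the same index.  A :class:`MaskSpec` records which interaction
(B) and covariate-effect (C) coefficients are estimated at all: a False
cell is an a-priori exclusion and the coefficient is pinned to exactly 0.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import InputError

__all__ = [
    "AbundancePanel",
    "CovariatePanel",
    "MaskSpec",
    "as_time_index",
]


def as_time_index(times) -> pd.Index:
    """Coerce ``times`` to a supported index (monthly periods or integers).

    Strings like ``"1962-01"`` become a monthly ``PeriodIndex``; integer
    sequences stay integer.  Anything else must already be an Index.
    """
    if isinstance(times, (pd.PeriodIndex, pd.RangeIndex)):
        return times
    if isinstance(times, pd.DatetimeIndex):
        return times.to_period("M")
    arr = pd.Index(times)
    if arr.dtype == object or str(arr.dtype).startswith("string"):
        return pd.PeriodIndex(arr, freq="M")
    if pd.api.types.is_integer_dtype(arr.dtype):
        return arr
    if isinstance(arr, pd.PeriodIndex):
        return arr
    raise InputError(f"unsupported time index type: {arr.dtype}")


def _check_regular(index: pd.Index, what: str) -> None:
    if len(index) == 0:
        raise InputError(f"{what}: empty time index")
    if index.has_duplicates:
        dup = index[index.duplicated()][0]
        raise InputError(f"{what}: duplicate time label {dup}")
    if isinstance(index, pd.PeriodIndex):
        steps = np.diff(index.asi8)
    else:
        steps = np.diff(np.asarray(index, dtype=np.int64))
    if len(steps) and not np.all(steps == steps[0]):
        raise InputError(f"{what}: time index not equally spaced")
    if len(steps) and steps[0] <= 0:
        raise InputError(f"{what}: time index not strictly increasing")


class _Panel:
    """Shared behaviour of abundance and covariate panels."""

    _kind = "panel"

    def __init__(self, values, times=None, names=None):
        if isinstance(values, pd.DataFrame):
            frame = values.copy()
            if times is not None:
                frame.index = as_time_index(times)
            else:
                frame.index = as_time_index(frame.index)
            if names is not None:
                frame.columns = list(names)
        else:
            arr = np.asarray(values, dtype=float)
            if arr.ndim == 1:
                arr = arr[:, None]
            if times is None:
                times = pd.RangeIndex(arr.shape[0])
            if names is None:
                names = [f"{self._kind}{j}" for j in range(arr.shape[1])]
            frame = pd.DataFrame(arr, index=as_time_index(times), columns=list(names))
        frame = frame.astype(float)
        _check_regular(frame.index, self._kind)
        if frame.shape[1] < 1:
            raise InputError(f"{self._kind}: needs at least one column")
        self.frame = frame

    # -- convenience accessors -------------------------------------------
    @property
    def values(self) -> np.ndarray:
        return self.frame.to_numpy()

    @property
    def times(self) -> pd.Index:
        return self.frame.index

    @property
    def n_times(self) -> int:
        return self.frame.shape[0]

    def __len__(self) -> int:
        return self.frame.shape[0]

    def window(self, start: int, stop: int):
        """Positional slice [start, stop) as a new panel of the same type."""
        return type(self)(self.frame.iloc[start:stop])

    def shift_times(self, offset: int):
        """Return a copy with every time label shifted by ``offset`` steps."""
        idx = self.frame.index
        new = idx + offset
        out = self.frame.copy()
        out.index = new
        return type(self)(out)

    def check_aligned(self, other: "_Panel") -> None:
        if len(self.times) != len(other.times) or not (self.times == other.times).all():
            raise InputError(
                f"time indices of {self._kind} and {other._kind} do not coincide"
            )

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        t0, t1 = self.times[0], self.times[-1]
        return (
            f"<{type(self).__name__} {self.frame.shape[0]}x{self.frame.shape[1]} "
            f"[{t0} .. {t1}]>"
        )


class AbundancePanel(_Panel):
    """T x p matrix of log-transformed abundances on a regular time grid."""

    _kind = "abundance"

    @property
    def taxon_names(self) -> list[str]:
        return list(self.frame.columns)

    @property
    def n_taxa(self) -> int:
        return self.frame.shape[1]


class CovariatePanel(_Panel):
    """T x q matrix of (standardized) environmental covariates."""

    _kind = "covariate"

    @property
    def covariate_names(self) -> list[str]:
        return list(self.frame.columns)

    @property
    def n_covariates(self) -> int:
        return self.frame.shape[1]

    def check_standardized(self, tol: float = 1e-8) -> None:
        """Each column must have mean 0 and sample SD 1 over observed entries."""
        for name in self.frame.columns:
            col = self.frame[name].dropna()
            if len(col) < 2:
                raise InputError(f"covariate {name!r}: fewer than 2 observed values")
            if abs(col.mean()) > tol or abs(col.std(ddof=1) - 1.0) > tol:
                raise InputError(
                    f"covariate {name!r} is not standardized "
                    f"(mean={col.mean():.3g}, sd={col.std(ddof=1):.3g})"
                )


@dataclass
class MaskSpec:
    """Boolean inclusion masks for the B (p x p) and C (p x q) matrices.

    ``True`` means the coefficient is estimated; ``False`` pins it to zero.
    Row = responding taxon, column = acting taxon / covariate.  The diagonal
    of ``b_mask`` is always estimated — density dependence is never excluded.
    """

    b_mask: np.ndarray
    c_mask: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self):
        self.b_mask = np.asarray(self.b_mask, dtype=bool)
        if self.b_mask.ndim != 2 or self.b_mask.shape[0] != self.b_mask.shape[1]:
            raise InputError("b_mask must be square (p x p)")
        p = self.b_mask.shape[0]
        if not np.all(np.diag(self.b_mask)):
            raise InputError("diagonal of b_mask must be all True (density dependence)")
        if self.c_mask is None:
            self.c_mask = np.zeros((p, 0), dtype=bool)
        else:
            self.c_mask = np.asarray(self.c_mask, dtype=bool)
            if self.c_mask.ndim != 2 or self.c_mask.shape[0] != p:
                raise InputError("c_mask must have shape (p, q)")

    @classmethod
    def full(cls, p: int, q: int = 0) -> "MaskSpec":
        """All coefficients estimated."""
        return cls(np.ones((p, p), bool), np.ones((p, q), bool))

    @property
    def p(self) -> int:
        return self.b_mask.shape[0]

    @property
    def q(self) -> int:
        return self.c_mask.shape[1]

    def n_coefficients(self) -> int:
        """Estimated coefficients per window: intercepts + B cells + C cells."""
        return self.p + int(self.b_mask.sum()) + int(self.c_mask.sum())

    def check_shapes(self, y: AbundancePanel, u: CovariatePanel | None) -> None:
        if self.p != y.n_taxa:
            raise InputError(
                f"b_mask is {self.p}x{self.p} but panel has {y.n_taxa} taxa"
            )
        q = 0 if u is None else u.n_covariates
        if self.q != q:
            raise InputError(f"c_mask has {self.q} columns but panel has {q} covariates")
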