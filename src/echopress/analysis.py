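"""Pressure analysis: Pearson correlation with exact small-sample significance,
ordinary least-squares trend fits, and the Laplace-law stress utility.

Correlations are computed on per-IOP means (n = number of pressure levels,
five in the default design).  Significance uses the exact transform

    t = r sqrt((n - 2) / (1 - r^2)),   df = n - 2,

with a two-sided p-value from the Student t distribution — the standard
small-sample test for a Pearson coefficient under bivariate normality.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

from .exceptions import AnalysisError

__all__ = [
    "MMHG_TO_PA",
    "PressureSeries",
    "CorrelationResult",
    "pearson_r",
    "pearson_p_two_sided",
    "linear_fit",
    "laplace_stress",
    "correlate_with_iop",
]

MMHG_TO_PA = 133.322  # pascal per mmHg


@dataclass(frozen=True)
class PressureSeries:
    """Per-pressure aggregated values of one quantity.

    iops in mmHg (strictly increasing); values are the per-level means
    (amplitude in arbitrary units, impedance in MRayl, or time in s);
    sds the matching dispersions; quantity a label such as "Z2".
    """

    iops: tuple[float, ...]
    values: tuple[float, ...]
    sds: tuple[float, ...]
    quantity: str = ""

    def __init__(
        self,
        iops: Sequence[float],
        values: Sequence[float],
        sds: Sequence[float] | None = None,
        quantity: str = "",
    ) -> None:
        iops = tuple(float(p) for p in iops)
        values = tuple(float(v) for v in values)
        sds = tuple(float(s) for s in (sds if sds is not None else [0.0] * len(values)))
        if not (len(iops) == len(values) == len(sds)):
            raise AnalysisError("iops, values and sds must have equal length")
        if any(b <= a for a, b in zip(iops, iops[1:])):
            raise AnalysisError("iops must be strictly increasing")
        object.__setattr__(self, "iops", iops)
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "sds", sds)
        object.__setattr__(self, "quantity", quantity)

    def __len__(self) -> int:
        return len(self.iops)


@dataclass(frozen=True)
class CorrelationResult:
    """Pearson correlation of one quantity with IOP, plus its linear trend."""

    quantity: str
    r: float
    n: int
    t_stat: float
    df: int
    p_two_sided: float
    slope: float
    intercept: float

    def as_dict(self) -> dict:
        return {
            "quantity": self.quantity,
            "r": self.r,
            "n": self.n,
            "t": self.t_stat,
            "df": self.df,
            "p": self.p_two_sided,
            "slope": self.slope,
            "intercept": self.intercept,
        }


def _as_1d(x: Sequence[float], name: str) -> np.ndarray:
    arr = np.asarray(x, dtype=float)
    if arr.ndim != 1:
        raise AnalysisError(f"{name} must be one-dimensional")
    return arr


def pearson_r(x: Sequence[float], y: Sequence[float]) -> float:
    """Product-moment correlation coefficient, clipped to [-1, 1].

    Computed directly from centred sums; raises for length mismatch,
    n < 3, or a constant input (undefined correlation).
    """
    xa, ya = _as_1d(x, "x"), _as_1d(y, "y")
    if xa.size != ya.size:
        raise AnalysisError(f"length mismatch: {xa.size} vs {ya.size}")
    if xa.size < 3:
        raise AnalysisError(f"need n >= 3 points, got {xa.size}")
    dx, dy = xa - xa.mean(), ya - ya.mean()
    sx, sy = np.sqrt(np.sum(dx**2)), np.sqrt(np.sum(dy**2))
    if sx == 0 or sy == 0:
        raise AnalysisError("correlation undefined for a constant input")
    return float(np.clip(np.sum(dx * dy) / (sx * sy), -1.0, 1.0))


def pearson_p_two_sided(r: float, n: int) -> float:
    """Two-sided p-value of a Pearson r via the exact t transform.

    t = r sqrt((n-2)/(1-r^2)) with df = n - 2.  For |r| = 1 the limit
    p = 0 is returned with a RuntimeWarning (the statistic diverges).
    Strictly decreasing in |r| at fixed n.
    """
    if n < 3:
        raise AnalysisError(f"need n >= 3, got {n}")
    if not -1.0 <= r <= 1.0:
        raise AnalysisError(f"|r| must be <= 1, got {r}")
    df = n - 2
    if abs(r) == 1.0:
        warnings.warn("|r| = 1: returning the limiting p = 0", RuntimeWarning)
        return 0.0
    t = r * np.sqrt(df / (1.0 - r * r))
    return float(2.0 * stats.t.sf(abs(t), df))


def linear_fit(series: PressureSeries) -> tuple[float, float, np.ndarray]:
    """Ordinary least squares of value on IOP: (slope, intercept, fitted values)."""
    if len(series) < 2:
        raise AnalysisError("need at least 2 points for a linear fit")
    x = np.asarray(series.iops)
    y = np.asarray(series.values)
    res = stats.linregress(x, y)
    return float(res.slope), float(res.intercept), res.slope * x + res.intercept


def laplace_stress(pressure_mmHg: float, radius: float, thickness: float) -> float:
    """Thin-shell hoop stress sigma = P R / (2 t) in pascal.

    pressure in mmHg (converted at 133.322 Pa/mmHg), radius and thickness
    in metres.
    """
    if pressure_mmHg < 0:
        raise ValueError("pressure must be >= 0")
    if radius <= 0:
        raise ValueError("radius must be > 0")
    if thickness <= 0:
        raise ValueError("thickness must be > 0")
    return pressure_mmHg * MMHG_TO_PA * radius / (2.0 * thickness)


def correlate_with_iop(series: PressureSeries) -> CorrelationResult:
    """Pearson r, exact two-sided p, and OLS trend of one quantity vs IOP."""
    if len(series) < 3:
        raise AnalysisError("need at least 3 pressure levels for correlation")
    r = pearson_r(series.iops, series.values)
    n = len(series)
    df = n - 2
    if abs(r) == 1.0:
        t = float("inf")
        p = 0.0
    else:
        t = float(r * np.sqrt(df / (1.0 - r * r)))
        p = pearson_p_two_sided(r, n)
    slope, intercept, _ = linear_fit(series)
    return CorrelationResult(
        quantity=series.quantity, r=r, n=n, t_stat=t, df=df,
        p_two_sided=p, slope=slope, intercept=intercept,
    )
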