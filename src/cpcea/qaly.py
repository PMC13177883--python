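"""QALY computation and discounting primitives.

Quality-adjusted life years are obtained from a utility trajectory by the
area-under-the-curve method with linear interpolation between assessments
(the trapezoidal rule).  The short-term analysis measures EQ-5D-Y utility at
0, 6 and 12 months, so a one-year QALY is

    QALY = 0.25 * u(0) + 0.5 * u(6m) + 0.25 * u(12m).

Discounting converts future costs and QALYs to present value at an annual
rate r (default 3%), end-of-cycle timing: cycle t contributes with factor
(1 + r)^-t, t = 1, 2, ...
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import InputError


@dataclass(frozen=True)
class UtilityTrajectory:
    """Utility measurements over time (years).

    Utilities may be negative (worse-than-dead EQ-5D-Y states) but never exceed 1.
    """

    times: tuple[float, ...] = (0.0, 0.5, 1.0)
    utilities: tuple[float, ...] = (1.0, 1.0, 1.0)

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        u = np.asarray(self.utilities, dtype=float)
        if t.size < 2:
            raise InputError("a utility trajectory needs at least 2 assessment points")
        if t.size != u.size:
            raise InputError("times and utilities must have equal length")
        if not np.all(np.diff(t) > 0):
            raise InputError("assessment times must be strictly increasing")
        if np.any(u > 1.0 + 1e-12):
            raise InputError("utilities cannot exceed 1 (full health)")


def auc_qaly(traj: UtilityTrajectory) -> float:
    """Area under the utility curve (trapezoidal rule) in QALYs."""
    return float(np.trapezoid(traj.utilities, traj.times))


def qaly_from_measurements(u0: float, u6: float, u12: float) -> float:
    """One-year QALY from utilities at baseline, 6 and 12 months."""
    return auc_qaly(UtilityTrajectory((0.0, 0.5, 1.0), (u0, u6, u12)))


def add_qaly_column(cohort: pd.DataFrame, column: str = "qaly") -> pd.DataFrame:
    """Return a copy of a cohort table with an AUC-derived ``qaly`` column.

    Vectorized equivalent of :func:`qaly_from_measurements` applied row-wise to
    the u0/u6/u12 columns.
    """
    for col in ("u0", "u6", "u12"):
        if col not in cohort.columns:
            raise InputError(f"cohort table lacks utility column {col!r}")
    out = cohort.copy()
    out[column] = 0.25 * out["u0"] + 0.5 * out["u6"] + 0.25 * out["u12"]
    return out


@dataclass(frozen=True)
class DiscountSpec:
    """Annual discounting specification (end-of-cycle timing)."""

    annual_rate: float = 0.03
    timing: str = "end_of_cycle"

    def __post_init__(self) -> None:
        if self.annual_rate < 0:
            raise InputError("discount annual_rate must be >= 0")
        if self.timing != "end_of_cycle":
            raise InputError(f"unsupported discount timing {self.timing!r}")


def discount_factor(spec: DiscountSpec, cycle: int) -> float:
    """Present-value factor (1 + r)^-cycle for cycle >= 1."""
    if cycle < 1:
        raise InputError("cycle must be >= 1 (end-of-cycle discounting)")
    return float((1.0 + spec.annual_rate) ** (-cycle))


def discount_factors(spec: DiscountSpec, horizon: int) -> np.ndarray:
    """Vector of factors for cycles 1..horizon."""
    if horizon < 1:
        raise InputError("horizon must be >= 1")
    cycles = np.arange(1, horizon + 1)
    return (1.0 + spec.annual_rate) ** (-cycles.astype(float))


def discounted_sum(values: Sequence[float], spec: DiscountSpec) -> float:
    """Sum of per-cycle values discounted end-of-cycle.

    ``values[0]`` is cycle 1.  An empty sequence sums to 0; rate 0 reduces to
    the plain sum.
    """
    v = np.asarray(values, dtype=float)
    if v.size == 0:
        return 0.0
    return float(v @ discount_factors(spec, v.size))


def annuity_factor(spec: DiscountSpec, horizon: int) -> float:
    """Present value of 1 per cycle for ``horizon`` cycles.

    Closed form (1 - (1+r)^-T) / r, reducing to T at r = 0.  At r = 3%,
    T = 30 this is 19.6004 -- the discounted QALY total of an individual in
    full health for 30 annual cycles.
    """
    if horizon < 1:
        raise InputError("horizon must be >= 1")
    r = spec.annual_rate
    if r == 0:
        return float(horizon)
    # expm1/log1p keep the small-r limit (-> horizon) numerically stable
    return float(-np.expm1(-horizon * np.log1p(r)) / r)
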