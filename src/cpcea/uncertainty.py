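"""Probabilistic sensitivity analysis: CEACs, confidence ellipses, bootstrap.

Uncertainty around an incremental (cost, effect) pair is summarised three ways:

* **CEAC** -- the cost-effectiveness acceptability curve gives, for each
  willingness-to-pay threshold lambda, the probability that the net monetary
  benefit ``lambda * delta_effect - delta_cost`` is positive.  Parametrically
  (from a SUR fit's coefficient covariance) this is
  ``Phi((lambda mu_e - mu_c) / sqrt(lambda^2 s_e^2 - 2 lambda s_ce + s_c^2))``;
  nonparametrically it is the fraction of PSA draws with positive net benefit.
* **Confidence ellipse** -- the bivariate-normal contour containing 50/75/95%
  of the (delta_cost, delta_effect) distribution; the boundary lies at squared
  Mahalanobis distance equal to the chi-square(2 df) quantile of the level.
* **Bootstrap** -- nonparametric resampling of individuals (stratified by
  treatment arm, preserving the design) with the full estimation pipeline
  re-run on each resample.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import EstimationError, InputError
from .sure import SureFit

#: Default willingness-to-pay grid, EUR/QALY (covers the Spanish 25k-60k range).
DEFAULT_WTP_GRID = tuple(float(x) for x in range(0, 100_001, 1_000))


@dataclass(frozen=True)
class CeacCurve:
    """Acceptability probabilities over a willingness-to-pay grid."""

    label: str
    wtp_grid: np.ndarray
    probabilities: np.ndarray

    def __post_init__(self) -> None:
        grid = np.asarray(self.wtp_grid, dtype=float)
        p = np.asarray(self.probabilities, dtype=float)
        if grid.size != p.size:
            raise InputError("wtp_grid and probabilities must have equal length")
        if grid.size and not np.all(np.diff(grid) > 0):
            raise InputError("wtp_grid must be strictly increasing")
        if np.any(p < -1e-12) or np.any(p > 1 + 1e-12):
            raise InputError("probabilities must lie in [0, 1]")
        object.__setattr__(self, "wtp_grid", grid)
        object.__setattr__(self, "probabilities", p)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"wtp": self.wtp_grid, "probability": self.probabilities}
        )


@dataclass(frozen=True)
class EllipsePath:
    """Closed boundary polyline of a bivariate confidence ellipse.

    ``boundary`` columns are (delta_cost, delta_effect); the first and last
    points coincide.
    """

    center: tuple[float, float]
    level: float
    boundary: np.ndarray


@dataclass(frozen=True)
class PsaDraws:
    """Draws of (delta_cost, delta_effect) pairs from a PSA."""

    draws: np.ndarray  # B x 2
    source: str  # {"parametric", "bootstrap"}
    n_failures: int = 0

    def __post_init__(self) -> None:
        d = np.atleast_2d(np.asarray(self.draws, dtype=float))
        if d.shape[0] < 1 or d.shape[1] != 2:
            raise InputError("draws must be a non-empty B x 2 array")
        if not np.all(np.isfinite(d)):
            raise InputError("draws must be finite")
        object.__setattr__(self, "draws", d)

    @property
    def b(self) -> int:
        return self.draws.shape[0]


def _nmb_probability(
    wtp: np.ndarray, mu: np.ndarray, cov: np.ndarray
) -> np.ndarray:
    """P(net monetary benefit > 0) under bivariate normal (delta_cost, delta_effect)."""
    mu_c, mu_e = mu
    s_c2, s_e2 = cov[0, 0], cov[1, 1]
    s_ce = cov[0, 1]
    mean_nmb = wtp * mu_e - mu_c
    var_nmb = wtp**2 * s_e2 - 2.0 * wtp * s_ce + s_c2
    if np.any(var_nmb < -1e-9):
        raise InputError("covariance block is not positive semidefinite")
    sd = np.sqrt(np.maximum(var_nmb, 0.0))
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(sd > 0, mean_nmb / np.where(sd > 0, sd, 1.0), np.nan)
    p = stats.norm.cdf(z)
    # Degenerate (zero-variance) limit: a step at NMB = 0.
    degenerate = sd == 0
    p = np.where(degenerate, np.where(mean_nmb > 0, 1.0, np.where(mean_nmb < 0, 0.0, 0.5)), p)
    return p


def ceac_parametric(
    fit: SureFit,
    therapy: str,
    wtp_grid: Sequence[float] = DEFAULT_WTP_GRID,
) -> CeacCurve:
    """CEAC from the SUR coefficient covariance (bivariate-normal closed form)."""
    mu, cov = fit.delta_block(therapy)
    if cov[0, 0] < 0 or cov[1, 1] < 0 or abs(cov[0, 1]) > np.sqrt(
        max(cov[0, 0] * cov[1, 1], 0.0)
    ) + 1e-9:
        raise InputError("coefficient covariance block is not positive semidefinite")
    grid = np.asarray(wtp_grid, dtype=float)
    return CeacCurve(therapy, grid, _nmb_probability(grid, mu, cov))


def ceac_normal(
    mu: Sequence[float],
    cov: np.ndarray,
    wtp_grid: Sequence[float] = DEFAULT_WTP_GRID,
    label: str = "",
) -> CeacCurve:
    """CEAC for an explicit bivariate-normal (delta_cost, delta_effect)."""
    grid = np.asarray(wtp_grid, dtype=float)
    return CeacCurve(
        label, grid, _nmb_probability(grid, np.asarray(mu, float), np.asarray(cov, float))
    )


def ceac_from_draws(
    draws: PsaDraws,
    wtp_grid: Sequence[float] = DEFAULT_WTP_GRID,
    label: str = "",
) -> CeacCurve:
    """Nonparametric CEAC: fraction of draws with positive net benefit."""
    grid = np.asarray(wtp_grid, dtype=float)
    d_cost = draws.draws[:, 0]
    d_eff = draws.draws[:, 1]
    nmb = grid[:, None] * d_eff[None, :] - d_cost[None, :]
    return CeacCurve(label, grid, (nmb > 0).mean(axis=1))


def confidence_ellipse(
    center: Sequence[float],
    cov2x2: np.ndarray,
    level: float,
    n_points: int = 256,
) -> EllipsePath:
    """Bivariate-normal confidence ellipse boundary.

    boundary = center + sqrt(q) * cov^{1/2} * unit circle, with q the
    chi-square(2 df) quantile of the level (q = 5.9915 at 95%).
    """
    if not 0 < level < 1:
        raise InputError("level must lie in (0, 1)")
    cov = np.asarray(cov2x2, dtype=float)
    if cov.shape != (2, 2):
        raise InputError("cov2x2 must be 2x2")
    eigval, eigvec = np.linalg.eigh((cov + cov.T) / 2.0)
    if np.any(eigval <= 0):
        raise InputError("covariance must be positive definite")
    sqrt_cov = eigvec @ np.diag(np.sqrt(eigval)) @ eigvec.T
    q = stats.chi2.ppf(level, df=2)
    theta = np.linspace(0.0, 2.0 * np.pi, n_points + 1)
    circle = np.column_stack([np.cos(theta), np.sin(theta)])
    boundary = np.asarray(center, float)[None, :] + np.sqrt(q) * circle @ sqrt_cov
    return EllipsePath(center=(float(center[0]), float(center[1])), level=level, boundary=boundary)


def ellipse_from_fit(
    fit: SureFit, therapy: str, level: float, n_points: int = 256
) -> EllipsePath:
    """Confidence ellipse of a therapy's (delta_cost, delta_effect) pair."""
    mu, cov = fit.delta_block(therapy)
    return confidence_ellipse(mu, cov, level, n_points=n_points)


def bootstrap_psa(
    cohort: pd.DataFrame,
    statistic: Callable[[pd.DataFrame], tuple[float, float]],
    b: int = 1000,
    seed: int = 0,
    stratify_by: str | None = "group",
) -> PsaDraws:
    """Nonparametric bootstrap of an incremental (cost, effect) statistic.

    Individuals are resampled with replacement within each stratum (treatment
    arm by default) to preserve the study design.  A statistic failing on a
    resample is recorded and skipped; more than 10% failures aborts.
    """
    if b < 1:
        raise InputError("B must be >= 1")
    if len(cohort) == 0:
        raise InputError("empty cohort")
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    if stratify_by is not None:
        positions = pd.RangeIndex(len(cohort))
        labels = cohort[stratify_by].to_numpy()
        strata = [positions[labels == lab].to_numpy() for lab in pd.unique(labels)]
    else:
        strata = [np.arange(len(cohort))]
    draws = []
    failures = 0
    for _ in range(b):
        rows = np.concatenate(
            [rng.choice(s, size=len(s), replace=True) for s in strata]
        )
        resample = cohort.iloc[rows].reset_index(drop=True)
        try:
            d_cost, d_eff = statistic(resample)
            if not (np.isfinite(d_cost) and np.isfinite(d_eff)):
                raise ValueError("non-finite statistic")
            draws.append((float(d_cost), float(d_eff)))
        except Exception:
            failures += 1
    if failures > 0.10 * b:
        raise EstimationError(
            f"bootstrap statistic failed on {failures}/{b} resamples (> 10%)"
        )
    if not draws:
        raise EstimationError("bootstrap produced no successful draws")
    return PsaDraws(np.asarray(draws), source="bootstrap", n_failures=failures)


def short_term_statistic(therapy: str, system: str = "irt"):
    """Statistic factory for :func:`bootstrap_psa` on the 12-month analysis.

    Re-runs the SUR estimation on each resample and returns the therapy's
    incremental (cost, effect) coefficient pair.
    """
    from .sure import run_short_term  # local import: avoids a module cycle

    def statistic(df: pd.DataFrame) -> tuple[float, float]:
        fit = run_short_term(df).fits[system]
        return float(fit.alpha[therapy]), float(fit.beta[therapy])

    return statistic


def microsim_psa_statistic(
    ms_config,
    base_rates,
    comparator,
    intervention,
    n_per_iteration: int = 10_000,
):
    """Statistic factory for the long-term bootstrap PSA.

    Each bootstrap resample of the observational cohort re-derives the
    microsimulation inputs it informs -- the baseline state mix (GMFCS levels
    mapped to H/S1/S2), per-state utilities (mean 12-month utility of the
    children occupying each state) and the cost levels of both strategies
    (scaled by the resampled arm means) -- then re-runs a reduced
    microsimulation (``n_per_iteration`` individuals) for the comparator and
    intervention strategies under common random numbers and returns the
    incremental discounted (cost, QALY) pair.  This is one reasonable mapping
    from individual-level data to model parameters; it propagates sampling
    uncertainty in utilities, costs and the severity mix, not in the
    progression/mortality rates (which come from literature, not the cohort).
    """
    import dataclasses

    from .cohort import GROUP_CONTROL
    from .microsim import (
        baseline_distribution_from_cohort,
        run_microsim,
    )

    def _state_utilities(df: pd.DataFrame) -> dict[str, float]:
        g = df["gmfcs"].to_numpy()
        u12 = df["u12"].to_numpy()
        out = {}
        for state, mask in (
            ("H", g <= 2),
            ("S1", g == 3),
            ("S2", g >= 4),
        ):
            out[state] = float(np.clip(u12[mask].mean(), 0.0, 1.0)) if mask.any() else 0.5
        return out

    comp_cost_ref = float(np.mean(list(comparator.state_costs.values())))
    int_cost_ref = float(np.mean(list(intervention.state_costs.values())))
    util_uplift = {
        s: intervention.state_utilities[s] - comparator.state_utilities[s]
        for s in comparator.state_utilities
    }

    def statistic(df: pd.DataFrame) -> tuple[float, float]:
        dist = baseline_distribution_from_cohort(df)
        util = _state_utilities(df)
        st_mean = float(df.loc[df["group"] == GROUP_CONTROL, "cost_total"].mean())
        iert_mean = float(df.loc[df["group"] != GROUP_CONTROL, "cost_total"].mean())
        comp = dataclasses.replace(
            comparator,
            state_costs={
                s: c * st_mean / comp_cost_ref for s, c in comparator.state_costs.items()
            },
            state_utilities=util,
        )
        intv = dataclasses.replace(
            intervention,
            state_costs={
                s: c * iert_mean / int_cost_ref
                for s, c in intervention.state_costs.items()
            },
            state_utilities={
                s: float(np.clip(util[s] + util_uplift[s], 0.0, 1.0)) for s in util
            },
        )
        cfg = dataclasses.replace(
            ms_config,
            n_individuals=n_per_iteration,
            baseline_state_distribution=dist,
        )
        results = run_microsim(cfg, [comp, intv], base_rates)
        rc, ri = results[comp.name], results[intv.name]
        return ri.mean_cost - rc.mean_cost, ri.mean_qaly - rc.mean_qaly

    return statistic


def ce_plane_summary(draws: PsaDraws, wtp: float) -> dict[str, float]:
    """Quadrant proportions on the cost-effectiveness plane plus P(cost-effective).

    Axis ties count toward the positive side (>= 0): NE = more effective and
    more costly, NW = less effective and more costly, SE = more effective and
    cost-saving, SW = less effective and cost-saving.
    """
    d_cost = draws.draws[:, 0]
    d_eff = draws.draws[:, 1]
    eff_pos = d_eff >= 0
    cost_pos = d_cost >= 0
    b = draws.b
    nmb = wtp * d_eff - d_cost
    return {
        "ne": float(np.sum(eff_pos & cost_pos) / b),
        "nw": float(np.sum(~eff_pos & cost_pos) / b),
        "se": float(np.sum(eff_pos & ~cost_pos) / b),
        "sw": float(np.sum(~eff_pos & ~cost_pos) / b),
        "p_cost_effective": float(np.mean(nmb > 0)),
    }
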