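"""First-order individual-level microsimulation over GMFCS health states.

Long-term (default 30-year) projection of costs and QALYs for children with
cerebral palsy.  Four mutually exclusive health states defined by motor
severity:

* ``H``  -- GMFCS I-II, walks without limitations
* ``S1`` -- GMFCS III, walks with limitations / assistive devices
* ``S2`` -- GMFCS IV-V, non-ambulatory or wheelchair-dependent
* ``D``  -- dead (absorbing)

Annual cycles; transitions follow fixed annual probabilities obtained from
per-edge rates via the standard conversion p = 1 - exp(-rate).  A treatment
strategy acts through (i) per-state per-cycle costs and utilities and (ii)
multiplicative modifiers on the progression (H->S1, S1->S2) and mortality
hazards.  Costs and QALYs are accrued for the state occupied during each
cycle and discounted end-of-cycle; Monte Carlo standard errors come from the
individual-level discounted totals.

Common random numbers: every strategy re-uses the identical per-individual,
per-cycle uniform draw stream derived from the configuration seed, so outcome
differences between strategies reflect parameters only.  Two strategies with
identical parameters produce bit-identical results, whatever their order.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import InputError, ParameterError
from .icer import EFFECT_TOLERANCE, classify_icer
from .qaly import DiscountSpec, annuity_factor, discount_factors

STATES = ("H", "S1", "S2", "D")
STATE_INDEX = {s: i for i, s in enumerate(STATES)}
LIVING_STATES = ("H", "S1", "S2")

#: Transition edges expressed as annual rates (events per person-year).
RATE_EDGES = ("H->S1", "S1->S2", "H->D", "S1->D", "S2->D", "S1->H", "S2->S1")
PROGRESSION_EDGES = ("H->S1", "S1->S2")
MORTALITY_EDGES = ("H->D", "S1->D", "S2->D")


@dataclass(frozen=True)
class TransitionModel:
    """Annual 4x4 row-stochastic transition matrix over (H, S1, S2, D)."""

    matrix: np.ndarray

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        if m.shape != (4, 4):
            raise ParameterError("transition matrix must be 4x4")
        if np.any(m < -1e-12) or np.any(m > 1 + 1e-12):
            raise ParameterError("transition probabilities must lie in [0, 1]")
        if np.max(np.abs(m.sum(axis=1) - 1.0)) > 1e-12:
            raise ParameterError("every transition row must sum to 1")
        if not np.allclose(m[3], [0.0, 0.0, 0.0, 1.0]):
            raise ParameterError("death must be absorbing (row D = 0,0,0,1)")
        object.__setattr__(self, "matrix", m)


@dataclass
class StrategyParams:
    """One treatment strategy: per-state economics plus hazard modifiers.

    ``state_costs``/``state_utilities`` map living states to per-cycle values
    (death contributes 0 by construction).  ``progression_multipliers`` scale
    the H->S1 and S1->S2 rates; ``mortality_multipliers`` scale each living
    state's death rate.  Multiplier 1 leaves the base rate unchanged, < 1 is a
    protective treatment effect.
    """

    name: str
    state_costs: dict[str, float]
    state_utilities: dict[str, float]
    progression_multipliers: dict[str, float] = field(default_factory=dict)
    mortality_multipliers: dict[str, float] = field(default_factory=dict)

    def validate(self) -> None:
        for mapping, label in (
            (self.state_costs, "state_costs"),
            (self.state_utilities, "state_utilities"),
        ):
            missing = set(LIVING_STATES) - set(mapping)
            if missing:
                raise ParameterError(
                    f"strategy {self.name!r}: {label} missing states {sorted(missing)}"
                )
        for mapping, allowed, label in (
            (self.progression_multipliers, PROGRESSION_EDGES, "progression_multipliers"),
            (self.mortality_multipliers, MORTALITY_EDGES, "mortality_multipliers"),
        ):
            unknown = set(mapping) - set(allowed)
            if unknown:
                raise ParameterError(
                    f"strategy {self.name!r}: {label} has unknown edges {sorted(unknown)}"
                )
            if any(v < 0 for v in mapping.values()):
                raise ParameterError(
                    f"strategy {self.name!r}: {label} must be non-negative"
                )

    def cost_vector(self) -> np.ndarray:
        return np.array([self.state_costs[s] for s in LIVING_STATES] + [0.0])

    def utility_vector(self) -> np.ndarray:
        return np.array([self.state_utilities[s] for s in LIVING_STATES] + [0.0])


def build_transitions(
    base_rates: Mapping[str, float],
    strategy: StrategyParams | None = None,
    as_probabilities: bool = False,
) -> TransitionModel:
    """Annual transition matrix from per-edge rates and a strategy's modifiers.

    Each off-diagonal probability is ``1 - exp(-rate * multiplier)`` (or the
    entry itself when ``as_probabilities``); the stay probability is the
    residual.  A residual below zero (modified exits exceeding 1) raises
    :class:`ParameterError` naming the state.
    """
    unknown = set(base_rates) - set(RATE_EDGES)
    if unknown:
        raise ParameterError(f"unknown transition edges {sorted(unknown)}")
    if any(v < 0 for v in base_rates.values()):
        raise ParameterError("transition rates must be >= 0")
    if strategy is not None:
        strategy.validate()

    def multiplier(edge: str) -> float:
        if strategy is None:
            return 1.0
        if edge in PROGRESSION_EDGES:
            return strategy.progression_multipliers.get(edge, 1.0)
        if edge in MORTALITY_EDGES:
            return strategy.mortality_multipliers.get(edge, 1.0)
        return 1.0

    m = np.zeros((4, 4))
    for edge in RATE_EDGES:
        rate = base_rates.get(edge, 0.0) * multiplier(edge)
        src, dst = edge.split("->")
        if as_probabilities:
            if rate > 1:
                raise ParameterError(f"probability for edge {edge} exceeds 1")
            p = rate
        else:
            p = 1.0 - np.exp(-rate)
        m[STATE_INDEX[src], STATE_INDEX[dst]] += p
    for s in LIVING_STATES:
        i = STATE_INDEX[s]
        residual = 1.0 - m[i].sum()
        if residual < -1e-12:
            raise ParameterError(
                f"exit probabilities from state {s} sum to {m[i].sum():.4f} > 1 "
                "after applying strategy multipliers"
            )
        m[i, i] = max(residual, 0.0)
    m[3] = [0.0, 0.0, 0.0, 1.0]
    return TransitionModel(m)


@dataclass
class MicrosimConfig:
    """Simulation settings: cohort size, horizon, discounting, baseline mix."""

    n_individuals: int = 100_000
    horizon_cycles: int = 30
    discount: DiscountSpec = field(default_factory=DiscountSpec)
    #: Probabilities over (H, S1, S2, D) at model entry.  Default: the study
    #: cohort's GMFCS mix (59/148 in I-II, 29/148 in III, 60/148 in IV-V).
    baseline_state_distribution: tuple[float, ...] = (59 / 148, 29 / 148, 60 / 148, 0.0)
    seed: int = 1

    def validate(self) -> None:
        if self.n_individuals < 1:
            raise ParameterError("n_individuals must be >= 1")
        if self.horizon_cycles < 1:
            raise ParameterError("horizon_cycles must be >= 1")
        dist = np.asarray(self.baseline_state_distribution, dtype=float)
        if dist.shape != (4,) or np.any(dist < 0):
            raise ParameterError(
                "baseline_state_distribution must be 4 non-negative probabilities"
            )
        if abs(dist.sum() - 1.0) > 1e-9:
            raise ParameterError("baseline_state_distribution must sum to 1")


@dataclass
class MicrosimResult:
    """Per-strategy discounted outcomes, MCSEs and occupancy trace."""

    strategy: str
    mean_cost: float
    mean_qaly: float
    mcse_cost: float
    mcse_qaly: float
    #: (horizon+1) x 4 state-occupancy proportions, row 0 = baseline.
    trace: pd.DataFrame
    transition_counts: np.ndarray
    individual_costs: np.ndarray = field(repr=False)
    individual_qalys: np.ndarray = field(repr=False)


def mcse(individual_totals: Sequence[float]) -> float:
    """Monte Carlo standard error: sample SD / sqrt(n)."""
    x = np.asarray(individual_totals, dtype=float)
    if x.size < 2:
        raise InputError("MCSE requires at least 2 individual totals")
    return float(np.std(x, ddof=1) / np.sqrt(x.size))


def baseline_distribution_from_cohort(cohort: pd.DataFrame) -> tuple[float, ...]:
    """Map a cohort's GMFCS levels to model entry states (I-II->H, III->S1, IV-V->S2)."""
    if len(cohort) == 0:
        raise InputError("empty cohort")
    g = cohort["gmfcs"].to_numpy()
    n = len(g)
    return (
        float(np.sum(g <= 2) / n),
        float(np.sum(g == 3) / n),
        float(np.sum(g >= 4) / n),
        0.0,
    )


def _simulate_one(
    config: MicrosimConfig,
    transitions: TransitionModel,
    strategy: StrategyParams,
) -> MicrosimResult:
    n, horizon = config.n_individuals, config.horizon_cycles
    # Fresh generator per strategy from the same seed: the common-random-number
    # contract (identical uniform streams across strategies).
    rng = np.random.default_rng(np.random.SeedSequence(config.seed))
    u_init = rng.random(n)
    u_cycle = rng.random((horizon, n))

    cum_init = np.cumsum(config.baseline_state_distribution)
    states = np.searchsorted(cum_init, u_init, side="right")
    states = np.minimum(states, 3)

    cum_rows = np.cumsum(transitions.matrix, axis=1)
    costs = strategy.cost_vector()
    utils = strategy.utility_vector()
    dfacts = discount_factors(config.discount, horizon)

    total_cost = np.zeros(n)
    total_qaly = np.zeros(n)
    trace = np.zeros((horizon + 1, 4))
    trace[0] = np.bincount(states, minlength=4) / n
    counts = np.zeros((4, 4), dtype=np.int64)

    for t in range(1, horizon + 1):
        # Accrue for the state occupied during cycle t, discounted end-of-cycle.
        total_cost += costs[states] * dfacts[t - 1]
        total_qaly += utils[states] * dfacts[t - 1]
        u = u_cycle[t - 1]
        nxt = (u[:, None] >= cum_rows[states][:, :3]).sum(axis=1)
        np.add.at(counts, (states, nxt), 1)
        states = nxt
        trace[t] = np.bincount(states, minlength=4) / n

    trace_df = pd.DataFrame(trace, columns=list(STATES))
    trace_df.index.name = "cycle"
    return MicrosimResult(
        strategy=strategy.name,
        mean_cost=float(total_cost.mean()),
        mean_qaly=float(total_qaly.mean()),
        mcse_cost=mcse(total_cost) if n >= 2 else 0.0,
        mcse_qaly=mcse(total_qaly) if n >= 2 else 0.0,
        trace=trace_df,
        transition_counts=counts,
        individual_costs=total_cost,
        individual_qalys=total_qaly,
    )


def run_microsim(
    config: MicrosimConfig,
    strategies: Sequence[StrategyParams],
    base_rates: Mapping[str, float],
    as_probabilities: bool = False,
) -> dict[str, MicrosimResult]:
    """Simulate every strategy under common random numbers.

    The QALY ceiling invariant holds by construction: mean_qaly <= annuity
    factor x max state utility.
    """
    config.validate()
    if len(strategies) == 0:
        raise InputError("at least one strategy is required")
    results: dict[str, MicrosimResult] = {}
    for strategy in strategies:
        strategy.validate()
        transitions = build_transitions(
            base_rates, strategy, as_probabilities=as_probabilities
        )
        result = _simulate_one(config, transitions, strategy)
        cap = annuity_factor(config.discount, config.horizon_cycles) * max(
            strategy.state_utilities.values()
        )
        assert result.mean_qaly <= cap + 1e-9
        results[strategy.name] = result
    return results


def incremental_table(
    results: Mapping[str, MicrosimResult],
    comparator: str,
    effect_tolerance: float = EFFECT_TOLERANCE,
) -> pd.DataFrame:
    """Incremental cost/QALY table against one comparator strategy.

    Mirrors the long-term results layout: absolute discounted means with their
    MCSEs, then deltas and the ICER (or a dominance label).  The comparator
    row carries no deltas.
    """
    if comparator not in results:
        raise InputError(f"unknown comparator strategy {comparator!r}")
    base = results[comparator]
    rows = []
    ordered = [comparator] + [s for s in results if s != comparator]
    for name in ordered:
        r = results[name]
        row = {
            "strategy": name,
            "cost": r.mean_cost,
            "mcse_cost": r.mcse_cost,
            "qaly": r.mean_qaly,
            "mcse_qaly": r.mcse_qaly,
            "delta_cost": np.nan,
            "delta_qaly": np.nan,
            "icer": np.nan,
            "classification": "-",
        }
        if name != comparator:
            d_cost = r.mean_cost - base.mean_cost
            d_qaly = r.mean_qaly - base.mean_qaly
            row["delta_cost"] = d_cost
            row["delta_qaly"] = d_qaly
            if abs(d_qaly) < effect_tolerance:
                row["classification"] = "undefined (delta QALY ~ 0)"
            else:
                res = classify_icer(name, d_cost, d_qaly, effect_tolerance)
                row["icer"] = res.icer_value if res.icer_value is not None else np.nan
                row["classification"] = res.label
        rows.append(row)
    return pd.DataFrame(rows)
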