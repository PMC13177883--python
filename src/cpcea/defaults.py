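"""Illustrative default parameters for the long-term microsimulation.

The published severity-specific progression and mortality inputs behind the
long-term model are not reproduced here; these defaults are ILLUSTRATIVE
placeholders of realistic magnitude (annual rates for a chronic, slowly
progressing pediatric motor disorder) so the model runs out of the box.  Every
operation is parameter-driven: substitute your own rates, costs and utilities
via :class:`cpcea.microsim.StrategyParams` or a pipeline configuration file.
No validated result in this package depends on these numbers.
"""

from __future__ import annotations

from .microsim import StrategyParams

#: Annual baseline transition rates (no-treatment natural history).
DEFAULT_BASE_RATES: dict[str, float] = {
    "H->S1": 0.030,
    "S1->S2": 0.050,
    "H->D": 0.004,
    "S1->D": 0.010,
    "S2->D": 0.030,
}


def default_strategies() -> list[StrategyParams]:
    """The four mutually exclusive strategies of the long-term comparison.

    Costs are per-cycle (annual) EUR, utilities per-cycle weights; active
    strategies add therapy cost and improve utilities while slowing
    progression/mortality through hazard multipliers.
    """
    return [
        StrategyParams(
            name="no_treatment",
            state_costs={"H": 2000.0, "S1": 4000.0, "S2": 8000.0},
            state_utilities={"H": 0.70, "S1": 0.50, "S2": 0.30},
        ),
        StrategyParams(
            name="standard",
            state_costs={"H": 4500.0, "S1": 5500.0, "S2": 9000.0},
            state_utilities={"H": 0.75, "S1": 0.55, "S2": 0.35},
            progression_multipliers={"H->S1": 0.85, "S1->S2": 0.85},
            mortality_multipliers={"H->D": 0.85, "S1->D": 0.85, "S2->D": 0.85},
        ),
        StrategyParams(
            name="standard_irt",
            state_costs={"H": 12000.0, "S1": 13000.0, "S2": 16500.0},
            state_utilities={"H": 0.80, "S1": 0.60, "S2": 0.40},
            progression_multipliers={"H->S1": 0.70, "S1->S2": 0.70},
            mortality_multipliers={"H->D": 0.80, "S1->D": 0.80, "S2->D": 0.80},
        ),
        StrategyParams(
            name="standard_ert",
            state_costs={"H": 8800.0, "S1": 9800.0, "S2": 13200.0},
            state_utilities={"H": 0.78, "S1": 0.58, "S2": 0.38},
            progression_multipliers={"H->S1": 0.75, "S1->S2": 0.75},
            mortality_multipliers={"H->D": 0.82, "S1->D": 0.82, "S2->D": 0.82},
        ),
    ]
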