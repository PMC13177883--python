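import dataclasses

import pytest

from cpcea import CohortConfig, apply_dropout, generate_cohort
from cpcea.qaly import add_qaly_column


def clean_recovery_config(seed: int = 1, scale: int = 20, **overrides) -> CohortConfig:
    """A well-posed estimator-recovery configuration.

    GMFCS does not shift baseline utility (no severity confounding between the
    unbalanced arms) and the baseline sits away from the utility ceiling, so
    the configured therapy increments are exactly the dummies-only estimand.
    Only physiotherapy carries increments: cost 1,700 EUR, effect 0.20 QALY.
    """
    cfg = CohortConfig(
        gmfcs_utility_offsets=(0.0, 0.0, 0.0, 0.0, 0.0),
        baseline_utility_mean=0.40,
        therapy_cost_increments={"physio": 1700.0},
        therapy_effect_increments={"physio": 0.20},
        dropout_count=0,
        seed=seed,
        **overrides,
    )
    return cfg.scaled(scale) if scale > 1 else cfg


@pytest.fixture(scope="session")
def default_cohort():
    """The default 148-child cohort with dropout flags and QALY column."""
    cfg = CohortConfig()
    return add_qaly_column(apply_dropout(generate_cohort(cfg), cfg))


@pytest.fixture(scope="session")
def recovery_cohort():
    """Scaled (n=2,960) clean-recovery cohort with known physiotherapy truth."""
    cfg = clean_recovery_config(seed=1, scale=20)
    return add_qaly_column(generate_cohort(cfg))
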