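"""Microsimulation: transitions, closed-form identities, CRN, Markov oracle."""

import dataclasses

import numpy as np
import pytest

from cpcea import (
    DiscountSpec,
    MicrosimConfig,
    StrategyParams,
    annuity_factor,
    build_transitions,
    incremental_table,
    mcse,
    run_microsim,
)
from cpcea.defaults import DEFAULT_BASE_RATES, default_strategies
from cpcea.errors import InputError, ParameterError
from cpcea.microsim import baseline_distribution_from_cohort


def full_health_strategy(utility=1.0):
    return StrategyParams(
        "test", {"H": 0.0, "S1": 0.0, "S2": 0.0},
        {"H": utility, "S1": utility, "S2": utility},
    )


class TestBuildTransitions:
    def test_zero_rates_identity_with_absorbing_death(self):
        m = build_transitions({}).matrix
        np.testing.assert_allclose(m, np.eye(4))

    def test_rate_to_probability_conversion(self):
        m = build_transitions({"H->S1": 0.02}).matrix
        assert m[0, 1] == pytest.approx(1 - np.exp(-0.02), abs=1e-12)
        assert m[0, 1] == pytest.approx(0.019801, abs=1e-6)

    def test_rows_sum_to_one_and_death_absorbing(self):
        strat = default_strategies()[2]
        m = build_transitions(DEFAULT_BASE_RATES, strat).matrix
        np.testing.assert_allclose(m.sum(axis=1), np.ones(4), atol=1e-12)
        np.testing.assert_allclose(m[3], [0, 0, 0, 1])

    def test_multipliers_scale_hazards(self):
        strat = dataclasses.replace(
            default_strategies()[0], progression_multipliers={"H->S1": 0.5}
        )
        m0 = build_transitions({"H->S1": 0.1}).matrix
        m1 = build_transitions({"H->S1": 0.1}, strat).matrix
        assert m1[0, 1] == pytest.approx(1 - np.exp(-0.05))
        assert m1[0, 1] < m0[0, 1]

    def test_infeasible_row_raises(self):
        with pytest.raises(ParameterError, match="state H"):
            build_transitions({"H->S1": 0.9, "H->D": 0.5}, as_probabilities=True)

    def test_unknown_edge_raises(self):
        with pytest.raises(ParameterError, match="edges"):
            build_transitions({"H->S2": 0.1})


class TestClosedFormIdentities:
    def test_full_health_annuity(self):
        """Identity transitions, utility 1, 3%/30y: mean QALY = 19.6004, MCSE 0."""
        cfg = MicrosimConfig(
            n_individuals=500, horizon_cycles=30, seed=3,
            baseline_state_distribution=(1.0, 0.0, 0.0, 0.0),
        )
        res = run_microsim(cfg, [full_health_strategy()], {})["test"]
        assert res.mean_qaly == pytest.approx(19.6004, abs=5e-5)
        assert res.mean_qaly == pytest.approx(
            annuity_factor(DiscountSpec(), 30), abs=1e-9
        )
        assert res.mcse_qaly == pytest.approx(0.0, abs=1e-12)

    def test_all_dead_baseline_accrues_nothing(self):
        cfg = MicrosimConfig(
            n_individuals=200, horizon_cycles=10, seed=1,
            baseline_state_distribution=(0.0, 0.0, 0.0, 1.0),
        )
        strat = StrategyParams(
            "s", {"H": 100.0, "S1": 100.0, "S2": 100.0}, {"H": 1, "S1": 1, "S2": 1}
        )
        res = run_microsim(cfg, [strat], DEFAULT_BASE_RATES)["s"]
        assert res.mean_cost == 0.0 and res.mean_qaly == 0.0

    def test_deterministic_chain_matches_hand_computation(self):
        """Everyone dies after exactly one cycle (rate -> prob 1): one discounted accrual."""
        cfg = MicrosimConfig(
            n_individuals=100, horizon_cycles=5, seed=2,
            baseline_state_distribution=(1.0, 0.0, 0.0, 0.0),
        )
        strat = StrategyParams("s", {"H": 1000.0, "S1": 0, "S2": 0}, {"H": 0.8, "S1": 0, "S2": 0})
        res = run_microsim(
            cfg, [strat], {"H->D": 1.0}, as_probabilities=True
        )["s"]
        assert res.mean_cost == pytest.approx(1000.0 / 1.03, abs=1e-9)
        assert res.mean_qaly == pytest.approx(0.8 / 1.03, abs=1e-12)
        assert res.trace["D"].iloc[1] == 1.0


class TestRandomNumberDiscipline:
    def test_identical_strategies_bit_identical(self):
        """Common random numbers: same parameters, same per-individual outcomes."""
        cfg = MicrosimConfig(n_individuals=2000, horizon_cycles=30, seed=11)
        s1 = default_strategies()[1]
        s2 = dataclasses.replace(s1, name="clone")
        res = run_microsim(cfg, [s1, s2], DEFAULT_BASE_RATES)
        assert np.array_equal(
            res[s1.name].individual_costs, res["clone"].individual_costs
        )
        assert np.array_equal(
            res[s1.name].individual_qalys, res["clone"].individual_qalys
        )

    def test_strategy_order_invariance(self):
        cfg = MicrosimConfig(n_individuals=2000, horizon_cycles=30, seed=11)
        a, b = default_strategies()[:2]
        fwd = run_microsim(cfg, [a, b], DEFAULT_BASE_RATES)
        rev = run_microsim(cfg, [b, a], DEFAULT_BASE_RATES)
        assert fwd[a.name].mean_cost == rev[a.name].mean_cost
        assert fwd[b.name].mean_qaly == rev[b.name].mean_qaly

    def test_seed_reproducibility(self):
        cfg = MicrosimConfig(n_individuals=1000, horizon_cycles=30, seed=5)
        a = run_microsim(cfg, default_strategies(), DEFAULT_BASE_RATES)
        b = run_microsim(cfg, default_strategies(), DEFAULT_BASE_RATES)
        for name in a:
            assert a[name].mean_cost == b[name].mean_cost
            np.testing.assert_array_equal(a[name].trace, b[name].trace)

    def test_utility_monotonicity_under_common_seed(self):
        """Raising a state utility never lowers mean QALYs (same draws)."""
        cfg = MicrosimConfig(n_individuals=3000, horizon_cycles=30, seed=7)
        base = default_strategies()[1]
        better = dataclasses.replace(
            base, name="better",
            state_utilities={**base.state_utilities, "S2": base.state_utilities["S2"] + 0.2},
        )
        res = run_microsim(cfg, [base, better], DEFAULT_BASE_RATES)
        assert res["better"].mean_qaly >= res[base.name].mean_qaly


class TestTraceConservation:
    def test_rows_sum_to_one_and_death_monotone(self):
        cfg = MicrosimConfig(n_individuals=5000, horizon_cycles=30, seed=13)
        res = run_microsim(cfg, [default_strategies()[0]], DEFAULT_BASE_RATES)
        trace = res["no_treatment"].trace.to_numpy()
        np.testing.assert_allclose(trace.sum(axis=1), np.ones(31), atol=1e-9)
        assert np.all(np.diff(trace[:, 3]) >= -1e-12)

    def test_transition_tallies_match_occupancy(self):
        cfg = MicrosimConfig(n_individuals=2000, horizon_cycles=30, seed=13)
        res = run_microsim(cfg, [default_strategies()[1]], DEFAULT_BASE_RATES)["standard"]
        counts = res.transition_counts
        # every individual transitions once per cycle
        assert counts.sum() == 2000 * 30
        # departures from each state equal person-cycles observed in that state
        occupancy_cycles = res.trace.iloc[:-1].to_numpy().sum(axis=0) * 2000
        np.testing.assert_allclose(counts.sum(axis=1), occupancy_cycles, atol=0.5)

    def test_markov_matrix_power_oracle(self):
        """Mean trace agrees with the cohort-limit matrix-power distribution."""
        strat = default_strategies()[1]
        P = build_transitions(DEFAULT_BASE_RATES, strat).matrix
        cfg = MicrosimConfig(n_individuals=100_000, horizon_cycles=30, seed=9)
        res = run_microsim(cfg, [strat], DEFAULT_BASE_RATES)[strat.name]
        dist = np.array(cfg.baseline_state_distribution)
        gap = 0.0
        for t in range(31):
            gap = max(gap, float(np.max(np.abs(res.trace.iloc[t].to_numpy() - dist))))
            dist = dist @ P
        assert gap < 0.01


class TestMcse:
    def test_constant_sequence_zero(self):
        assert mcse([5.0] * 10) == 0.0

    def test_hand_computed_pair(self):
        assert mcse([0.0, 2.0]) == pytest.approx(1.0)  # SD sqrt(2), /sqrt(2)

    def test_too_short_raises(self):
        with pytest.raises(InputError):
            mcse([1.0])

    def test_root_n_scaling(self):
        """Quadrupling the simulated cohort halves the MCSE (+/- 20%)."""
        strat = default_strategies()[1]
        small = MicrosimConfig(n_individuals=5_000, horizon_cycles=30, seed=21)
        large = MicrosimConfig(n_individuals=20_000, horizon_cycles=30, seed=22)
        m_small = run_microsim(small, [strat], DEFAULT_BASE_RATES)[strat.name].mcse_qaly
        m_large = run_microsim(large, [strat], DEFAULT_BASE_RATES)[strat.name].mcse_qaly
        assert m_large == pytest.approx(m_small / 2, rel=0.20)


class TestIncrementalTable:
    def test_published_style_arithmetic(self):
        """Deltas 50,173 EUR / 1.464 QALY give an ICER near 34,271 EUR/QALY."""
        a = _fake_result("none", 94_049.0, 14.454)
        b = _fake_result("standard", 144_222.0, 15.918)
        table = incremental_table({"none": a, "standard": b}, "none")
        row = table[table["strategy"] == "standard"].iloc[0]
        assert row["delta_cost"] == pytest.approx(50_173.0)
        assert row["delta_qaly"] == pytest.approx(1.464)
        assert row["icer"] == pytest.approx(50_173.0 / 1.464, abs=1e-6)

    def test_therasuit_style_arithmetic(self):
        a = _fake_result("standard", 0.0, 0.0)
        b = _fake_result("therasuit", 70_889.0, 5.486)
        table = incremental_table({"standard": a, "therasuit": b}, "standard")
        assert table.iloc[1]["icer"] == pytest.approx(70_889.0 / 5.486, abs=1e-6)

    def test_self_comparison_flagged_undefined(self):
        a = _fake_result("s", 10.0, 1.0)
        b = _fake_result("t", 10.0, 1.0)
        table = incremental_table({"s": a, "t": b}, "s")
        assert "undefined" in table.iloc[1]["classification"]

    def test_unknown_comparator_raises(self):
        with pytest.raises(InputError):
            incremental_table({"s": _fake_result("s", 1.0, 1.0)}, "missing")


def _fake_result(name, cost, qaly):
    from cpcea.microsim import MicrosimResult
    import pandas as pd

    return MicrosimResult(
        strategy=name, mean_cost=cost, mean_qaly=qaly, mcse_cost=0.0, mcse_qaly=0.0,
        trace=pd.DataFrame(), transition_counts=np.zeros((4, 4)),
        individual_costs=np.array([cost]), individual_qalys=np.array([qaly]),
    )


def test_baseline_distribution_from_cohort(default_cohort):
    dist = baseline_distribution_from_cohort(default_cohort)
    assert dist == pytest.approx((59 / 148, 29 / 148, 60 / 148, 0.0))
    assert sum(dist) == pytest.approx(1.0)
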