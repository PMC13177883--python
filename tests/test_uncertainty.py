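"""PSA machinery: CEAC closed form vs sampling, ellipse geometry, bootstrap."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from cpcea import (
    PsaDraws,
    bootstrap_psa,
    ce_plane_summary,
    ceac_from_draws,
    ceac_parametric,
    confidence_ellipse,
    fit_sure,
)
from cpcea.errors import EstimationError, InputError
from cpcea.sure import IRT_SPEC
from cpcea.uncertainty import ceac_normal, ellipse_from_fit, short_term_statistic

MU = np.array([3000.0, 0.15])
COV = np.array([[250_000.0, 20.0], [20.0, 0.0025]])
GRID = np.array([0.0, 10_000.0, 25_000.0, 50_000.0, 100_000.0])


class TestCeacParametric:
    def test_degenerate_zero_variance_is_step(self):
        c = ceac_normal(MU, np.zeros((2, 2)), GRID)
        # NMB positive iff lambda * 0.15 > 3000, i.e. lambda > 20,000
        np.testing.assert_allclose(c.probabilities, [0, 0, 1, 1, 1])

    def test_zero_means_give_half_everywhere(self):
        c = ceac_normal([0.0, 0.0], COV, GRID)
        np.testing.assert_allclose(c.probabilities, 0.5 * np.ones(5))

    def test_closed_form_matches_million_draw_oracle(self):
        """Phi-based CEAC within 0.005 of a 10^6-draw Monte Carlo estimate."""
        c = ceac_normal(MU, COV, GRID)
        rng = np.random.default_rng(123)
        draws = rng.multivariate_normal(MU, COV, size=1_000_000)
        for lam, p in zip(GRID, c.probabilities):
            mc = float(np.mean(lam * draws[:, 1] - draws[:, 0] > 0))
            assert abs(p - mc) < 0.005

    def test_limits(self):
        """lambda->0 gives P(delta_cost<0); lambda->inf gives P(delta_effect>0)."""
        c0 = ceac_normal(MU, COV, [1e-9])
        p_cost_neg = stats.norm.cdf(-MU[0] / np.sqrt(COV[0, 0]))
        assert c0.probabilities[0] == pytest.approx(p_cost_neg, abs=1e-6)
        cinf = ceac_normal(MU, COV, [1e12])
        p_eff_pos = 1 - stats.norm.cdf(-MU[1] / np.sqrt(COV[1, 1]))
        assert cinf.probabilities[0] == pytest.approx(p_eff_pos, abs=1e-6)

    def test_from_sure_fit(self, default_cohort):
        fit = fit_sure(default_cohort, IRT_SPEC)
        c = ceac_parametric(fit, "physio", GRID)
        assert c.probabilities.shape == (5,)
        assert np.all((0 <= c.probabilities) & (c.probabilities <= 1))


class TestCeacFromDraws:
    def test_identical_positive_nmb_draws(self):
        draws = PsaDraws(np.tile([1000.0, 0.5], (20, 1)), "parametric")
        c = ceac_from_draws(draws, [50_000.0])
        assert c.probabilities[0] == 1.0

    def test_symmetric_draws_near_half(self):
        rng = np.random.default_rng(5)
        x = rng.multivariate_normal([0, 0], COV, size=4000)
        sym = np.vstack([x, -x])  # exactly symmetric about the origin
        c = ceac_from_draws(PsaDraws(sym, "parametric"), GRID)
        np.testing.assert_allclose(c.probabilities, 0.5, atol=0.01)

    def test_agrees_with_parametric_on_normal_draws(self):
        """Empirical CEAC from 10^5 normal draws within 0.01 of the closed form."""
        rng = np.random.default_rng(17)
        sample = rng.multivariate_normal(MU, COV, size=100_000)
        emp = ceac_from_draws(PsaDraws(sample, "parametric"), GRID)
        par = ceac_normal(MU, COV, GRID)
        assert np.max(np.abs(emp.probabilities - par.probabilities)) < 0.01

    def test_empty_draws_rejected(self):
        with pytest.raises(InputError):
            PsaDraws(np.empty((0, 2)), "bootstrap")


class TestConfidenceEllipse:
    def test_identity_covariance_radius(self):
        e = confidence_ellipse([0.0, 0.0], np.eye(2), 0.95)
        radii = np.linalg.norm(e.boundary, axis=1)
        np.testing.assert_allclose(radii, np.sqrt(5.9915), atol=1e-4)

    @settings(derandomize=True, max_examples=25)
    @given(
        a=st.floats(0.5, 3), b=st.floats(0.5, 3), r=st.floats(-0.8, 0.8),
        level=st.sampled_from([0.5, 0.75, 0.95]),
    )
    def test_mahalanobis_identity_on_boundary(self, a, b, r, level):
        """Every boundary point sits at the chi-square(2) quantile distance."""
        cov = np.array([[a * a, r * a * b], [r * a * b, b * b]])
        e = confidence_ellipse([1.0, -2.0], cov, level)
        d = e.boundary - np.array([1.0, -2.0])
        mah = np.einsum("ij,jk,ik->i", d, np.linalg.inv(cov), d)
        np.testing.assert_allclose(mah, stats.chi2.ppf(level, 2), atol=1e-9)

    def test_nested_levels(self):
        """The 50% ellipse lies strictly inside 75% inside 95%."""
        inv = np.linalg.inv(COV)
        radii = {}
        for level in (0.5, 0.75, 0.95):
            e = confidence_ellipse(MU, COV, level)
            d = e.boundary - MU
            radii[level] = np.einsum("ij,jk,ik->i", d, inv, d).max()
        assert radii[0.5] < radii[0.75] < radii[0.95]

    def test_monte_carlo_coverage(self):
        """95% of 10^5 bivariate-normal samples fall inside the 95% ellipse."""
        rng = np.random.default_rng(29)
        sample = rng.multivariate_normal(MU, COV, size=100_000)
        d = sample - MU
        mah = np.einsum("ij,jk,ik->i", d, np.linalg.inv(COV), d)
        inside = np.mean(mah <= stats.chi2.ppf(0.95, 2))
        assert inside == pytest.approx(0.95, abs=0.01)

    def test_singular_covariance_rejected(self):
        with pytest.raises(InputError):
            confidence_ellipse([0, 0], np.array([[1.0, 1.0], [1.0, 1.0]]), 0.95)

    def test_from_fit_centers_on_coefficients(self, default_cohort):
        fit = fit_sure(default_cohort, IRT_SPEC)
        e = ellipse_from_fit(fit, "physio", 0.95)
        assert e.center[0] == pytest.approx(fit.alpha["physio"])
        assert e.center[1] == pytest.approx(fit.beta["physio"])


class TestBootstrap:
    def test_identical_records_zero_variance(self):
        df = pd.DataFrame(
            {"group": ["A"] * 6 + ["B"] * 6, "y": [2.0] * 6 + [5.0] * 6}
        )
        stat = lambda d: (
            d.loc[d.group == "B", "y"].mean() - d.loc[d.group == "A", "y"].mean(),
            1.0,
        )
        draws = bootstrap_psa(df, stat, b=30, seed=0)
        np.testing.assert_allclose(draws.draws[:, 0], 3.0)

    def test_seeded_reproducibility(self, default_cohort):
        stat = short_term_statistic("physio")
        a = bootstrap_psa(default_cohort, stat, b=20, seed=42)
        b = bootstrap_psa(default_cohort, stat, b=20, seed=42)
        np.testing.assert_array_equal(a.draws, b.draws)

    def test_bootstrap_se_matches_closed_form(self):
        """Bootstrap SE of a mean within 15% of SD/sqrt(n) (n=500, B=1,000)."""
        rng = np.random.default_rng(7)
        y = rng.normal(10.0, 2.0, size=500)
        df = pd.DataFrame({"group": ["A"] * 500, "y": y})
        stat = lambda d: (d["y"].mean(), 0.0)
        draws = bootstrap_psa(df, stat, b=1000, seed=3)
        boot_se = draws.draws[:, 0].std(ddof=1)
        closed = y.std(ddof=1) / np.sqrt(500)
        assert boot_se == pytest.approx(closed, rel=0.15)

    def test_stratification_preserves_arm_sizes(self, default_cohort):
        sizes = []

        def stat(d):
            sizes.append(((d["group"] == "IERT_ST").sum(), (d["group"] == "ST").sum()))
            return (0.0, 1.0)

        bootstrap_psa(default_cohort, stat, b=5, seed=1)
        assert all(s == (92, 56) for s in sizes)

    def test_failure_rate_guard(self):
        df = pd.DataFrame({"group": ["A"] * 10, "y": range(10)})

        def flaky(d):
            raise ValueError("boom")

        with pytest.raises(EstimationError, match="10%"):
            bootstrap_psa(df, flaky, b=20, seed=0)


class TestLongTermPsa:
    def test_microsim_statistic_produces_reproducible_draws(self, default_cohort):
        """Cohort resample -> model inputs -> reduced microsim -> (dCost, dQALY)."""
        from cpcea import MicrosimConfig
        from cpcea.defaults import DEFAULT_BASE_RATES, default_strategies
        from cpcea.uncertainty import microsim_psa_statistic

        cfg = MicrosimConfig(n_individuals=1000, horizon_cycles=30, seed=13)
        strategies = default_strategies()
        stat = microsim_psa_statistic(
            cfg, DEFAULT_BASE_RATES, strategies[1], strategies[3],
            n_per_iteration=1000,
        )
        a = bootstrap_psa(default_cohort, stat, b=4, seed=8)
        b = bootstrap_psa(default_cohort, stat, b=4, seed=8)
        assert a.draws.shape == (4, 2)
        assert np.all(np.isfinite(a.draws))
        np.testing.assert_array_equal(a.draws, b.draws)
        # parameter uncertainty only: draws differ across resamples
        assert len(np.unique(a.draws[:, 0])) > 1


class TestCePlane:
    def test_all_northeast(self):
        draws = PsaDraws(np.array([[100.0, 0.1], [50.0, 0.2]]), "bootstrap")
        s = ce_plane_summary(draws, 50_000.0)
        assert s["ne"] == 1.0 and s["nw"] == s["se"] == s["sw"] == 0.0

    def test_four_symmetric_quadrants(self):
        draws = PsaDraws(
            np.array([[1.0, 1.0], [1.0, -1.0], [-1.0, 1.0], [-1.0, -1.0]]), "bootstrap"
        )
        s = ce_plane_summary(draws, 1.0)
        assert s["ne"] == s["nw"] == s["se"] == s["sw"] == 0.25

    def test_proportions_sum_to_one(self):
        rng = np.random.default_rng(11)
        draws = PsaDraws(rng.normal(size=(500, 2)), "bootstrap")
        s = ce_plane_summary(draws, 30_000.0)
        assert s["ne"] + s["nw"] + s["se"] + s["sw"] == pytest.approx(1.0)
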