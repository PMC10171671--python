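"""The comparative-risk-assessment engine: PIF, deaths averted, Monte Carlo."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

import sodium_cra as sc
from sodium_cra.core import BetaEntry, RR20Entry, RRParameterSet
from sodium_cra.cra import potential_impact_fraction as pif


def make_params(slope=2.0, slope_se=0.0, rr=2.0, ci=None, cause="I20-25"):
    lo, hi = ci if ci else (rr, rr)
    return RRParameterSet(
        beta=[BetaEntry(age_min=0, age_max=200, slope=slope, se=slope_se,
                        source="test")],
        rr20=[RR20Entry(cause=cause, age_min=0, age_max=200, rr=rr,
                        ci_low=lo, ci_high=hi, source="test")],
    )


def single_cell_inputs(base_mean=3000.0, base_sd=1500.0, cf_mean=2400.0,
                       cf_sd=1200.0, deaths=1000.0, cause="I20-25"):
    mortality = pd.DataFrame({
        "sex": ["male"], "age_band": ["75-79"], "cause": [cause],
        "deaths": [deaths], "population": [100000],
    })
    baseline = pd.DataFrame({
        "sex": ["male"], "age_group": ["71+"],
        "mean_mg": [base_mean], "sd_mg": [base_sd],
    })
    cf = pd.DataFrame({
        "sex": ["male"], "age_group": ["71+"],
        "mean_mg": [cf_mean], "sd_mg": [cf_sd],
    })
    return mortality, baseline, cf


class TestElementaryPieces:
    def test_sbp_shift(self):
        assert sc.sbp_shift(0.0, 2.0) == 0.0
        assert sc.sbp_shift(3.0, 2.0) == 6.0
        assert sc.sbp_shift(2 * 3.0, 2.0) == 2 * sc.sbp_shift(3.0, 2.0)
        with pytest.raises(ValueError):
            sc.sbp_shift(1.0, -0.5)

    def test_relative_risk_identity_and_definition(self):
        assert sc.relative_risk_at(5.0, 5.0, 1.5, 4.0) == 1.0
        # beta * (x - x_ref) = 20 mmHg -> RR = rr20
        assert sc.relative_risk_at(10.0, 0.0, 2.0, 4.0) == pytest.approx(4.0)
        # 10 mmHg -> sqrt scaling: 4^(10/20) = 2
        assert sc.relative_risk_at(5.0, 0.0, 2.0, 4.0) == pytest.approx(2.0)
        with pytest.raises(ValueError):
            sc.relative_risk_at(5.0, 0.0, 2.0, 0.9)


class TestPotentialImpactFraction:
    def test_identical_distributions_zero(self):
        for method in ("analytic", "quadrature"):
            assert pif(7.0, 2.0, 7.0, 2.0, 1.5, 2.0, method=method) == pytest.approx(
                0.0, abs=1e-12
            )

    def test_point_mass_20mmhg_shift(self):
        # point masses, beta * delta = 20 mmHg downward, rr20 = 4 -> 1 - 1/4
        assert pif(10.0, 0.0, 0.0, 0.0, 2.0, 4.0) == pytest.approx(0.75)

    @pytest.mark.parametrize("method", ["analytic", "quadrature"])
    def test_untruncated_normal_matches_mgf_closed_form(self, method):
        mu_b, sd_b, mu_c, sd_c = 7.5, 2.0, 5.5, 1.6
        beta, rr20 = 1.2, 2.5
        k = math.log(rr20) / 20.0 * beta
        expected = 1.0 - math.exp(
            k * (mu_c - mu_b) + k**2 * (sd_c**2 - sd_b**2) / 2.0
        )
        got = pif(mu_b, sd_b, mu_c, sd_c, beta, rr20,
                  truncated_at_zero=False, method=method)
        assert got == pytest.approx(expected, abs=1e-8)

    def test_x_ref_invariance(self):
        vals = [
            pif(7.0, 2.0, 5.0, 1.5, 1.5, 2.0, method="quadrature", x_ref=x0)
            for x0 in (0.0, 3.0, 7.0, 12.0)
        ]
        for v in vals[1:]:
            assert v == pytest.approx(vals[0], abs=1e-10)

    def test_quadrature_agrees_with_analytic_truncated(self):
        for mu_b, sd_b, mu_c, sd_c in [(7, 4, 5.5, 3.1), (3, 2.5, 2, 1.7)]:
            a = pif(mu_b, sd_b, mu_c, sd_c, 1.3, 2.2, method="analytic")
            q = pif(mu_b, sd_b, mu_c, sd_c, 1.3, 2.2, method="quadrature")
            assert a == pytest.approx(q, abs=1e-8)

    def test_lognormal_quadrature_agrees_with_gauss_hermite(self):
        a = pif(7.0, 3.0, 5.0, 2.2, 1.3, 2.2, form="lognormal", method="analytic")
        q = pif(7.0, 3.0, 5.0, 2.2, 1.3, 2.2, form="lognormal", method="quadrature")
        assert a == pytest.approx(q, rel=1e-7)

    def test_null_parameters_give_zero(self):
        assert pif(7.0, 2.0, 5.0, 1.5, 1.5, 1.0) == pytest.approx(0.0, abs=1e-12)
        assert pif(7.0, 2.0, 5.0, 1.5, 0.0, 3.0) == pytest.approx(0.0, abs=1e-12)

    @given(delta=st.floats(0.05, 3.0))
    def test_monotone_in_counterfactual_mean(self, delta):
        hi = pif(7.0, 2.0, 7.0 - delta, 2.0, 1.5, 2.0)
        lo = pif(7.0, 2.0, 7.0 - delta / 2, 2.0, 1.5, 2.0)
        assert hi > lo > 0

    def test_quadrature_vs_monte_carlo_sampling(self):
        # E[RR] by simulation at 1e6 draws vs adaptive quadrature, 3 SEs
        rng = np.random.default_rng(2024)
        mu, sd, beta, rr20 = 7.0, 2.5, 1.3, 2.0
        k = math.log(rr20) / 20.0 * beta
        draws = rng.normal(mu, sd, 1_000_000)
        draws = draws[draws >= 0]
        rr = np.exp(k * draws)
        mc, se = rr.mean(), rr.std(ddof=1) / np.sqrt(len(rr))
        from sodium_cra.cra import _mean_rr_quadrature

        quad = _mean_rr_quadrature(mu, sd, k, 0.0, "normal", True)
        assert abs(quad - mc) < 3 * se

    def test_small_shift_linearization(self):
        mu, sd, beta, rr20, deaths = 7.0, 2.0, 1.5, 2.0, 10_000.0
        k = math.log(rr20) / 20.0 * beta
        dmu = 1e-4
        p = pif(mu, sd, mu - dmu, sd, beta, rr20, truncated_at_zero=False)
        assert deaths * p == pytest.approx(deaths * k * dmu, rel=1e-3)

    def test_exposure_shift_wrapper(self):
        s = sc.Stratum("male", "51-70")
        shift = sc.ExposureShift(
            sc.IntakeDistribution(s, 3000, 1500),
            sc.IntakeDistribution(s, 2400, 1200),
        )
        direct = pif(sc.sodium_to_salt(3000), 1500 * 2.5 / 1000,
                     sc.sodium_to_salt(2400), 1200 * 2.5 / 1000, 1.5, 2.0)
        assert shift.pif(1.5, 2.0) == pytest.approx(direct)
        with pytest.raises(ValueError, match="share a stratum"):
            sc.ExposureShift(
                sc.IntakeDistribution(s, 3000, 1500),
                sc.IntakeDistribution(sc.Stratum("female", "51-70"), 2400, 1200),
            )


class TestDeathsAverted:
    def test_zero_pif_zero_averted(self):
        mort, base, _ = single_cell_inputs()
        res = sc.deaths_averted(mort, base, base, make_params())
        assert res.total_averted == pytest.approx(0.0, abs=1e-9)

    def test_single_cell_closed_form(self):
        # mean-shift with beta * delta-salt = 20 mmHg and rr20 = 4 -> pif 0.75
        mort, base, cf = single_cell_inputs(
            base_mean=salt_mg(10.0), base_sd=1.0, cf_mean=0.004,  # ~0 g salt
            cf_sd=1.0, deaths=1000.0,
        )
        params = make_params(slope=2.0, rr=4.0)
        res = sc.deaths_averted(mort, base, cf, params, mean_shift_only=True)
        assert res.total_averted == pytest.approx(750.0, rel=1e-3)

    def test_sign_flips_when_counterfactual_higher(self):
        mort, base, cf = single_cell_inputs(cf_mean=3600.0, cf_sd=1500.0)
        res = sc.deaths_averted(mort, base, cf, make_params())
        assert res.total_averted < 0  # excess deaths, not averted

    def test_conservation_cell_by_cell(self, params, mortality, adult_baseline,
                                       adult_scenario_a):
        res = sc.deaths_averted(mortality, adult_baseline, adult_scenario_a, params)
        np.testing.assert_allclose(
            res.cells["deaths"] - res.cells["deaths_averted"],
            res.cells["deaths_counterfactual"],
        )

    def test_unmapped_cell_error_lists_cell(self, params, adult_baseline):
        mort = pd.DataFrame({
            "sex": ["male"], "age_band": ["10-14"], "cause": ["I50"],
            "deaths": [5], "population": [1000],
        })
        with pytest.raises(ValueError, match="10-14"):
            sc.deaths_averted(mort, adult_baseline, adult_baseline, params)

    def test_monotone_in_counterfactual_mean(self, params, mortality,
                                             adult_baseline):
        res = []
        for target in (2300.0, 2000.0, 1500.0):
            cf = sc.build_proportional_scenario(
                adult_baseline, target, population_baseline_mean=2758.0)
            res.append(sc.deaths_averted(
                mortality, adult_baseline, cf, params).total_averted)
        assert res[0] < res[1] < res[2]

    def test_reference_deaths_default_is_table_total(self, params, mortality,
                                                     adult_baseline,
                                                     adult_scenario_a):
        res = sc.deaths_averted(mortality, adult_baseline, adult_scenario_a, params)
        assert res.reference_deaths == float(mortality["deaths"].sum())
        assert res.pct_of_reference == pytest.approx(
            res.total_averted / mortality["deaths"].sum() * 100.0
        )


def salt_mg(salt_g: float) -> float:
    return salt_g * 1000.0 / 2.5


class TestMonteCarlo:
    def test_zero_uncertainty_collapses_to_point(self):
        mort, base, cf = single_cell_inputs()
        params = make_params(slope=1.5, slope_se=0.0, rr=2.0)
        res = sc.monte_carlo_ui(mort, base, cf, params, iterations=200, seed=9)
        lo, hi = res.ui()
        assert lo == pytest.approx(res.total_averted, rel=1e-12)
        assert hi == pytest.approx(res.total_averted, rel=1e-12)

    def test_fixed_seed_reproducible(self, params, mortality, adult_baseline,
                                     adult_scenario_a):
        kw = dict(iterations=500, seed=123)
        r1 = sc.monte_carlo_ui(mortality, adult_baseline, adult_scenario_a,
                               params, **kw)
        r2 = sc.monte_carlo_ui(mortality, adult_baseline, adult_scenario_a,
                               params, **kw)
        pd.testing.assert_frame_equal(r1.summary, r2.summary)

    def test_ui_brackets_point_estimate(self, params, mortality, adult_baseline,
                                        adult_scenario_a):
        res = sc.monte_carlo_ui(mortality, adult_baseline, adult_scenario_a,
                                params, iterations=2000, seed=4)
        lo, hi = res.ui()
        assert lo < res.total_averted < hi
        for sex in ("male", "female"):
            lo, hi = res.ui("sex", sex)
            assert lo < res.averted("sex", sex) < hi

    def test_too_few_iterations_rejected(self, params, mortality,
                                         adult_baseline, adult_scenario_a):
        with pytest.raises(ValueError, match="iterations"):
            sc.monte_carlo_ui(mortality, adult_baseline, adult_scenario_a,
                              params, iterations=1)

    def test_negative_beta_draws_truncated(self):
        # huge slope SE: truncation at zero keeps all PIFs non-negative
        mort, base, cf = single_cell_inputs()
        params = make_params(slope=0.1, slope_se=5.0, rr=2.0, ci=(1.9, 2.1))
        res = sc.monte_carlo_ui(mort, base, cf, params, iterations=500, seed=11)
        lo, _ = res.ui()
        assert lo >= 0.0
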