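"""Unit and property tests for the logistic / Luedeking-Piret kinetics."""

import numpy as np
import pytest
from scipy.integrate import solve_ivp

from mycomorph import (
    LogisticParams,
    LuedekingPiretParams,
    TimeCourse,
    anchor_trajectory,
    biomass,
    biomass_from_rate,
    cumulative_biomass,
    fit_logistic,
    fit_luedeking_piret,
    growth_rate,
    lipid,
    lipid_rate,
    rate_table,
)
from mycomorph.reference import DAILY_RATES, DAY1_GROWTH_RATE, KINETIC_PARAMS


class TestClosedForms:
    def test_initial_condition_and_fixed_point(self):
        p = LogisticParams(mu_max=0.5, x_m=20.0, x_0=2.0)
        assert biomass(0.0, p) == pytest.approx(2.0, rel=1e-14)
        sat = LogisticParams(mu_max=0.5, x_m=20.0, x_0=20.0)
        assert np.allclose(biomass(np.linspace(0, 50, 7), sat), 20.0)

    def test_biomass_monotone_and_saturating(self, random_param_sets):
        t = np.linspace(0, 60, 400)
        for p, _ in random_param_sets:
            x = biomass(t, p)
            assert np.all(np.diff(x) >= -1e-12)
            assert x[-1] == pytest.approx(p.x_m, rel=1e-3)
            assert growth_rate(x[-1], p) == pytest.approx(0.0, abs=1e-2)

    def test_growth_rate_parabola(self):
        p = LogisticParams(mu_max=0.8, x_m=10.0, x_0=1.0)
        assert growth_rate(p.x_m / 2, p) == pytest.approx(p.mu_max * p.x_m / 4, rel=1e-14)
        assert growth_rate(0.0, p) == 0.0
        assert growth_rate(p.x_m, p) == 0.0
        with pytest.raises(ValueError):
            growth_rate(p.x_m * 1.1, p)

    def test_ode_consistency_finite_difference(self, random_param_sets):
        """Central difference of X(t) matches the rate law everywhere."""
        t = np.linspace(0.05, 10.0, 200)
        h = 1e-5
        for p, _ in random_param_sets:
            dxdt = (biomass(t + h, p) - biomass(t - h, p)) / (2 * h)
            expected = growth_rate(biomass(t, p), p)
            assert np.allclose(dxdt, expected, rtol=1e-6)

    def test_lipid_initial_and_growth_associated_limit(self):
        p = LogisticParams(mu_max=0.6, x_m=25.0, x_0=3.0)
        lp = LuedekingPiretParams(alpha=0.4, beta=0.0, p_0=1.5)
        t = np.linspace(0, 8, 30)
        assert lipid(0.0, p, lp) == pytest.approx(1.5, rel=1e-14)
        # beta = 0: production tracks biomass gain exactly
        assert np.allclose(lipid(t, p, lp), 1.5 + 0.4 * (biomass(t, p) - 3.0), rtol=1e-13)

    def test_lipid_matches_numerical_ode(self, random_param_sets):
        """Closed-form P(t) vs high-accuracy integration of the ODE pair."""
        t_eval = np.linspace(0.0, 10.0, 41)
        for p, lp in random_param_sets:
            def rhs(t, y):
                x = y[0]
                dx = p.mu_max * x * (1 - x / p.x_m)
                return [dx, lp.alpha * dx + lp.beta * x]

            sol = solve_ivp(rhs, (0.0, 10.0), [p.x_0, lp.p_0], t_eval=t_eval,
                            rtol=1e-11, atol=1e-12, method="DOP853")
            assert np.allclose(lipid(t_eval, p, lp), sol.y[1], rtol=1e-6)

    def test_lipid_monotone_for_nonnegative_coefficients(self, random_param_sets):
        t = np.linspace(0, 12, 200)
        for p, lp in random_param_sets:
            assert np.all(np.diff(lipid(t, p, lp)) >= -1e-12)

    def test_cumulative_biomass_constant_trajectory(self):
        sat = LogisticParams(mu_max=0.5, x_m=20.0, x_0=20.0)
        assert cumulative_biomass(4.0, sat) == pytest.approx(80.0, rel=1e-14)


class TestRateInversionAndAnchoring:
    def test_branches_and_repeated_root(self):
        p = LogisticParams(mu_max=0.8, x_m=12.0, x_0=1.0)
        qmax = p.mu_max * p.x_m / 4
        assert biomass_from_rate(qmax, p, "pre_inflection") == pytest.approx(6.0)
        assert biomass_from_rate(qmax, p, "post_inflection") == pytest.approx(6.0)
        assert biomass_from_rate(0.0, p, "pre_inflection") == 0.0
        assert biomass_from_rate(0.0, p, "post_inflection") == pytest.approx(12.0)
        with pytest.raises(ValueError, match="exceeds logistic maximum"):
            biomass_from_rate(qmax * 1.01, p)

    def test_inversion_round_trip(self):
        p = LogisticParams(mu_max=0.4373, x_m=16.19, x_0=1.0)
        for q in (0.3, 0.9, 1.5115):
            for branch in ("pre_inflection", "post_inflection"):
                x = biomass_from_rate(q, p, branch)
                assert growth_rate(x, p) == pytest.approx(q, rel=1e-12)
        assert biomass_from_rate(1.5115, p, "pre_inflection") == pytest.approx(5.003, abs=2e-3)

    def test_anchor_reproduces_day1_rate(self, morphology):
        kp = KINETIC_PARAMS[morphology]
        q1 = DAY1_GROWTH_RATE[morphology]
        p = anchor_trajectory(q1, kp["mu_max"], kp["x_m"])
        assert growth_rate(biomass(1.0, p), p) == pytest.approx(q1, rel=1e-9)

    def test_anchor_recovers_known_inoculum(self):
        """Round trip: simulate day-1 rate from a known x_0, anchor, recover it."""
        truth = LogisticParams(mu_max=0.7, x_m=22.0, x_0=1.8)
        q1 = growth_rate(biomass(1.0, truth), truth)
        p = anchor_trajectory(q1, truth.mu_max, truth.x_m)
        assert p.x_0 == pytest.approx(truth.x_0, rel=1e-10)

    def test_hollow_anchor_value(self):
        p = anchor_trajectory(1.5115, 0.4373, 16.19)
        assert p.x_0 == pytest.approx(3.628, abs=2e-3)


class TestDailyRateTables:
    def test_reproduces_published_daily_rates(self, morphology, anchored):
        """All 8 published (Q_X, Q_L) pairs per morphology, within print rounding."""
        p, lp = anchored
        rt = rate_table(p, lp, range(1, 9))
        printed = np.array(DAILY_RATES[morphology])
        assert np.max(np.abs(rt.q_x - printed[:, 0])) <= 2e-3
        assert np.max(np.abs(rt.q_l - printed[:, 1])) <= 2e-3

    def test_grid_max_bounded_by_continuous_max(self, random_param_sets):
        for p, lp in random_param_sets:
            rt = rate_table(p, lp, range(1, 9))
            assert rt.q_x_max <= p.mu_max * p.x_m / 4 + 1e-12

    def test_dispersed_peak_on_day_two(self):
        p, lp = (anchor_trajectory(DAY1_GROWTH_RATE["dispersed"], 1.153, 30.68),
                 LuedekingPiretParams(alpha=0.2289, beta=0.0127))
        rt = rate_table(p, lp, range(1, 9))
        assert rt.day[np.argmax(rt.q_x)] == 2
        assert rt.q_x_max == pytest.approx(8.6831, abs=2e-3)


class TestFitting:
    def test_logistic_noise_free_recovery(self, random_param_sets):
        t = np.arange(0.0, 9.0)
        for p, _ in random_param_sets[:8]:
            tc = TimeCourse(t=t, x=biomass(t, p))
            fit = fit_logistic(tc)
            assert fit.converged
            assert fit.params.mu_max == pytest.approx(p.mu_max, rel=1e-4)
            assert fit.params.x_m == pytest.approx(p.x_m, rel=1e-4)
            assert fit.params.x_0 == pytest.approx(p.x_0, rel=1e-4)

    def test_logistic_recovery_published_fluffy(self, fluffy_params):
        p, _ = fluffy_params
        t = np.arange(0.0, 9.0)
        fit = fit_logistic(TimeCourse(t=t, x=biomass(t, p)))
        assert fit.params.mu_max == pytest.approx(0.6584, rel=1e-4)
        assert fit.params.x_m == pytest.approx(28.44, rel=1e-4)

    def test_logistic_degenerate_series_flagged(self):
        tc = TimeCourse(t=np.arange(5.0), x=np.full(5, 3.0))
        fit = fit_logistic(tc)
        assert not fit.converged
        assert "degenerate_series" in fit.flags

    def test_logistic_too_few_points(self):
        with pytest.raises(ValueError, match=">= 4"):
            fit_logistic(TimeCourse(t=np.arange(3.0), x=np.array([1.0, 2.0, 3.0])))

    def test_logistic_fixed_x0_mode(self, fluffy_params):
        p, _ = fluffy_params
        t = np.arange(0.0, 9.0)
        fit = fit_logistic(TimeCourse(t=t, x=biomass(t, p)), fix_x_0=p.x_0)
        assert fit.params.x_0 == p.x_0
        assert fit.params.mu_max == pytest.approx(p.mu_max, rel=1e-6)

    def test_logistic_noisy_monte_carlo(self, fluffy_params):
        """Median fitted mu_max over noisy replicates stays within 5% of truth."""
        p, _ = fluffy_params
        t = np.arange(0.0, 9.0)
        clean = biomass(t, p)
        rng = np.random.default_rng(7)
        mus = []
        for _ in range(200):
            x = np.clip(clean + rng.normal(0, 0.5, size=t.shape), 1e-6, None)
            fit = fit_logistic(TimeCourse(t=t, x=x))
            if fit.converged:
                mus.append(fit.params.mu_max)
        assert len(mus) > 150
        assert np.median(mus) == pytest.approx(p.mu_max, rel=0.05)

    def test_luedeking_piret_noise_free_recovery(self, random_param_sets):
        t = np.arange(0.0, 9.0)
        for p, lp in random_param_sets[:8]:
            tc = TimeCourse(t=t, x=biomass(t, p), p=lipid(t, p, lp))
            fit = fit_luedeking_piret(tc, p)
            assert fit.params.alpha == pytest.approx(lp.alpha, rel=1e-6, abs=1e-12)
            assert fit.params.beta == pytest.approx(lp.beta, rel=1e-6, abs=1e-12)

    def test_luedeking_piret_recovery_published_fluffy(self, fluffy_params):
        p, lp = fluffy_params
        t = np.arange(0.0, 9.0)
        tc = TimeCourse(t=t, x=biomass(t, p), p=lipid(t, p, lp))
        fit = fit_luedeking_piret(tc, p)
        assert fit.params.alpha == pytest.approx(0.3531, rel=1e-6)
        assert fit.params.beta == pytest.approx(0.0204, rel=1e-6)

    def test_luedeking_piret_zero_production(self, fluffy_params):
        p, _ = fluffy_params
        t = np.arange(0.0, 9.0)
        tc = TimeCourse(t=t, x=biomass(t, p), p=np.full(t.shape, 2.0))
        fit = fit_luedeking_piret(tc, p)
        assert fit.params.alpha == 0.0
        assert fit.params.beta == 0.0

    def test_luedeking_piret_negative_clipped_and_flagged(self, fluffy_params):
        p, _ = fluffy_params
        t = np.arange(0.0, 9.0)
        # declining product cannot come from nonnegative alpha, beta
        tc = TimeCourse(t=t, x=biomass(t, p), p=np.linspace(5.0, 4.9, len(t)))
        fit = fit_luedeking_piret(tc, p)
        assert "negative_coefficient_clipped" in fit.flags
        assert fit.params.alpha >= 0 and fit.params.beta >= 0

    def test_luedeking_piret_requires_lipid_column(self, fluffy_params):
        p, _ = fluffy_params
        with pytest.raises(ValueError, match="lipid"):
            fit_luedeking_piret(TimeCourse(t=np.arange(5.0), x=np.arange(1.0, 6.0)), p)

    def test_day3_rates_from_anchored_hollow(self):
        """Forward computation at day 3 hits the published growth and lipid rates."""
        p = anchor_trajectory(1.5115, 0.4373, 16.19)
        lp = LuedekingPiretParams(alpha=0.5594, beta=0.0037)
        x3 = biomass(3.0, p)
        q3 = growth_rate(x3, p)
        assert q3 == pytest.approx(1.7678, abs=2e-3)
        assert lipid_rate(x3, q3, lp) == pytest.approx(1.0198, abs=2e-3)
        assert x3 == pytest.approx(8.378, abs=2e-3)


from hypothesis import given, settings
from hypothesis import strategies as st


@settings(max_examples=60, derandomize=True, deadline=None)
@given(
    mu=st.floats(0.05, 3.0),
    x_m=st.floats(0.5, 60.0),
    frac=st.floats(1e-3, 1.0 - 1e-9),
    t=st.floats(0.0, 25.0),
)
def test_rate_law_inversion_is_exact(mu, x_m, frac, t):
    """growth_rate and biomass_from_rate are mutual inverses along any
    valid trajectory, on whichever side of the inflection X(t) falls."""
    p = LogisticParams(mu_max=mu, x_m=x_m, x_0=frac * x_m)
    x = biomass(t, p)
    q = growth_rate(x, p)
    branch = "pre_inflection" if x <= x_m / 2 else "post_inflection"
    assert biomass_from_rate(q, p, branch) == pytest.approx(x, rel=1e-6, abs=1e-9)


class TestValidation:
    @pytest.mark.parametrize("mu,xm,x0", [(-0.1, 10, 1), (0.5, -1, 1), (0.5, 10, 0),
                                          (0.5, 10, 11)])
    def test_invalid_logistic_params(self, mu, xm, x0):
        with pytest.raises(ValueError):
            LogisticParams(mu_max=mu, x_m=xm, x_0=x0)

    def test_invalid_lp_params(self):
        with pytest.raises(ValueError):
            LuedekingPiretParams(alpha=-0.1, beta=0.0)

    def test_timecourse_requires_increasing_times(self):
        with pytest.raises(ValueError, match="strictly increasing"):
            TimeCourse(t=np.array([0.0, 2.0, 1.0]), x=np.ones(3))
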