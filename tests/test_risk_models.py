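import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import integrate

from t2dsim.cohort import CohortProfile, generate_cohort, generate_event_panel, impute_missing
from t2dsim.risk import (
    FitRejectedError,
    RiskEquation,
    RiskModelError,
    annual_event_probability,
    density,
    fit_risk_equation,
    inverse_survival,
    linear_predictor,
    mortality_probability,
    retinopathy_survival,
    select_model,
    survival,
)


def eq(family="exponential", intercept=0.0, shape=None, gamma=None, knots=None, **betas):
    return RiskEquation(
        outcome="test",
        family=family,
        coefficients={"intercept": intercept, **betas},
        shape=shape,
        spline_gamma=gamma,
        knots=knots,
    )


# ---------------------------------------------------------------------------
# linear predictor


class TestLinearPredictor:
    def test_all_zero_covariates_returns_intercept(self):
        e = eq(intercept=-2.5, hba1c=0.2, sbp=0.01)
        assert linear_predictor(e, {"hba1c": 0.0, "sbp": 0.0}) == -2.5

    def test_hand_arithmetic(self):
        e = eq(intercept=-1.0, hba1c=0.2)
        assert linear_predictor(e, {"hba1c": 7.0}) == pytest.approx(0.4)

    def test_extra_covariate_ignored(self):
        e = eq(intercept=-1.0, hba1c=0.2)
        with_extra = linear_predictor(e, {"hba1c": 7.0, "unused": 99.0})
        assert with_extra == pytest.approx(0.4)

    def test_missing_covariate_is_error_naming_it(self):
        e = eq(intercept=0.0, hba1c=0.2, sbp=0.01)
        with pytest.raises(RiskModelError, match="sbp"):
            linear_predictor(e, {"hba1c": 7.0})

    def test_vectorised(self):
        e = eq(intercept=0.0, x=2.0)
        out = linear_predictor(e, {"x": np.array([1.0, 2.0, 3.0])})
        np.testing.assert_allclose(out, [2.0, 4.0, 6.0])


# ---------------------------------------------------------------------------
# survival families


class TestSurvival:
    @pytest.mark.parametrize(
        "e",
        [
            eq("exponential"),
            eq("weibull", shape=1.7),
            eq("gompertz", shape=0.1),
            eq("loglogistic", shape=0.5),
            eq("lognormal", shape=0.8),
        ],
    )
    def test_s0_is_one(self, e):
        assert survival(e, 0.3, 0.0) == pytest.approx(1.0)

    def test_exponential_closed_form(self):
        e = eq("exponential", intercept=np.log(0.1))
        assert survival(e, np.log(0.1), 10.0) == pytest.approx(np.exp(-1.0), abs=1e-12)

    def test_weibull_shape_one_equals_exponential(self):
        w = eq("weibull", shape=1.0)
        x = eq("exponential")
        ts = np.linspace(0, 20, 50)
        np.testing.assert_allclose(survival(w, -1.2, ts), survival(x, -1.2, ts), atol=1e-12)

    def test_gompertz_shape_to_zero_approaches_exponential(self):
        g = eq("gompertz", shape=1e-8)
        x = eq("exponential")
        ts = np.linspace(0, 20, 50)
        np.testing.assert_allclose(survival(g, -1.2, ts), survival(x, -1.2, ts), atol=1e-6)

    def test_negative_t_error(self):
        with pytest.raises(RiskModelError):
            survival(eq("exponential"), 0.0, -1.0)

    def test_logistic_not_a_survival_family(self):
        with pytest.raises(RiskModelError):
            survival(eq("logistic"), 0.0, 1.0)

    @settings(max_examples=60, deadline=None)
    @given(
        family=st.sampled_from(["exponential", "weibull", "gompertz", "loglogistic", "lognormal"]),
        lp=st.floats(-4, 1),
        shape=st.floats(0.3, 3.0),
    )
    def test_survival_is_monotone_nonincreasing(self, family, lp, shape):
        e = eq(family, shape=None if family == "exponential" else shape)
        ts = np.linspace(0.0, 30.0, 120)
        s = survival(e, lp, ts)
        assert s[0] == pytest.approx(1.0)
        assert np.all(np.diff(s) <= 1e-12)
        assert np.all((s >= 0) & (s <= 1))

    @settings(max_examples=40, deadline=None)
    @given(
        family=st.sampled_from(["exponential", "weibull", "gompertz", "loglogistic", "lognormal"]),
        lp=st.floats(-4, 0.5),
        shape=st.floats(0.4, 2.5),
        u=st.floats(0.01, 0.99),
    )
    def test_inverse_survival_roundtrip(self, family, lp, shape, u):
        e = eq(family, shape=None if family == "exponential" else shape)
        t = inverse_survival(e, lp, u)
        assert survival(e, lp, t) == pytest.approx(u, rel=1e-6, abs=1e-9)


class TestMortalityProbability:
    def test_lp_zero_gives_half(self):
        e = eq("logistic")
        assert mortality_probability(e, {}) == pytest.approx(0.5)

    def test_limits(self):
        assert mortality_probability(eq("logistic", intercept=-60.0), {}) == pytest.approx(0.0)
        assert mortality_probability(eq("logistic", intercept=60.0), {}) == pytest.approx(1.0)

    def test_log3_gives_three_quarters(self):
        e = eq("logistic", intercept=np.log(3.0))
        assert mortality_probability(e, {}) == pytest.approx(0.75)

    def test_rejects_non_logistic(self):
        with pytest.raises(RiskModelError):
            mortality_probability(eq("exponential"), {})


class TestAnnualEventProbability:
    def test_exponential_memoryless(self):
        lam = 0.13
        e = eq("exponential", intercept=np.log(lam))
        ps = [float(annual_event_probability(e, {}, t)) for t in range(10)]
        np.testing.assert_allclose(ps, 1 - np.exp(-lam), rtol=1e-12)

    def test_weibull_shape_two_increasing(self):
        e = eq("weibull", intercept=np.log(0.01), shape=2.0)
        ps = np.array([annual_event_probability(e, {}, float(t)) for t in range(12)])
        assert np.all(np.diff(ps) > 0)

    def test_probability_in_unit_interval_extremes(self):
        e = eq("exponential", intercept=10.0)  # enormous hazard
        assert annual_event_probability(e, {}, 0.0) == pytest.approx(1.0)

    @pytest.mark.parametrize(
        "e",
        [
            eq("exponential", intercept=-2.0),
            eq("weibull", intercept=-2.5, shape=1.6),
            eq("gompertz", intercept=-3.0, shape=0.08),
            eq("loglogistic", intercept=2.0, shape=0.6),
            eq("lognormal", intercept=2.2, shape=0.9),
            eq("flexible_parametric", gamma=(-3.0, 1.3, 0.05), knots=(-1.5, 0.8, 2.8)),
        ],
    )
    def test_quadrature_oracle(self, e):
        # p(t) must equal the conditional event mass int_t^{t+1} f / S(t)
        lp = e.coefficients["intercept"]
        for t in (0.0, 1.0, 3.0, 7.0):
            st_ = float(survival(e, lp, t))
            num, _ = integrate.quad(
                lambda u: float(density(e, lp, u)), t, t + 1.0, epsabs=1e-12, epsrel=1e-12
            )
            expected = num / st_
            got = float(annual_event_probability(e, {}, t))
            assert got == pytest.approx(expected, abs=1e-8)


class TestRetinopathySurvival:
    def test_reduces_to_weibull_when_spline_is_linear(self):
        # gamma = (log(lam), k) with no internal-knot terms is exactly
        # H = lam * t**k
        lam, k = 0.02, 1.4
        fp = eq("flexible_parametric", gamma=(np.log(lam), k), knots=(np.log(0.1), np.log(30.0)))
        wb = eq("weibull", shape=k)
        ts = np.linspace(0.0, 10.0, 40)
        np.testing.assert_allclose(
            retinopathy_survival(fp, 0.0, ts), survival(wb, np.log(lam), ts), rtol=1e-10
        )

    def test_s0_one_and_monotone(self):
        fp = eq(
            "flexible_parametric",
            gamma=(-3.5, 1.2, 0.08),
            knots=(np.log(0.5), np.log(3.0), np.log(15.0)),
        )
        ts = np.linspace(0.0, 10.0, 200)
        s = retinopathy_survival(fp, 0.2, ts)
        assert s[0] == pytest.approx(1.0)
        assert np.all(np.diff(s) <= 1e-12)

    def test_requires_flexible_parametric(self):
        with pytest.raises(RiskModelError):
            retinopathy_survival(eq("weibull", shape=1.0), 0.0, 1.0)


# ---------------------------------------------------------------------------
# fitting


def _fit_cohort(n, seed):
    return impute_missing(generate_cohort(CohortProfile(n=n, seed=seed)))


class TestFitRiskEquation:
    def test_exponential_mle_closed_form(self):
        # no-covariate exponential MLE: rate = events / person-time
        rng = np.random.default_rng(1)
        t = rng.exponential(1 / 0.2, 4000)
        horizon = 5.0
        panel = pd.DataFrame({"time": np.minimum(t, horizon), "event": (t <= horizon).astype(int)})
        fr = fit_risk_equation(panel, "exponential", [])
        expected = np.log(panel["event"].sum() / panel["time"].sum())
        assert fr.equation.coefficients["intercept"] == pytest.approx(expected, abs=1e-5)
        assert fr.converged

    def test_aic_definition(self):
        rng = np.random.default_rng(2)
        t = rng.exponential(2.0, 500)
        panel = pd.DataFrame({"time": t, "event": 1, "x": rng.normal(size=500)})
        fr = fit_risk_equation(panel, "weibull", ["x"])
        k = 3  # intercept, x, shape
        assert fr.equation.n_parameters == k
        assert fr.aic == pytest.approx(2 * k - 2 * fr.log_likelihood, abs=1e-9)

    def test_zero_events_error(self):
        panel = pd.DataFrame({"time": [1.0, 2.0], "event": [0, 0]})
        with pytest.raises(RiskModelError):
            fit_risk_equation(panel, "exponential", [])

    def test_weibull_parameter_recovery_within_3se(self):
        true = eq("weibull", intercept=-3.2, shape=1.8, hba1c=0.15, female=-0.3)
        cohort = _fit_cohort(20_000, 5)
        panel = generate_event_panel(cohort, true, horizon=10.0, seed=5)
        fr = fit_risk_equation(panel, "weibull", ["hba1c", "female"])
        assert fr.converged
        for name, truth in [("intercept", -3.2), ("hba1c", 0.15), ("female", -0.3)]:
            se = fr.standard_errors[name]
            assert abs(fr.equation.coefficients[name] - truth) < 3 * se, name
        assert abs(fr.equation.shape - 1.8) < 3 * fr.standard_errors["shape"]

    def test_logistic_fit_recovers_probability(self):
        rng = np.random.default_rng(3)
        p_true = 0.12
        y = (rng.random(30_000) < p_true).astype(int)
        panel = pd.DataFrame({"event": y})
        fr = fit_risk_equation(panel, "logistic", [])
        from scipy.special import expit

        assert expit(fr.equation.coefficients["intercept"]) == pytest.approx(
            y.mean(), abs=1e-6
        )

    def test_flexible_parametric_fits_weibull_data(self):
        true = eq("weibull", intercept=-2.7, shape=1.5, hba1c=0.2)
        cohort = _fit_cohort(8000, 9)
        panel = generate_event_panel(cohort, true, horizon=10.0, seed=9)
        fr = fit_risk_equation(panel, "flexible_parametric", ["hba1c"])
        assert fr.converged
        assert fr.equation.coefficients["hba1c"] == pytest.approx(0.2, abs=0.05)
        # fitted log-cumulative-hazard slope should be close to the Weibull shape
        assert fr.equation.spline_gamma[1] == pytest.approx(1.5, abs=0.2)


class TestSelectModel:
    def test_single_candidate_returned(self):
        rng = np.random.default_rng(4)
        panel = pd.DataFrame({"time": rng.exponential(2.0, 800), "event": 1})
        fr = select_model(panel, ["exponential"], [])
        assert fr.equation.family == "exponential"
        assert fr.aic_table[0][0] == "exponential"

    def test_tie_goes_to_first_family_in_order(self):
        rng = np.random.default_rng(5)
        panel = pd.DataFrame({"time": rng.exponential(2.0, 500), "event": 1})
        a = select_model(panel, ["exponential", "exponential"], [])
        assert a.equation.family == "exponential"
        assert len(a.aic_table) == 2

    def test_empty_candidate_list_error(self):
        with pytest.raises(RiskModelError):
            select_model(pd.DataFrame({"time": [1.0], "event": [1]}), [], [])

    def test_gompertz_selected_on_gompertz_data(self):
        # strong positive shape; scaled-down replicate study
        true = eq("gompertz", intercept=-4.2, shape=0.25, hba1c=0.1)
        wins = 0
        n_rep = 6
        for rep in range(n_rep):
            cohort = _fit_cohort(5000, 100 + rep)
            panel = generate_event_panel(cohort, true, horizon=12.0, seed=200 + rep)
            fr = select_model(
                panel,
                ["exponential", "weibull", "gompertz", "loglogistic", "lognormal"],
                ["hba1c"],
            )
            wins += fr.equation.family == "gompertz"
        assert wins > n_rep / 2


class TestEquationValidation:
    def test_unknown_family_rejected(self):
        with pytest.raises(RiskModelError):
            eq("gamma", shape=1.0)

    def test_negative_shape_rejected(self):
        with pytest.raises(RiskModelError):
            eq("weibull", shape=-1.0)

    def test_gompertz_negative_shape_allowed(self):
        eq("gompertz", shape=-0.05)

    def test_flexparam_requires_knots(self):
        with pytest.raises(RiskModelError):
            RiskEquation("x", "flexible_parametric", {"intercept": 0.0})
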