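"""Weibull PH model: closed forms, conditionals, and the interval-censored MLE."""

import math

import numpy as np
import pytest
from scipy import integrate

from icval.event import (
    FitError,
    WeibullPH,
    WeibullPHParams,
    conditional_density_given_failure,
    fit_interval_censored,
    interval_conditional_survival,
    predict_binary,
    survival,
)
from icval.simulate import draw_event_time


class TestSurvivalHazard:
    def test_survival_at_zero_is_one(self):
        m = WeibullPHParams(0.7, 1.25, [0.3, -0.2])
        assert survival(0.0, [1.0, 2.0], m) == 1.0

    def test_median_closed_form(self):
        # (lambda * 1)^kappa = log 2 with X'beta = 0 gives S(1) = 1/2
        kappa = 1.7
        lam = math.log(2.0) ** (1.0 / kappa)
        m = WeibullPHParams(lam, kappa, [0.0])
        assert survival(1.0, [3.0], m) == pytest.approx(0.5, abs=1e-12)

    def test_direct_evaluation(self):
        m = WeibullPHParams(0.3, 1.25, [math.log(2), math.log(1.5)])
        expected = math.exp(-(0.3**1.25) * 3.0)  # e^{X'beta} = 2 * 1.5 = 3
        assert survival(1.0, [1.0, 1.0], m) == pytest.approx(expected, rel=1e-12)

    def test_exponential_limit_constant_hazard(self):
        m = WeibullPHParams(0.4, 1.0, [0.0])
        t = np.array([0.2, 1.0, 5.0])
        np.testing.assert_allclose(m.hazard(t, [0.0]), 0.4)

    def test_hazard_integrates_to_cumulative_hazard(self):
        m = WeibullPHParams(0.6, 1.4, [0.5])
        X = [1.0]
        val, _ = integrate.quad(lambda u: float(m.hazard(u, X)[0]), 0.0, 2.0)
        assert val == pytest.approx(-math.log(float(m.survival(2.0, X)[0])), rel=1e-8)

    def test_proportional_hazards_property(self):
        base = WeibullPHParams(0.6, 1.4, [math.log(2.0)])
        t = np.linspace(0.1, 3.0, 7)
        ratio = base.hazard(t, [1.0]) / base.hazard(t, [0.0])
        np.testing.assert_allclose(ratio, 2.0)

    def test_negative_time_rejected(self):
        m = WeibullPHParams(1.0, 1.0, [0.0])
        with pytest.raises(ValueError):
            m.survival(-0.1, [0.0])
        with pytest.raises(ValueError):
            WeibullPHParams(1.0, 0.8, [0.0]).hazard(0.0, [0.0])


class TestPredictBinary:
    def test_threshold_is_strict(self):
        # S(t0) = 0.5 exactly: not predicted event-free at c = 0.5
        kappa = 1.0
        m = WeibullPHParams(math.log(2.0), kappa, [0.0])
        assert predict_binary([0.0], m, t0=1.0, c=0.5) == 0
        assert predict_binary([0.0], m, t0=0.5, c=0.5) == 1


class TestConditionals:
    def test_interval_conditional_survival_endpoints(self, exp_model):
        assert interval_conditional_survival(3.0, 1.0, 2.0, [0.0], exp_model) == 0.0
        assert interval_conditional_survival(3.0, 4.0, 9.0, [0.0], exp_model) == 1.0

    def test_interval_conditional_survival_closed_form(self, exp_model):
        # exponential rate 1, T in (0, 2], t0 = 1
        expected = (math.exp(-1) - math.exp(-2)) / (1 - math.exp(-2))
        got = interval_conditional_survival(1.0, 0.0, 2.0, [0.0], exp_model)
        assert got == pytest.approx(expected, rel=1e-12)

    def test_interval_conditional_survival_monte_carlo(self, exp_model, rng):
        t = rng.exponential(size=400_000)
        keep = t <= 2.0
        mc = np.mean(t[keep] > 1.0)
        got = interval_conditional_survival(1.0, 0.0, 2.0, [0.0], exp_model)
        assert got == pytest.approx(mc, abs=4 * 0.5 / math.sqrt(keep.sum()))

    def test_monotone_nonincreasing_in_landmark(self, exp_model):
        vals = [
            interval_conditional_survival(t0, 0.5, 4.0, [0.0], exp_model)
            for t0 in np.linspace(0.6, 3.9, 12)
        ]
        assert all(b <= a + 1e-12 for a, b in zip(vals, vals[1:]))

    def test_right_censored_interval_uses_infinite_endpoint(self, exp_model):
        got = interval_conditional_survival(1.0, 0.5, math.inf, [0.0], exp_model)
        # T | T > 0.5 memoryless: P(T > 1) = e^{-0.5}
        assert got == pytest.approx(math.exp(-0.5), rel=1e-12)

    def test_conditional_density_normalizes(self):
        m = WeibullPHParams(0.7, 1.25, [math.log(2.0)])
        X = [0.6]
        val, _ = integrate.quad(
            lambda t: conditional_density_given_failure(t, 2.0, X, m), 1e-12, 2.0
        )
        assert val == pytest.approx(1.0, abs=1e-6)

    def test_conditional_density_exponential_closed_form(self):
        h = 1.3
        m = WeibullPHParams(h, 1.0, [0.0])
        t0, t = 2.0, 0.7
        expected = h * math.exp(-h * t) / (1 - math.exp(-h * t0))
        assert conditional_density_given_failure(t, t0, [0.0], m) == pytest.approx(
            expected, rel=1e-12
        )

    def test_conditional_density_domain(self, exp_model):
        with pytest.raises(ValueError):
            conditional_density_given_failure(2.5, 2.0, [0.0], exp_model)


class TestFit:
    def test_tight_intervals_match_uncensored_mle(self, rng):
        """Width-1e-6 intervals reproduce the uncensored Weibull regression MLE.

        Oracle: lifelines' WeibullAFTFitter on the exact times (an AFT fit;
        the PH parameters are a reparameterisation)."""
        from lifelines import WeibullAFTFitter
        import pandas as pd

        n = 600
        X = rng.standard_normal((n, 1))
        true = WeibullPHParams(0.8, 1.3, [0.5])
        T = draw_event_time(X, true.lam, true.kappa, true.beta, rng)
        res = fit_interval_censored((np.maximum(T - 5e-7, 0.0), T + 5e-7, X))

        aft = WeibullAFTFitter()
        df = pd.DataFrame({"x": X[:, 0], "T": T, "E": 1})
        aft.fit(df, duration_col="T", event_col="E")
        lam_o = math.exp(-aft.params_["lambda_"]["Intercept"])
        kap_o = math.exp(aft.params_["rho_"]["Intercept"])
        beta_o = -kap_o * aft.params_["lambda_"]["x"]
        assert res.lam == pytest.approx(lam_o, abs=2e-3)
        assert res.kappa == pytest.approx(kap_o, abs=2e-3)
        assert res.beta[0] == pytest.approx(beta_o, abs=2e-3)

    def test_interval_censored_cross_check_lifelines(self, small_dataset):
        """On genuinely interval-censored data the MLE agrees with lifelines'
        interval-censoring fit (independent implementation)."""
        from lifelines import WeibullAFTFitter
        import pandas as pd

        model = WeibullPH.from_sample(small_dataset.train, (0, 1))
        res = model.fit()
        df = pd.DataFrame(model.X, columns=["x1", "x2"])
        df["lower"] = np.maximum(model.left, 1e-8)
        df["upper"] = model.right
        aft = WeibullAFTFitter()
        aft.fit_interval_censoring(df, lower_bound_col="lower", upper_bound_col="upper")
        kap_o = math.exp(aft.params_["rho_"]["Intercept"])
        lam_o = math.exp(-aft.params_["lambda_"]["Intercept"])
        beta_o = -kap_o * np.array(
            [aft.params_["lambda_"]["x1"], aft.params_["lambda_"]["x2"]]
        )
        assert res.kappa == pytest.approx(kap_o, rel=5e-3)
        assert res.lam == pytest.approx(lam_o, rel=5e-3)
        np.testing.assert_allclose(res.beta, beta_o, atol=5e-3)

    def test_loglike_at_mle_beats_truth(self, small_dataset, default_design):
        model = WeibullPH.from_sample(small_dataset.train, (0, 1))
        res = model.fit()
        d = default_design
        truth = np.r_[math.log(d.lam), math.log(d.config.kappa), d.config.beta]
        assert res.llf >= model.loglike(truth) - 1e-6

    def test_all_right_censored_fails(self):
        with pytest.raises(FitError, match="right-censored"):
            WeibullPH([1.0] * 10, [math.inf] * 10, np.zeros((10, 1)))

    def test_degenerate_identical_intervals_flagged(self):
        model = WeibullPH([1.0] * 10, [2.0] * 10, np.zeros((10, 1)))
        assert model.degenerate
        with pytest.raises(FitError, match="degenerate"):
            model.fit()

    def test_serialization_round_trip(self):
        m = WeibullPHParams(0.7, 1.25, [0.3, -0.2], covariate_indices=(0, 1))
        back = WeibullPHParams.from_json(m.to_json())
        assert back.lam == m.lam and back.kappa == m.kappa
        np.testing.assert_allclose(back.beta, m.beta)
        assert back.covariate_indices == (0, 1)
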