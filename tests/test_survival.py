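"""Parametric survival families: closed forms, likelihood, MLE, selection."""

from __future__ import annotations

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import psmcea.survival as sv

from conftest import ipd


class TestSurvivalFunction:
    @pytest.mark.parametrize(
        "family,params",
        [
            ("exponential", (0.1,)),
            ("weibull", (10.0, 1.5)),
            ("gamma", (2.0, 5.0)),
            ("gompertz", (0.05, 0.03)),
            ("loglogistic", (10.0, 2.0)),
            ("lognormal", (2.0, 0.5)),
        ],
    )
    def test_starts_at_one(self, family, params):
        assert sv.survival(family, params, 0.0) == pytest.approx(1.0)

    @pytest.mark.parametrize(
        "family,params,t,expected",
        [
            ("loglogistic", (10.0, 2.0), 10.0, 0.5),  # S(scale) = 1/2 by definition
            ("exponential", (0.1,), 10.0, math.exp(-1.0)),
            ("weibull", (10.0, 1.0), 10.0, math.exp(-1.0)),  # shape 1 = exponential
            ("lognormal", (math.log(10.0), 1.0), 10.0, 0.5),  # median = e^mu
        ],
    )
    def test_closed_forms(self, family, params, t, expected):
        assert sv.survival(family, params, t) == pytest.approx(expected, rel=1e-9)

    def test_invalid_params_rejected(self):
        with pytest.raises(sv.InvalidParameterError):
            sv.survival("weibull", (-1.0, 2.0), 1.0)
        with pytest.raises(sv.InvalidParameterError):
            sv.survival("gompertz", (0.1, -0.5), 1.0)  # rate must be positive
        with pytest.raises(sv.InvalidParameterError):
            sv.survival("nosuch", (1.0,), 1.0)

    def test_gompertz_negative_shape_allowed(self):
        # defective distribution: S(inf) = exp(rate/shape) > 0
        s = sv.survival("gompertz", (-0.1, 0.05), 1e6)
        assert s == pytest.approx(math.exp(-0.05 / 0.1), rel=1e-6)

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(
        family=st.sampled_from(sv.FAMILIES),
        raw=st.tuples(
            st.floats(0.05, 30.0), st.floats(0.3, 4.0)
        ),
    )
    def test_monotone_into_unit_interval(self, family, raw):
        """S maps [0, 600] months into [0,1], non-increasing, for valid params."""
        if family == "exponential":
            params = (raw[0] / 10.0,)
        elif family == "lognormal":
            params = (math.log(raw[0]), raw[1])
        elif family == "gompertz":
            params = (raw[1] - 2.0, raw[0] / 10.0)  # shape may be negative
        else:
            params = raw
        t = np.linspace(0.0, 600.0, 301)
        s = sv.survival(family, params, t)
        assert np.all(s >= -1e-12) and np.all(s <= 1 + 1e-12)
        assert np.all(np.diff(s) <= 1e-12)
        assert s[0] == pytest.approx(1.0)


class TestLogLikelihood:
    def test_exponential_event_closed_form(self):
        ll = sv.log_likelihood("exponential", (0.5,), [2.0], [1])
        assert ll == pytest.approx(math.log(0.5 * math.exp(-1.0)), abs=1e-12)

    def test_exponential_censoring_closed_form(self):
        ll = sv.log_likelihood("exponential", (0.5,), [2.0], [0])
        assert ll == pytest.approx(-1.0, abs=1e-12)

    def test_weibull_shape_one_nests_exponential(self, rng):
        """Weibull(scale=1/rate, shape=1) reproduces the exponential likelihood."""
        times = rng.exponential(5.0, size=10)
        events = rng.integers(0, 2, size=10)
        events[0] = 1
        lam = 0.23
        ll_exp = sv.log_likelihood("exponential", (lam,), times, events)
        ll_wei = sv.log_likelihood("weibull", (1.0 / lam, 1.0), times, events)
        assert ll_wei == pytest.approx(ll_exp, rel=1e-10)

    def test_gompertz_small_shape_nests_exponential(self):
        t = np.linspace(0.5, 40.0, 20)
        s_gom = sv.survival("gompertz", (1e-8, 0.1), t)
        s_exp = sv.survival("exponential", (0.1,), t)
        assert np.allclose(s_gom, s_exp, atol=1e-6)

    def test_zero_event_time_is_finite(self):
        for family, params in [
            ("weibull", (5.0, 0.8)),
            ("lognormal", (1.0, 1.0)),
            ("gamma", (0.5, 5.0)),
        ]:
            ll = sv.log_likelihood(family, params, [0.0], [1])
            assert np.isfinite(ll)


class TestFitMLE:
    def test_exponential_closed_form_uncensored(self):
        fit = sv.fit_mle("exponential", [1.0, 2.0, 3.0], [1, 1, 1])
        assert fit.params[0] == pytest.approx(3.0 / 6.0, abs=1e-12)

    def test_exponential_closed_form_censored(self):
        fit = sv.fit_mle("exponential", [1.0, 2.0], [1, 0])
        assert fit.params[0] == pytest.approx(1.0 / 3.0, abs=1e-12)

    def test_all_censored_raises(self):
        with pytest.raises(sv.NoEventsError):
            sv.fit_mle("weibull", [1.0, 2.0], [0, 0])

    def test_information_criteria_identities(self):
        fit = sv.fit_mle("weibull", [1.0, 2.0, 3.0, 4.0], [1, 1, 0, 1])
        assert fit.aic == pytest.approx(2 * fit.k - 2 * fit.log_lik, abs=1e-12)
        assert fit.bic == pytest.approx(fit.k * math.log(fit.n) - 2 * fit.log_lik, abs=1e-12)
        assert fit.k == 2

    def test_loglogistic_parameter_recovery(self):
        from psmcea.synthetic import SurvivalTruth, simulate_ipd

        truth = SurvivalTruth("loglogistic", (10.0, 2.0))
        df = simulate_ipd(truth, 5000, admin_censor=1e6, dropout_rate=0.0, seed=7)
        fit = sv.fit_mle("loglogistic", df["time_months"], df["event"])
        assert fit.params[0] == pytest.approx(10.0, rel=0.05)
        assert fit.params[1] == pytest.approx(2.0, rel=0.05)

    @pytest.mark.parametrize("family", ["weibull", "loglogistic", "lognormal", "exponential"])
    def test_agrees_with_lifelines(self, family):
        """Independent oracle: lifelines' parametric fitters on the same data."""
        import lifelines

        from psmcea.synthetic import SurvivalTruth, simulate_ipd

        truths = {
            "weibull": ("weibull", (12.0, 1.4)),
            "loglogistic": ("loglogistic", (10.0, 2.0)),
            "lognormal": ("lognormal", (2.3, 0.7)),
            "exponential": ("exponential", (0.08,)),
        }
        df = simulate_ipd(SurvivalTruth(*truths[family]), 800, 40.0, 0.01, seed=3)
        fit = sv.fit_mle(family, df["time_months"], df["event"])
        fitter = {
            "weibull": lifelines.WeibullFitter,
            "loglogistic": lifelines.LogLogisticFitter,
            "lognormal": lifelines.LogNormalFitter,
            "exponential": lifelines.ExponentialFitter,
        }[family]()
        fitter.fit(df["time_months"], df["event"])
        if family == "weibull":
            ours, theirs = fit.params, (fitter.lambda_, fitter.rho_)
        elif family == "loglogistic":
            ours, theirs = fit.params, (fitter.alpha_, fitter.beta_)
        elif family == "lognormal":
            ours, theirs = fit.params, (fitter.mu_, fitter.sigma_)
        else:  # lifelines parameterizes the exponential by its scale 1/rate
            ours, theirs = (1.0 / fit.params[0],), (fitter.lambda_,)
        assert np.allclose(ours, theirs, rtol=1e-3)


class TestRanking:
    def _mk(self, family, ll, n=100):
        params = {"exponential": (0.1,)}.get(family, (10.0, 1.5))
        return sv.ParametricFit(family, params, ll, n)

    def test_argmin_selected(self):
        fits = [
            self._mk("weibull", -100.0),
            self._mk("loglogistic", -97.1),
            self._mk("gamma", -103.25),
        ]
        ranking = sv.rank_fits(fits, "aic")
        assert ranking.selected == "loglogistic"
        aics = [a for _, a, _ in ranking.entries]
        assert aics == sorted(aics)

    def test_tie_prefers_fewer_parameters(self):
        # exponential k=1 at ll, weibull k=2 at ll+1 have equal AIC
        fits = [self._mk("weibull", -99.0), self._mk("exponential", -100.0)]
        assert sv.rank_fits(fits, "aic").selected == "exponential"

    def test_mixed_sample_sizes_rejected(self):
        with pytest.raises(ValueError):
            sv.rank_fits([self._mk("weibull", -10, n=50), self._mk("gamma", -10, n=60)])

    def test_generating_family_recovered(self):
        """AIC ranks log-logistic first on most log-logistic samples (n=1000)."""
        from psmcea.synthetic import SurvivalTruth, simulate_ipd

        truth = SurvivalTruth("loglogistic", (10.0, 2.0))
        wins = 0
        n_rep = 20
        for rep in range(n_rep):
            df = simulate_ipd(truth, 1000, admin_censor=1e6, seed=100 + rep)
            fits = sv.fit_all(df["time_months"], df["event"])
            if sv.rank_fits(fits, "aic").selected == "loglogistic":
                wins += 1
        assert wins >= 0.8 * n_rep


class TestMedian:
    @pytest.mark.parametrize(
        "family,params,expected",
        [
            ("exponential", (0.1,), math.log(2) / 0.1),
            ("loglogistic", (9.84, 1.3), 9.84),
            ("weibull", (10.0, 2.0), 10.0 * math.log(2) ** 0.5),
            ("lognormal", (2.0, 0.7), math.exp(2.0)),
        ],
    )
    def test_closed_forms(self, family, params, expected):
        assert sv.median_survival((family, params)) == pytest.approx(expected, rel=1e-9)

    @pytest.mark.parametrize(
        "family,params",
        [("gompertz", (0.05, 0.05)), ("gamma", (2.3, 4.1)), ("gompertz", (-0.01, 0.08))],
    )
    def test_agrees_with_independent_root_finder(self, family, params):
        from scipy.optimize import brentq

        med = sv.median_survival((family, params))
        root = brentq(lambda t: sv.survival(family, params, t) - 0.5, 1e-9, 1e4)
        assert med == pytest.approx(root, abs=1e-6)

    def test_defective_gompertz_median_undefined(self):
        # surviving fraction exp(-0.05/0.2) ~ 0.78 > 0.5
        with pytest.raises(sv.UndefinedMedianError):
            sv.median_survival(("gompertz", (-0.2, 0.05)))
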