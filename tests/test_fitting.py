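"""Parametric survival fitting, information-criterion ranking, screening."""

import numpy as np
import pandas as pd
import pytest
from lifelines import LogNormalFitter, WeibullFitter

import mcrc_cea as m
from mcrc_cea.fitting import (
    FAMILIES,
    CurveSet,
    FitResult,
    fit_all,
    fit_parametric,
    rank_fits,
    screen_pair,
    survival_at,
)


def _complete(times):
    return pd.DataFrame({"time_months": times, "event": 1})


# true parameters per family used for the recovery study
_TRUE_PARAMS = {
    "exponential": {"rate": 0.1},
    "weibull": {"shape": 1.2704, "scale": 13.21},
    "gompertz": {"rate": 0.05, "shape": 0.06},
    "gamma": {"shape": 1.6, "scale": 8.0},
    "loglogistic": {"shape": 2.0, "scale": 10.0},
    "lognormal": {"mu": 2.3, "sigma": 0.8},
    "generalized_gamma": {"mu": 2.5, "sigma": 0.7, "q": 0.8},
}


def _sample_from(family, params, n, rng):
    u = rng.uniform(size=n)
    if family == "exponential":
        return -np.log(u) / params["rate"]
    if family == "weibull":
        return params["scale"] * (-np.log(u)) ** (1.0 / params["shape"])
    if family == "gompertz":
        a, b = params["rate"], params["shape"]
        return np.log1p(-b * np.log(u) / a) / b
    if family == "gamma":
        return rng.gamma(params["shape"], params["scale"], size=n)
    if family == "loglogistic":
        return params["scale"] * (1.0 / u - 1.0) ** (1.0 / params["shape"])
    if family == "lognormal":
        return np.exp(params["mu"] + params["sigma"] * rng.standard_normal(n))
    if family == "generalized_gamma":
        # inverse-CDF via the gamma representation (q > 0)
        from scipy import stats

        q = params["q"]
        g = stats.gamma(q**-2).ppf(1 - u)
        w = np.log(q * q * g) / q
        return np.exp(params["mu"] + params["sigma"] * w)
    raise ValueError(family)


class TestMaximumLikelihood:
    def test_exponential_closed_form(self):
        fit = fit_parametric(_complete([1.0, 2.0, 3.0, 4.0, 5.0]), "exponential")
        assert fit.params["rate"] == pytest.approx(5.0 / 15.0, rel=1e-6)

    def test_all_censored_rejected(self):
        ipd = pd.DataFrame({"time_months": [1.0, 2.0], "event": [0, 0]})
        with pytest.raises(ValueError):
            fit_parametric(ipd, "weibull")

    def test_unknown_family_rejected(self):
        with pytest.raises(ValueError):
            fit_parametric(_complete([1, 2, 3]), "frechet")

    @pytest.mark.parametrize("family", FAMILIES)
    def test_parameter_recovery(self, family):
        rng = np.random.default_rng(12345)
        truth = _TRUE_PARAMS[family]
        t = _sample_from(family, truth, 10_000, rng)
        fit = fit_parametric(_complete(t), family)
        assert fit.converged
        for name, value in truth.items():
            assert fit.params[name] == pytest.approx(value, rel=0.05), name

    def test_weibull_on_exponential_data_shape_one(self):
        rng = np.random.default_rng(7)
        t = rng.exponential(10.0, size=10_000)
        fit = fit_parametric(_complete(t), "weibull")
        assert fit.params["shape"] == pytest.approx(1.0, rel=0.03)

    def test_censored_fit_matches_lifelines(self, arm_specs):
        ipd = m.simulate_arm_ipd(
            arm_specs[("control", "PFS")], 1000, m.CensorSpec(), seed=4
        )
        ours = fit_parametric(ipd, "weibull")
        ll = WeibullFitter().fit(ipd["time_months"], ipd["event"])
        assert ours.loglik == pytest.approx(ll.log_likelihood_, abs=1e-3)
        assert ours.params["scale"] == pytest.approx(ll.lambda_, rel=1e-4)
        assert ours.params["shape"] == pytest.approx(ll.rho_, rel=1e-4)
        ours_ln = fit_parametric(ipd, "lognormal")
        ll_ln = LogNormalFitter().fit(ipd["time_months"], ipd["event"])
        assert ours_ln.loglik == pytest.approx(ll_ln.log_likelihood_, abs=1e-3)

    def test_information_criterion_identities(self):
        fits = fit_all(_complete(np.linspace(1, 30, 40)))
        for f in fits:
            p = f.n_params
            assert f.aic == pytest.approx(-2 * f.loglik + 2 * p, abs=1e-12)
            assert f.bic == pytest.approx(-2 * f.loglik + p * np.log(f.n), abs=1e-12)


class TestRanking:
    def _mk(self, family, aic, bic):
        return FitResult(family, {"rate": 1.0}, 0.0, aic, bic, 10, 10, True)

    def test_lowest_aic_first(self):
        fits = [self._mk("a", 100, 110), self._mk("b", 95, 112), self._mk("c", 103, 100)]
        assert rank_fits(fits)[0].family == "b"

    def test_near_tie_broken_by_bic(self):
        fits = [self._mk("a", 100.0, 110), self._mk("b", 100.5, 104)]
        assert rank_fits(fits)[0].family == "b"

    def test_nonconverged_excluded(self):
        bad = FitResult("x", {"rate": 1.0}, 0.0, 1.0, 1.0, 10, 10, False)
        with pytest.raises(ValueError):
            rank_fits([bad])

    def test_true_family_wins_by_bic_penalty(self):
        # on exponential data the 1-parameter model outranks generalized gamma
        rng = np.random.default_rng(11)
        ipd = _complete(rng.exponential(8.0, size=5000))
        ranked = rank_fits(
            [fit_parametric(ipd, "exponential"),
             fit_parametric(ipd, "generalized_gamma")]
        )
        assert ranked[0].family == "exponential"


class TestSurvivalEvaluation:
    def test_exponential_closed_form_value(self):
        fit = FitResult("exponential", {"rate": 1 / 3}, 0, 0, 0, 5, 5, True)
        assert survival_at(fit, 3.0) == pytest.approx(np.exp(-1.0), rel=1e-12)

    @pytest.mark.parametrize("family", FAMILIES)
    def test_survival_at_zero_is_one(self, family):
        fit = FitResult(family, _TRUE_PARAMS[family], 0, 0, 0, 5, 5, True)
        assert survival_at(fit, 0.0) == 1.0

    def test_negative_time_rejected(self):
        fit = FitResult("exponential", {"rate": 0.5}, 0, 0, 0, 5, 5, True)
        with pytest.raises(ValueError):
            survival_at(fit, -1.0)

    def test_calibrated_weibull_median_identity(self):
        shape, scale = m.calibrate_control_weibull(9.9, 14.8, 0.60)
        fit = FitResult("weibull", {"shape": shape, "scale": scale}, 0, 0, 0, 5, 5, True)
        assert survival_at(fit, 9.9) == pytest.approx(0.5, abs=1e-9)

    def test_gengamma_weibull_reduction(self):
        gg = FitResult(
            "generalized_gamma",
            {"mu": np.log(13.21), "sigma": 1 / 1.2704, "q": 1.0},
            0, 0, 0, 5, 5, True,
        )
        wb = FitResult("weibull", {"shape": 1.2704, "scale": 13.21}, 0, 0, 0, 5, 5, True)
        ts = np.array([1.0, 5.0, 13.21, 30.0])
        assert gg.survival(ts) == pytest.approx(wb.survival(ts), abs=1e-12)

    def test_gengamma_lognormal_limit(self):
        gg = FitResult(
            "generalized_gamma", {"mu": 2.0, "sigma": 0.5, "q": 1e-6},
            0, 0, 0, 5, 5, True,
        )
        ln = FitResult("lognormal", {"mu": 2.0, "sigma": 0.5}, 0, 0, 0, 5, 5, True)
        ts = np.array([1.0, 5.0, 10.0, 40.0])
        assert gg.survival(ts) == pytest.approx(ln.survival(ts), abs=1e-6)


class TestScreening:
    def test_equal_curves_pass(self):
        s = lambda t: np.exp(-0.05 * np.asarray(t, float))
        cs = CurveSet("control", s_pfs=s, s_os=s)
        assert screen_pair(cs, np.linspace(0, 240, 100))

    def test_pfs_above_os_fails(self):
        cs = CurveSet(
            "control",
            s_pfs=lambda t: np.exp(-0.05 * np.asarray(t, float)),
            s_os=lambda t: np.exp(-0.10 * np.asarray(t, float)),
        )
        assert not screen_pair(cs, np.linspace(0, 240, 100))

    def test_trial_calibrated_pair_passes(self, curve_sets, settings):
        grid = np.arange(settings.n_cycles + 1) * settings.cycle_months
        for cs in curve_sets:
            assert screen_pair(cs, grid)
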