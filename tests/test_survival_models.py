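"""Parametric fitting, model selection and anchor calibration."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from capecea import (
    SurvivalParams,
    calibrate_time_scale,
    fit_parametric,
    goodness_of_fit,
    select_best,
    survival_at,
)
from capecea.errors import CalibrationError, DomainError, EstimationError
from capecea.survival_models import DISTRIBUTIONS, GOFStats, SurvivalFit, fit_all
from capecea.synthetic_trial import KMCurve, TrialConfig, generate_trial, kaplan_meier


class TestFitting:
    def test_exponential_closed_form_uncensored(self):
        fit = fit_parametric([1.0, 2.0, 3.0], [1, 1, 1], "exponential")
        assert fit.params["rate"] == pytest.approx(0.5, abs=1e-10)

    def test_exponential_closed_form_censored(self):
        fit = fit_parametric([1.0, 2.0, 3.0], [1, 0, 1], "exponential")
        assert fit.params["rate"] == pytest.approx(2 / 6, abs=1e-10)

    def test_lognormal_closed_form_uncensored(self):
        rng = np.random.default_rng(3)
        t = np.exp(rng.normal(2.0, 0.5, size=80))
        fit = fit_parametric(t, np.ones(80), "lognormal")
        lt = np.log(t)
        assert fit.params["mu"] == pytest.approx(lt.mean(), abs=1e-6)
        # MLE sigma is the 1/n (not 1/(n-1)) standard deviation
        assert fit.params["sigma"] == pytest.approx(lt.std(), abs=1e-6)

    def test_lognormal_parameter_recovery_censored(self):
        rng = np.random.default_rng(42)
        n = 2000
        t = np.exp(rng.normal(6.0, 0.9, size=n))
        cens = rng.uniform(200.0, 2000.0, size=n)
        fit = fit_parametric(np.minimum(t, cens), t <= cens, "lognormal")
        # +-0.06 is ~3 Monte-Carlo standard errors at this n and censoring
        assert fit.params["mu"] == pytest.approx(6.0, abs=0.06)
        assert fit.params["sigma"] == pytest.approx(0.9, abs=0.06)

    def test_loglik_matches_manual_computation(self):
        t = np.array([5.0, 10.0, 20.0, 40.0])
        d = np.array([1, 1, 0, 1])
        fit = fit_parametric(t, d, "weibull")
        dist = stats.weibull_min(fit.params["shape"], scale=fit.params["scale"])
        manual = dist.logpdf(t[d == 1]).sum() + dist.logsf(t[d == 0]).sum()
        assert fit.loglik == pytest.approx(manual, rel=1e-12)

    def test_too_few_events_rejected(self):
        with pytest.raises(EstimationError):
            fit_parametric([1.0, 2.0, 3.0], [1, 0, 0], "weibull")

    def test_all_censored_rejected(self):
        with pytest.raises(EstimationError):
            fit_parametric([1.0, 2.0], [0, 0], "exponential")

    def test_nonpositive_times_rejected(self):
        with pytest.raises(EstimationError):
            fit_parametric([0.0, 2.0, 3.0], [1, 1, 1], "exponential")

    @pytest.mark.parametrize("name", DISTRIBUTIONS)
    def test_every_family_fits_trial_like_data(self, trial_records, name):
        sub = trial_records[trial_records["arm"] == "observation"]
        fit = fit_parametric(sub["dfs_time"], sub["dfs_event"], name)
        assert np.isfinite(fit.loglik)
        assert all(np.isfinite(v) for v in fit.params.values())


class TestSurvivalAt:
    def test_lognormal_median(self):
        sp = SurvivalParams("lognormal", mu=3.0, sigma=0.7)
        assert survival_at(sp, np.exp(3.0)) == pytest.approx(0.5, abs=1e-12)

    def test_zero_time_is_one(self):
        sp = SurvivalParams("lognormal", mu=6.4, sigma=0.908)
        assert survival_at(sp, 0.0) == 1.0

    def test_printed_params_one_sigma_above(self):
        # t with (ln t - mu)/sigma = 1  ->  S = 1 - Phi(1)
        sp = SurvivalParams("lognormal", mu=6.400, sigma=0.908)
        t = np.exp(6.400 + 0.908)
        assert survival_at(sp, t) == pytest.approx(1 - stats.norm.cdf(1.0), abs=1e-10)

    def test_negative_time_rejected(self):
        sp = SurvivalParams("lognormal", mu=1.0, sigma=1.0)
        with pytest.raises(DomainError):
            survival_at(sp, -1.0)

    @settings(deadline=None, max_examples=60)
    @given(
        name=st.sampled_from(DISTRIBUTIONS),
        p1=st.floats(0.3, 3.0),
        p2=st.floats(0.2, 50.0),
    )
    def test_monotone_and_bounded(self, name, p1, p2):
        params = {
            "exponential": {"rate": p1 / 10.0},
            "weibull": {"shape": p1, "scale": p2},
            "lognormal": {"mu": np.log(p2), "sigma": p1},
            "loglogistic": {"shape": p1, "scale": p2},
            "gamma": {"shape": p1, "scale": p2},
        }[name]
        fit = SurvivalFit(name, params, loglik=0.0, n=1, n_events=1)
        grid = np.linspace(0.0, 200.0, 101)
        s = survival_at(fit, grid)
        assert np.all(s <= 1.0 + 1e-12) and np.all(s >= -1e-12)
        assert np.all(np.diff(s) <= 1e-12)
        assert s[0] == pytest.approx(1.0)


class TestGoodnessOfFitAndSelection:
    def _km(self, fit, times):
        return KMCurve(
            times=np.asarray(times, float),
            survival=np.asarray(survival_at(fit, np.asarray(times, float))),
            at_risk=np.full(len(times), 10.0),
        )

    def test_aic_bic_identities(self):
        fit = SurvivalFit("weibull", {"shape": 1.2, "scale": 30.0}, loglik=-100.0, n=100, n_events=60)
        g = goodness_of_fit(fit, self._km(fit, [5.0, 10.0]))
        assert g.neg2loglik == pytest.approx(200.0)
        assert g.aic == pytest.approx(204.0)
        assert g.bic == pytest.approx(200.0 + 2 * np.log(100))

    def test_perfect_agreement_gives_zero_sse(self):
        fit = SurvivalFit("exponential", {"rate": 0.05}, loglik=-10.0, n=20, n_events=20)
        g = goodness_of_fit(fit, self._km(fit, [1.0, 5.0, 25.0]))
        assert g.sse_vs_km == pytest.approx(0.0, abs=1e-15)

    def test_empty_km_support_rejected(self):
        fit = SurvivalFit("exponential", {"rate": 0.05}, loglik=-10.0, n=20, n_events=20)
        with pytest.raises(DomainError):
            goodness_of_fit(fit, KMCurve(np.array([]), np.array([]), np.array([])))

    def test_smaller_k_wins_on_equal_loglik(self):
        f1 = SurvivalFit("exponential", {"rate": 0.1}, loglik=-50.0, n=40, n_events=30)
        f2 = SurvivalFit("weibull", {"shape": 1.0, "scale": 10.0}, loglik=-50.0, n=40, n_events=30)
        km = self._km(f1, [2.0, 8.0])
        gof = {"exponential": goodness_of_fit(f1, km), "weibull": goodness_of_fit(f2, km)}
        assert gof["exponential"].aic < gof["weibull"].aic
        assert gof["exponential"].bic < gof["weibull"].bic

    def test_dominant_candidate_selected(self):
        fits = {
            "a": SurvivalFit("exponential", {"rate": 0.1}, -50.0, 40, 30),
            "b": SurvivalFit("weibull", {"shape": 1.0, "scale": 10.0}, -60.0, 40, 30),
        }
        gof = {
            "a": GOFStats(aic=102, bic=104, neg2loglik=100, sse_vs_km=0.01, k=1, n=40),
            "b": GOFStats(aic=124, bic=128, neg2loglik=120, sse_vs_km=0.05, k=2, n=40),
        }
        assert select_best(fits, gof) is fits["a"]

    def test_single_candidate_selected(self):
        fits = {"a": SurvivalFit("exponential", {"rate": 0.1}, -50.0, 40, 30)}
        gof = {"a": GOFStats(102, 104, 100, 0.01, 1, 40)}
        assert select_best(fits, gof) is fits["a"]

    def test_empty_candidates_rejected(self):
        with pytest.raises(DomainError):
            select_best({}, {})

    def test_lognormal_recovered_on_lognormal_trial_data(self):
        wins = 0
        for seed in range(1, 9):
            records = generate_trial(TrialConfig(seed=seed))
            sub = records[records["arm"] == "observation"]
            fits = fit_all(sub["dfs_time"], sub["dfs_event"])
            km = kaplan_meier(records, "dfs", "observation")
            gof = {k: goodness_of_fit(v, km) for k, v in fits.items()}
            wins += select_best(fits, gof).distribution == "lognormal"
        # log-normal truth should win a clear majority of replicates
        assert wins >= 5


class TestCalibration:
    def test_single_anchor_closed_form(self):
        sp = SurvivalParams("lognormal", mu=6.400, sigma=0.908)
        cal = calibrate_time_scale(sp, [(60.0, 0.828)])
        expected = np.log(60.0) + 0.908 * stats.norm.ppf(0.828)
        assert cal.params.mu == pytest.approx(expected, abs=1e-9)
        assert cal.params.mu == pytest.approx(4.9536, abs=1e-3)
        assert cal.params.sigma == 0.908  # shape preserved
        assert cal.residual_sse == pytest.approx(0.0, abs=1e-12)
        assert survival_at(cal.params, 60.0) == pytest.approx(0.828, abs=1e-9)

    def test_already_satisfied_anchor_is_noop(self):
        sp = SurvivalParams("lognormal", mu=4.9536, sigma=0.908)
        mu_cal = calibrate_time_scale(sp, [(60.0, 0.828)]).params.mu
        cal = calibrate_time_scale(SurvivalParams("lognormal", mu_cal, 0.908), [(60.0, 0.828)])
        assert cal.params.mu == pytest.approx(mu_cal, abs=1e-12)
        assert cal.log_scale == pytest.approx(0.0, abs=1e-12)

    def test_time_unit_doubling_shifts_location_by_ln2(self):
        sp = SurvivalParams("lognormal", mu=6.0, sigma=0.8)
        a = calibrate_time_scale(sp, [(60.0, 0.8)]).params.mu
        b = calibrate_time_scale(sp, [(120.0, 0.8)]).params.mu
        assert b - a == pytest.approx(np.log(2.0), abs=1e-12)

    def test_unattainable_anchor_rejected(self):
        sp = SurvivalParams("lognormal", mu=6.0, sigma=0.8)
        with pytest.raises(CalibrationError):
            calibrate_time_scale(sp, [(60.0, 1.2)])
        with pytest.raises(CalibrationError):
            calibrate_time_scale(sp, [])
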