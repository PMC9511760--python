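"""Parametric survival modelling for extrapolation beyond the trial window.

Five candidate right-censored maximum-likelihood fits (exponential, Weibull,
log-normal, log-logistic, gamma), goodness-of-fit statistics against the
Kaplan-Meier curve, a composite model-selection rule, and the anchor-based
time-scale calibration that resolves the unit ambiguity of externally
reported log-normal fits.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import optimize, stats

from .errors import CalibrationError, DomainError, EstimationError
from .parameters import SurvivalParams

DISTRIBUTIONS = ("exponential", "weibull", "lognormal", "loglogistic", "gamma")

_OPT_TOL = 1e-8  # fixed convergence tolerance: deterministic fits


@dataclass(frozen=True)
class SurvivalFit:
    distribution: str
    params: Mapping[str, float]
    loglik: float
    n: int
    n_events: int
    time_unit: str = "months"

    def survival(self, t) -> np.ndarray:
        return survival_at(self, t)


@dataclass(frozen=True)
class GOFStats:
    """AIC = -2LL + 2k, BIC = -2LL + k ln n, SSE against the KM step times."""

    aic: float
    bic: float
    neg2loglik: float
    sse_vs_km: float
    k: int
    n: int


@dataclass(frozen=True)
class CalibrationResult:
    params: SurvivalParams
    log_scale: float  # ln(c) applied to the location: mu' = mu + ln(c)... stored as mu' - mu
    residual_sse: float  # squared survival-scale deviation left at the anchors


# ---------------------------------------------------------------------------
# distribution primitives (scipy.stats frozen distributions per parameter dict)


def _frozen(distribution: str, params: Mapping[str, float]):
    if distribution == "exponential":
        return stats.expon(scale=1.0 / params["rate"])
    if distribution == "weibull":
        return stats.weibull_min(params["shape"], scale=params["scale"])
    if distribution == "lognormal":
        return stats.lognorm(params["sigma"], scale=np.exp(params["mu"]))
    if distribution == "loglogistic":
        return stats.fisk(params["shape"], scale=params["scale"])
    if distribution == "gamma":
        return stats.gamma(params["shape"], scale=params["scale"])
    raise DomainError(f"unknown distribution {distribution!r}")


def _pack(distribution: str, params: Mapping[str, float]) -> np.ndarray:
    # optimizer works on unconstrained log-scale (mu is already unconstrained)
    if distribution == "lognormal":
        return np.array([params["mu"], np.log(params["sigma"])])
    keys = _param_names(distribution)
    return np.log(np.array([params[k] for k in keys]))


def _unpack(distribution: str, x: np.ndarray) -> dict:
    if distribution == "lognormal":
        return {"mu": float(x[0]), "sigma": float(np.exp(x[1]))}
    keys = _param_names(distribution)
    return {k: float(np.exp(v)) for k, v in zip(keys, x)}


def _param_names(distribution: str) -> tuple[str, ...]:
    return {
        "exponential": ("rate",),
        "weibull": ("shape", "scale"),
        "lognormal": ("mu", "sigma"),
        "loglogistic": ("shape", "scale"),
        "gamma": ("shape", "scale"),
    }[distribution]


def log_likelihood(
    distribution: str, params: Mapping[str, float], times, events
) -> float:
    """Right-censored log-likelihood: sum of log f over events, log S over censored."""
    t = np.asarray(times, dtype=float)
    d = np.asarray(events, dtype=bool)
    dist = _frozen(distribution, params)
    ll = dist.logpdf(t[d]).sum() + dist.logsf(t[~d]).sum()
    return float(ll)


def _start_values(distribution: str, times, events) -> dict:
    """Method-of-moments starting values (documented, deterministic)."""
    t = np.asarray(times, dtype=float)
    d = np.asarray(events, dtype=bool)
    obs = t[d] if d.sum() >= 2 else t
    m, v = float(np.mean(obs)), float(np.var(obs)) or (0.25 * float(np.mean(obs)) ** 2)
    if distribution == "exponential":
        return {"rate": d.sum() / t.sum()}
    if distribution == "weibull":
        cv = np.sqrt(v) / m
        return {"shape": max(0.5, min(5.0, 1.0 / max(cv, 0.2))), "scale": m}
    if distribution == "lognormal":
        lt = np.log(obs)
        return {"mu": float(np.mean(lt)), "sigma": max(float(np.std(lt)), 1e-3)}
    if distribution == "loglogistic":
        lt = np.log(obs)
        s = max(float(np.std(lt)), 1e-3)
        return {"shape": np.pi / (np.sqrt(3.0) * s), "scale": float(np.exp(np.mean(lt)))}
    if distribution == "gamma":
        return {"shape": max(m * m / v, 0.05), "scale": v / m}
    raise DomainError(f"unknown distribution {distribution!r}")


def fit_parametric(times, events, distribution: str) -> SurvivalFit:
    """Maximum-likelihood fit of one candidate distribution to censored data.

    The exponential rate has the closed form d / sum(t) and is used directly;
    the remaining families are maximized numerically (L-BFGS-B on log-scale
    parameters from method-of-moments starts, tolerance 1e-8).
    """
    t = np.asarray(times, dtype=float)
    d = np.asarray(events, dtype=bool).astype(int)
    if distribution not in DISTRIBUTIONS:
        raise DomainError(f"unknown distribution {distribution!r}")
    if np.any(t <= 0):
        raise EstimationError("all times must be > 0")
    if d.sum() < 2:
        raise EstimationError("need at least 2 events to fit a survival model")

    if distribution == "exponential":
        rate = float(d.sum() / t.sum())
        params = {"rate": rate}
    else:
        x0 = _pack(distribution, _start_values(distribution, t, d))

        def nll(x):
            p = _unpack(distribution, x)
            ll = log_likelihood(distribution, p, t, d)
            return np.inf if not np.isfinite(ll) else -ll

        res = optimize.minimize(
            nll, x0, method="L-BFGS-B", options={"ftol": _OPT_TOL, "gtol": _OPT_TOL}
        )
        if not res.success and not np.isfinite(res.fun):
            raise EstimationError(f"{distribution} fit failed: {res.message}")
        params = _unpack(distribution, res.x)

    ll = log_likelihood(distribution, params, t, d)
    if not np.isfinite(ll):
        raise EstimationError(f"{distribution} fit produced non-finite log-likelihood")
    return SurvivalFit(
        distribution=distribution,
        params=params,
        loglik=ll,
        n=len(t),
        n_events=int(d.sum()),
    )


def fit_all(times, events) -> dict[str, SurvivalFit]:
    """Fit every candidate family; families that fail to converge are skipped."""
    fits = {}
    for name in DISTRIBUTIONS:
        try:
            fits[name] = fit_parametric(times, events, name)
        except EstimationError:
            continue
    if not fits:
        raise EstimationError("no candidate distribution could be fitted")
    return fits


# ---------------------------------------------------------------------------
# survival evaluation


def survival_at(fit_or_params, t) -> np.ndarray | float:
    """S(t) for a SurvivalFit or log-normal SurvivalParams; S(0) = 1.

    For the log-normal, S(t) = 1 - Phi((ln t - mu) / sigma).
    """
    scalar = np.isscalar(t)
    tt = np.atleast_1d(np.asarray(t, dtype=float))
    if np.any(tt < 0):
        raise DomainError("t must be >= 0")
    if isinstance(fit_or_params, SurvivalParams):
        dist = _frozen("lognormal", {"mu": fit_or_params.mu, "sigma": fit_or_params.sigma})
    else:
        dist = _frozen(fit_or_params.distribution, fit_or_params.params)
    out = np.where(tt == 0.0, 1.0, dist.sf(np.maximum(tt, 1e-300)))
    out = np.clip(out, 0.0, 1.0)
    return float(out[0]) if scalar else out


# ---------------------------------------------------------------------------
# goodness of fit and model selection


def goodness_of_fit(fit: SurvivalFit, km_curve) -> GOFStats:
    """AIC/BIC/-2LL from the fit plus SSE of S_fit against the KM step times.

    ``km_curve`` needs ``times`` and ``survival`` arrays (event step times and
    the KM estimate immediately after each step).
    """
    times = np.asarray(km_curve.times, dtype=float)
    km = np.asarray(km_curve.survival, dtype=float)
    if len(times) == 0:
        raise DomainError("KM curve has empty support")
    k = len(fit.params)
    neg2 = -2.0 * fit.loglik
    sse = float(np.sum((survival_at(fit, times) - km) ** 2))
    return GOFStats(
        aic=neg2 + 2 * k,
        bic=neg2 + k * np.log(fit.n),
        neg2loglik=neg2,
        sse_vs_km=sse,
        k=k,
        n=fit.n,
    )


def select_best(
    fits: Mapping[str, SurvivalFit], gof: Mapping[str, GOFStats]
) -> SurvivalFit:
    """Composite selection: average rank over AIC, BIC, -2LL and SSE.

    Each criterion ranks candidates separately (lower is better); the best
    mean rank wins, ties broken by lower AIC then lexicographic name.
    """
    names = sorted(fits)
    if not names:
        raise DomainError("empty candidate list")
    criteria = np.array(
        [
            [getattr(gof[n], crit) for n in names]
            for crit in ("aic", "bic", "neg2loglik", "sse_vs_km")
        ]
    )
    ranks = np.argsort(np.argsort(criteria, axis=1), axis=1).astype(float)
    mean_rank = ranks.mean(axis=0)
    order = sorted(
        range(len(names)), key=lambda i: (mean_rank[i], gof[names[i]].aic, names[i])
    )
    return fits[names[order[0]]]


# ---------------------------------------------------------------------------
# anchor calibration


def calibrate_time_scale(
    params: SurvivalParams, anchors: Sequence[tuple[float, float]]
) -> CalibrationResult:
    """Rescale a log-normal fit's time unit so it meets survival anchors.

    A change of unit t -> c*t leaves sigma untouched and shifts the location
    to mu' = mu + ln(c). The least-squares solution on the probit scale is
    closed-form: mu' = mean over anchors of (ln t_a + sigma * Phi^-1(S_a)).
    The residual is reported as squared deviation on the survival scale.
    """
    anchors = [(float(t), float(s)) for t, s in anchors]
    if not anchors:
        raise CalibrationError("need at least one anchor")
    for t_a, s_a in anchors:
        if t_a <= 0:
            raise CalibrationError(f"anchor time must be > 0 (got {t_a})")
        if not 0.0 < s_a < 1.0:
            raise CalibrationError(f"anchor survival must be in (0, 1) (got {s_a})")
    mu_new = float(
        np.mean([np.log(t_a) + params.sigma * stats.norm.ppf(s_a) for t_a, s_a in anchors])
    )
    new = replace(params, mu=mu_new, time_unit="months")
    resid = float(
        sum((survival_at(new, t_a) - s_a) ** 2 for t_a, s_a in anchors)
    )
    return CalibrationResult(params=new, log_scale=mu_new - params.mu, residual_sse=resid)


def engine_survival_inputs(params_set) -> dict[str, dict[str, SurvivalParams]]:
    """Survival curves to feed the cohort engine, per the configured mode.

    "calibrated": printed sigma, location re-anchored to the 5-year trial
    survival (months). "as_printed": Table values read on a months axis.
    """
    out: dict[str, dict[str, SurvivalParams]] = {}
    for arm, eps in params_set.survival_params.items():
        out[arm] = {}
        for ep, sp in eps.items():
            if params_set.options.survival_input_mode == "calibrated":
                anchors = params_set.anchors.get(arm, {}).get(ep, ())
                if anchors:
                    out[arm][ep] = calibrate_time_scale(sp, anchors).params
                    continue
            out[arm][ep] = replace(sp, time_unit="months")
    return out
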