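"""Covariate-adjusted absolute risk reduction and number needed to treat.

The adjusted risk at a landmark time is obtained by g-computation
(standardization): a Cox proportional-hazards model with treatment and
baseline covariates (Efron tie handling, Breslow baseline hazard) is fitted
to the individual-patient data, then the model-predicted event risk at the
landmark is averaged over the FULL cohort's covariate distribution with the
treatment indicator forced to each arm in turn. ARR is the control-minus-
treated difference of those standardized risks and NNT its reciprocal;
confidence intervals come from a nonparametric bootstrap that refits the
whole procedure on each resample.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter

from .errors import DomainError, EstimationError

DEFAULT_COVARIATES = (
    "age",
    "menopausal",
    "tumor_size",
    "node_status",
    "ki67",
    "surgery_type",
)

_TREATED_ARM = "capecitabine"


@dataclass(frozen=True)
class CoxFit:
    model: CoxPHFitter
    covariates: tuple[str, ...]
    design_columns: tuple[str, ...]
    endpoint: str
    n: int
    n_events: int
    standardize: bool = True  # g-computation; False = mean-covariate plug-in

    @property
    def treatment_coef(self) -> float:
        return float(self.model.params_["treated"])

    @property
    def treatment_se(self) -> float:
        return float(self.model.standard_errors_["treated"])

    def coefficients(self) -> pd.Series:
        return self.model.params_.copy()


@dataclass(frozen=True)
class NNTResult:
    endpoint: str
    time: float
    arr: float
    nnt: float  # inf when arr <= 0 (non-beneficial)
    ci: tuple[float, float] | None = None

    @property
    def beneficial(self) -> bool:
        return self.arr > 0.0


def _design(records: pd.DataFrame, covariates: Sequence[str]) -> pd.DataFrame:
    df = records.copy()
    df["treated"] = (df["arm"] == _TREATED_ARM).astype(float)
    cols = ["treated"]
    for cov in covariates:
        if cov not in df.columns:
            raise EstimationError(f"covariate {cov!r} missing from records")
        if df[cov].dtype == object:
            dummies = pd.get_dummies(df[cov], prefix=cov, drop_first=True, dtype=float)
            df = pd.concat([df, dummies], axis=1)
            cols.extend(dummies.columns)
        else:
            cols.append(cov)
    # zero-variance columns make the partial likelihood singular; drop them
    keep = [c for c in cols if c == "treated" or df[c].nunique() > 1]
    return df, tuple(keep)


def fit_cox(
    records: pd.DataFrame,
    covariates: Sequence[str] = DEFAULT_COVARIATES,
    endpoint: str = "dfs",
    standardize: bool = True,
) -> CoxFit:
    """Fit the adjusted Cox model for one endpoint (dfs or os)."""
    endpoint = endpoint.lower()
    if endpoint not in ("dfs", "os"):
        raise DomainError(f"unknown endpoint {endpoint!r}")
    n_events = int(records[f"{endpoint}_event"].sum())
    if n_events < 2:
        raise EstimationError("need at least 2 events to fit a Cox model")
    df, cols = _design(records, covariates)
    data = df[list(cols)].copy()
    data["time"] = records[f"{endpoint}_time"].to_numpy()
    data["event"] = records[f"{endpoint}_event"].to_numpy()
    cph = CoxPHFitter()
    try:
        cph.fit(data, duration_col="time", event_col="event", show_progress=False)
    except Exception as exc:  # lifelines raises several convergence errors
        raise EstimationError(f"Cox fit failed: {exc}") from exc
    if not np.all(np.isfinite(cph.params_.to_numpy())):
        raise EstimationError("Cox fit produced non-finite coefficients")
    return CoxFit(
        model=cph,
        covariates=tuple(covariates),
        design_columns=cols,
        endpoint=endpoint,
        n=len(records),
        n_events=n_events,
        standardize=standardize,
    )


def adjusted_risk(fit: CoxFit, records: pd.DataFrame, arm: str, t: float) -> float:
    """Standardized event risk by time t with treatment forced to ``arm``."""
    max_t = float(records[f"{fit.endpoint}_time"].max())
    if t > max_t:
        raise DomainError(f"t={t} beyond observed follow-up ({max_t:.1f})")
    df, cols = _design(records, fit.covariates)
    X = df[list(fit.design_columns)].copy()
    for c in fit.design_columns:
        if c not in X.columns:
            X[c] = 0.0
    X["treated"] = 1.0 if arm == _TREATED_ARM else 0.0
    if not fit.standardize:
        X = X.mean(axis=0).to_frame().T  # mean-covariate plug-in variant
    surv = fit.model.predict_survival_function(X, times=[t])
    return float(1.0 - surv.iloc[0].mean())


def nnt_at(fit: CoxFit, records: pd.DataFrame, t: float) -> NNTResult:
    """Point estimate: ARR = risk(control) - risk(treated), NNT = 1/ARR."""
    risk_treated = adjusted_risk(fit, records, _TREATED_ARM, t)
    risk_control = adjusted_risk(fit, records, "observation", t)
    arr = risk_control - risk_treated
    nnt = 1.0 / arr if arr > 0.0 else float("inf")
    return NNTResult(endpoint=fit.endpoint, time=t, arr=arr, nnt=nnt)


def bootstrap_ci(
    records: pd.DataFrame,
    t: float,
    n_boot: int = 2000,
    seed: int = 0,
    endpoint: str = "dfs",
    covariates: Sequence[str] = DEFAULT_COVARIATES,
    level: float = 0.95,
) -> tuple[float, float]:
    """Percentile bootstrap CI of the NNT (refitting the Cox model each time).

    Percentiles are taken on the absolute-risk-reduction scale and inverted,
    because the NNT scale is discontinuous at ARR = 0: a resampled ARR at or
    below zero maps to an infinite (non-beneficial) NNT bound, so a CI whose
    upper end is ``inf`` spans the no-benefit region. Resamples on which the
    model cannot be fitted (no events, separation, single arm) are skipped,
    and more than 50% degenerate resamples is an estimation error.
    """
    if n_boot < 100:
        raise DomainError("n_boot must be >= 100")
    rng = np.random.default_rng(seed)
    n = len(records)
    arrs = []
    degenerate = 0
    for _ in range(n_boot):
        idx = rng.integers(0, n, size=n)
        sample = records.iloc[idx].reset_index(drop=True)
        try:
            fit = fit_cox(sample, covariates=covariates, endpoint=endpoint)
            res = nnt_at(fit, sample, t)
        except (EstimationError, DomainError):
            degenerate += 1
            continue
        arrs.append(res.arr)
    if degenerate > 0.5 * n_boot:
        raise EstimationError(
            f"{degenerate}/{n_boot} bootstrap resamples were degenerate"
        )
    alpha = (1.0 - level) / 2.0
    arr_lo, arr_hi = np.quantile(np.array(arrs), [alpha, 1.0 - alpha])
    nnt_low = 1.0 / arr_hi if arr_hi > 0 else float("inf")
    nnt_high = 1.0 / arr_lo if arr_lo > 0 else float("inf")
    return float(nnt_low), float(nnt_high)


def nnt_table(
    records: pd.DataFrame,
    times: Sequence[float],
    endpoints: Sequence[str] = ("dfs", "os"),
    n_boot: int = 0,
    seed: int = 0,
    covariates: Sequence[str] = DEFAULT_COVARIATES,
) -> pd.DataFrame:
    """NNT point estimates (and optional bootstrap CIs) at several landmarks."""
    rows = []
    for ep in endpoints:
        fit = fit_cox(records, covariates=covariates, endpoint=ep)
        for t in times:
            res = nnt_at(fit, records, t)
            ci = (np.nan, np.nan)
            if n_boot:
                ci = bootstrap_ci(
                    records, t, n_boot=n_boot, seed=seed, endpoint=ep, covariates=covariates
                )
            rows.append(
                {
                    "endpoint": ep,
                    "time": t,
                    "arr": res.arr,
                    "nnt": res.nnt,
                    "ci_low": ci[0],
                    "ci_high": ci[1],
                }
            )
    return pd.DataFrame(rows)


def cost_per_event_prevented(nnt: float, incremental_cost_per_patient: float) -> float:
    """Cost to prevent one additional event: NNT x incremental cost/patient."""
    if not np.isfinite(nnt) or nnt <= 0:
        raise DomainError("cost per event prevented requires a finite NNT > 0")
    return nnt * incremental_cost_per_patient
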