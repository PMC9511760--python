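"""Synthetic individual-patient data emulating a two-arm maintenance trial.

No individual-patient data from the source trial are deposited, so this
module generates a stand-in cohort: 221 patients randomized to capecitabine
maintenance and 213 to observation, disease-free-survival (DFS) and
overall-survival (OS) event times drawn from per-arm log-normal models whose
marginals equal the anchor-calibrated engine curves, uniform accrual plus an
administrative cutoff reproducing the trial's ~61-month median follow-up,
and six baseline covariates for Cox adjustment.

DFS and OS times share a single standard-normal residual per patient
(comonotone coupling): taking dfs = min(dfs_raw, os) then preserves both
marginal survival curves everywhere the DFS curve lies below the OS curve —
in particular throughout the observation window — while guaranteeing
dfs_time <= os_time record by record.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter

from .errors import ConfigurationError, EstimationError
from .parameters import ARMS, default_parameters
from .survival_models import engine_survival_inputs

#: column dictionary for the records frame (documented external interface)
RECORD_COLUMNS = {
    "id": "patient identifier",
    "arm": "capecitabine | observation",
    "age": "age at randomization, years",
    "menopausal": "pre | post",
    "tumor_size": "<=2cm | >2cm",
    "node_status": "negative | positive",
    "ki67": "low | high",
    "surgery_type": "mastectomy | breast-conserving",
    "dfs_time": "months to relapse/death or censoring",
    "dfs_event": "1 = relapse or death observed",
    "os_time": "months to death or censoring",
    "os_event": "1 = death observed",
}


@dataclass(frozen=True)
class CovariateModel:
    """Baseline covariate distribution and its accelerated-failure effects.

    Effects are additive shifts of log event time (months); negative values
    shorten survival. They are shared by both endpoints and centered, so the
    configured per-arm (mu, sigma) remain the marginal event-time parameters.
    """

    age_mean: float = 46.0
    age_sd: float = 9.0
    age_range: tuple[float, float] = (24.0, 70.0)
    p_postmenopausal: float = 0.45
    p_tumor_gt2cm: float = 0.45
    p_node_positive: float = 0.36
    p_ki67_high: float = 0.55
    p_breast_conserving: float = 0.15
    log_time_effects: Mapping[str, float] = field(
        default_factory=lambda: {
            "age_per_decade": -0.04,
            "postmenopausal": -0.02,
            "tumor_gt2cm": -0.12,
            "node_positive": -0.20,
            "ki67_high": -0.10,
            "breast_conserving": 0.02,
        }
    )

    def variance(self) -> float:
        """Population variance of the linear predictor (for residual scaling)."""
        e = self.log_time_effects
        v = (e["age_per_decade"] * self.age_sd / 10.0) ** 2
        for eff, p in (
            ("postmenopausal", self.p_postmenopausal),
            ("tumor_gt2cm", self.p_tumor_gt2cm),
            ("node_positive", self.p_node_positive),
            ("ki67_high", self.p_ki67_high),
            ("breast_conserving", self.p_breast_conserving),
        ):
            v += e[eff] ** 2 * p * (1.0 - p)
        return v


@dataclass(frozen=True)
class TrialConfig:
    """Generator configuration; defaults reproduce the trial's design."""

    n_per_arm: Mapping[str, int] = field(
        default_factory=lambda: {"capecitabine": 221, "observation": 213}
    )
    #: marginal log-normal (mu, sigma) on log-months, per arm and endpoint;
    #: None -> the anchor-calibrated default engine curves
    event_models: Mapping[str, Mapping[str, tuple[float, float]]] | None = None
    accrual_months: float = 24.0
    cutoff_months: float = 73.0  # accrual midpoint gives ~61-month median follow-up
    covariates: CovariateModel = field(default_factory=CovariateModel)
    use_covariate_effects: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if any(n <= 0 for n in self.n_per_arm.values()):
            raise ConfigurationError("n_per_arm values must be positive")
        if self.cutoff_months <= 0:
            raise ConfigurationError("censoring cutoff must be > 0")
        if self.accrual_months < 0:
            raise ConfigurationError("accrual window must be >= 0")
        if self.event_models is not None:
            for arm, eps in self.event_models.items():
                for ep, (_, sigma) in eps.items():
                    if sigma < 0:
                        raise ConfigurationError(
                            f"event model {arm}/{ep}: sigma must be >= 0"
                        )


def default_event_models() -> dict[str, dict[str, tuple[float, float]]]:
    """Anchor-calibrated marginals — identical to the engine's default curves."""
    surv = engine_survival_inputs(default_parameters())
    return {
        arm: {ep: (sp.mu, sp.sigma) for ep, sp in eps.items()}
        for arm, eps in surv.items()
    }


def generate_trial(config: TrialConfig | None = None, seed: int | None = None) -> pd.DataFrame:
    """Draw one synthetic trial as a records DataFrame (see RECORD_COLUMNS)."""
    config = config or TrialConfig()
    if seed is not None:
        config = replace(config, seed=seed)
    rng = np.random.default_rng(config.seed)
    models = config.event_models or default_event_models()

    frames = []
    offset = 0
    for arm in ARMS:
        n = int(config.n_per_arm.get(arm, 0))
        if n == 0:
            continue
        cov = _draw_covariates(config.covariates, n, rng)
        lp = (
            _linear_predictor(cov, config.covariates)
            if config.use_covariate_effects
            else np.zeros(n)
        )
        v_lp = config.covariates.variance() if config.use_covariate_effects else 0.0

        z = rng.standard_normal(n)  # shared residual -> comonotone DFS/OS
        times = {}
        for ep in ("dfs", "os"):
            mu, sigma = models[arm][ep]
            resid_var = sigma**2 - v_lp
            if resid_var < 0:
                raise ConfigurationError(
                    f"{arm}/{ep}: covariate effects exceed marginal variance"
                )
            times[ep] = np.exp(mu + lp + np.sqrt(resid_var) * z)
        t_os = times["os"]
        t_dfs = np.minimum(times["dfs"], t_os)

        accrual = rng.uniform(0.0, config.accrual_months, size=n)
        follow_up = np.maximum(config.cutoff_months - accrual, 1e-9)

        df = pd.DataFrame(cov)
        df.insert(0, "arm", arm)
        df.insert(0, "id", np.arange(offset, offset + n))
        df["dfs_time"] = np.minimum(t_dfs, follow_up)
        df["dfs_event"] = (t_dfs <= follow_up).astype(int)
        df["os_time"] = np.minimum(t_os, follow_up)
        df["os_event"] = (t_os <= follow_up).astype(int)
        frames.append(df)
        offset += n
    out = pd.concat(frames, ignore_index=True)
    return out[list(RECORD_COLUMNS)]


def _draw_covariates(cm: CovariateModel, n: int, rng: np.random.Generator) -> dict:
    age = cm.age_mean + cm.age_sd * rng.standard_normal(n)
    age = np.clip(age, *cm.age_range)
    return {
        "age": np.round(age, 1),
        "menopausal": np.where(rng.random(n) < cm.p_postmenopausal, "post", "pre"),
        "tumor_size": np.where(rng.random(n) < cm.p_tumor_gt2cm, ">2cm", "<=2cm"),
        "node_status": np.where(rng.random(n) < cm.p_node_positive, "positive", "negative"),
        "ki67": np.where(rng.random(n) < cm.p_ki67_high, "high", "low"),
        "surgery_type": np.where(
            rng.random(n) < cm.p_breast_conserving, "breast-conserving", "mastectomy"
        ),
    }


def _linear_predictor(cov: Mapping[str, np.ndarray], cm: CovariateModel) -> np.ndarray:
    e = cm.log_time_effects
    lp = e["age_per_decade"] * (np.asarray(cov["age"]) - cm.age_mean) / 10.0
    lp = lp + e["postmenopausal"] * (
        (np.asarray(cov["menopausal"]) == "post") - cm.p_postmenopausal
    )
    lp = lp + e["tumor_gt2cm"] * ((np.asarray(cov["tumor_size"]) == ">2cm") - cm.p_tumor_gt2cm)
    lp = lp + e["node_positive"] * (
        (np.asarray(cov["node_status"]) == "positive") - cm.p_node_positive
    )
    lp = lp + e["ki67_high"] * ((np.asarray(cov["ki67"]) == "high") - cm.p_ki67_high)
    lp = lp + e["breast_conserving"] * (
        (np.asarray(cov["surgery_type"]) == "breast-conserving") - cm.p_breast_conserving
    )
    return lp


# ---------------------------------------------------------------------------
# Kaplan-Meier estimation and trial summaries


@dataclass(frozen=True)
class KMCurve:
    """Right-continuous product-limit curve: S(t) constant between steps."""

    times: np.ndarray     # event (step) times
    survival: np.ndarray  # KM estimate just after each step
    at_risk: np.ndarray   # risk-set size just before each step

    def __call__(self, t) -> np.ndarray | float:
        scalar = np.isscalar(t)
        tt = np.atleast_1d(np.asarray(t, dtype=float))
        idx = np.searchsorted(self.times, tt, side="right")
        surv = np.concatenate([[1.0], self.survival])
        out = surv[idx]
        return float(out[0]) if scalar else out

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"time": self.times, "survival": self.survival, "at_risk": self.at_risk}
        )


def kaplan_meier(records: pd.DataFrame, endpoint: str, arm: str | None = None) -> KMCurve:
    """Product-limit estimator for one endpoint (optionally one arm)."""
    endpoint = endpoint.lower()
    if endpoint not in ("dfs", "os"):
        raise ConfigurationError(f"unknown endpoint {endpoint!r}")
    df = records if arm is None else records[records["arm"] == arm]
    if len(df) == 0:
        raise EstimationError(f"no records for arm {arm!r}")
    kmf = KaplanMeierFitter()
    kmf.fit(df[f"{endpoint}_time"], df[f"{endpoint}_event"])
    event_table = kmf.event_table
    steps = event_table[event_table["observed"] > 0]
    times = steps.index.to_numpy(dtype=float)
    surv = kmf.survival_function_at_times(times).to_numpy(dtype=float)
    at_risk = steps["at_risk"].to_numpy(dtype=float)
    return KMCurve(times=times, survival=surv, at_risk=at_risk)


def summarize_trial(records: pd.DataFrame, horizon_months: float = 60.0) -> dict:
    """Event/censoring counts, follow-up quantiles and landmark KM per arm."""
    if len(records) == 0:
        raise EstimationError("empty record collection")
    out: dict = {
        "n": int(len(records)),
        "n_per_arm": records["arm"].value_counts().to_dict(),
        "dfs_events": int(records["dfs_event"].sum()),
        "os_events": int(records["os_event"].sum()),
        "followup_quantiles_months": {
            q: float(records["os_time"].quantile(q)) for q in (0.25, 0.5, 0.75)
        },
        "landmark_months": horizon_months,
        "km": {},
    }
    for arm in records["arm"].unique():
        out["km"][arm] = {
            ep: float(kaplan_meier(records, ep, arm)(horizon_months))
            for ep in ("dfs", "os")
        }
    return out


# ---------------------------------------------------------------------------
# I/O


def write_records(records: pd.DataFrame, path, config: TrialConfig | None = None) -> None:
    """CSV export with a JSON sidecar echoing the generating configuration."""
    import json
    from pathlib import Path

    path = Path(path)
    records.to_csv(path, index=False)
    if config is not None:
        sidecar = {
            "columns": RECORD_COLUMNS,
            "n_per_arm": dict(config.n_per_arm),
            "accrual_months": config.accrual_months,
            "cutoff_months": config.cutoff_months,
            "seed": config.seed,
        }
        path.with_suffix(".json").write_text(json.dumps(sidecar, indent=2))


def read_records(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = [c for c in RECORD_COLUMNS if c not in df.columns]
    if missing:
        raise ConfigurationError(f"records file missing columns: {missing}")
    return df
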