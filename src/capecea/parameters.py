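"""Model parameterization: cost/utility/incidence entries, survival inputs,
the background-mortality life table, config I/O and discounting arithmetic.

The bundled default configuration reproduces the published base case: every
cost is in 2020 USD (fixed rate $1 = ¥6.4665), utilities are quality weights
in [0, 1], the cycle is one month and the horizon 360 cycles (30 years from
age 45).
"""

from __future__ import annotations

import copy
import io
from dataclasses import dataclass, field, replace
from importlib import resources
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
import yaml

from .errors import ConfigurationError, DomainError, ValidationError

ARMS = ("capecitabine", "observation")
ENDPOINTS = ("dfs", "os")

#: semantic kinds whose values must lie in [0, 1]
_UNIT_INTERVAL_KINDS = frozenset({"probability", "utility"})

#: every entry the bundled default config must define
REQUIRED_ENTRIES = (
    "cost_capecitabine_month",
    "cost_monitoring_month",
    "cost_relapse_month",
    "cost_followup_lt3y",
    "cost_followup_3to5y",
    "cost_followup_gt5y",
    "cost_time_y1_capecitabine",
    "cost_time_y1_observation",
    "cost_time_1to2y",
    "cost_time_3to5y",
    "cost_time_gt5y",
    "cost_travel_y1_capecitabine",
    "cost_travel_y1_observation",
    "cost_travel_1to2y",
    "cost_travel_3to5y",
    "cost_travel_gt5y",
    "cost_ae_hand_foot",
    "cost_ae_diarrhea",
    "incidence_hand_foot",
    "incidence_diarrhea",
    "utility_dfs",
    "utility_relapse",
    "disutility_hand_foot",
    "disutility_diarrhea",
    "annual_discount_rate",
    "transition_multiplier",
)

_PSA_DISTRIBUTIONS = ("gamma", "beta", "uniform", "fixed")


@dataclass(frozen=True)
class ParamEntry:
    """One model input with its deterministic range and PSA distribution."""

    name: str
    base: float
    low: float
    high: float
    psa_distribution: str = "fixed"
    kind: str = "cost"  # cost | probability | utility | rate | multiplier

    def __post_init__(self) -> None:
        if self.psa_distribution not in _PSA_DISTRIBUTIONS:
            raise ConfigurationError(
                f"{self.name}: unknown psa_distribution {self.psa_distribution!r}"
            )
        if not (self.low <= self.base <= self.high):
            raise ValidationError(
                f"{self.name}: range must satisfy low <= base <= high "
                f"(got {self.low}, {self.base}, {self.high})"
            )
        if self.kind in _UNIT_INTERVAL_KINDS:
            for label, v in (("low", self.low), ("base", self.base), ("high", self.high)):
                if not 0.0 <= v <= 1.0:
                    raise ValidationError(
                        f"{self.name}: {self.kind} {label} value {v} outside [0, 1]"
                    )


@dataclass(frozen=True)
class SurvivalParams:
    """A log-normal survival function S(t) = 1 - Phi((ln t - mu) / sigma).

    ``time_unit`` records the unit of t; the printed fits carry the
    unresolved unit ``"model-fit"`` until anchor calibration rescales them
    to months (see :func:`capecea.survival_models.calibrate_time_scale`).
    """

    distribution: str
    mu: float
    sigma: float
    time_unit: str = "model-fit"

    def __post_init__(self) -> None:
        if self.sigma <= 0:
            raise ValidationError(f"sigma must be > 0 (got {self.sigma})")


@dataclass(frozen=True)
class ModelOptions:
    """Structural conventions that are deliberately config-switchable."""

    #: relapse->death rule: "os_formula" applies 1 - S(t+1)/S(t) to the OS
    #: fit (the formula-based construction); "os_matching" decomposes the
    #: fitted OS decrement into background and relapse deaths each cycle.
    relapse_death_mode: str = "os_formula"
    #: survival inputs fed to the engine: "calibrated" re-anchors mu to the
    #: trial's 5-year survival; "as_printed" uses Table values on a months axis.
    survival_input_mode: str = "calibrated"
    #: charge routine follow-up concurrently with drug/monitoring in year 1
    followup_during_treatment: bool = True
    #: average adjacent-cycle occupancy when accruing costs/QALYs
    half_cycle_correction: bool = False
    #: charge relapse treatment per month of relapse-state occupancy
    #: ("occupancy") or once per incident relapse ("per_case")
    relapse_cost_mode: str = "occupancy"

    def __post_init__(self) -> None:
        if self.relapse_death_mode not in ("os_formula", "os_matching"):
            raise ConfigurationError(
                f"relapse_death_mode: unknown value {self.relapse_death_mode!r}"
            )
        if self.survival_input_mode not in ("calibrated", "as_printed"):
            raise ConfigurationError(
                f"survival_input_mode: unknown value {self.survival_input_mode!r}"
            )
        if self.relapse_cost_mode not in ("occupancy", "per_case"):
            raise ConfigurationError(
                f"relapse_cost_mode: unknown value {self.relapse_cost_mode!r}"
            )


@dataclass(frozen=True)
class ParameterSet:
    """The complete, validated model input set."""

    entries: Mapping[str, ParamEntry]
    survival_params: Mapping[str, Mapping[str, SurvivalParams]]
    anchors: Mapping[str, Mapping[str, tuple[float, float]]]
    wtp_threshold: float = 28130.0
    horizon: int = 360
    cycles_per_year: int = 12
    start_age: float = 45.0
    retirement_age: float = 55.0
    treatment_cycles: int = 12
    utility_death: float = 0.0
    options: ModelOptions = field(default_factory=ModelOptions)
    #: per-(arm, endpoint) multiplicative perturbation of monthly exit
    #: probabilities; the PSA samples these, the base case leaves them at 1
    transition_multipliers: Mapping[tuple[str, str], float] = field(
        default_factory=lambda: {(a, e): 1.0 for a in ARMS for e in ENDPOINTS}
    )

    def __post_init__(self) -> None:
        missing = [n for n in REQUIRED_ENTRIES if n not in self.entries]
        if missing:
            raise ConfigurationError(f"missing required entries: {missing}")
        if self.horizon < 0:
            raise ValidationError("horizon must be >= 0")
        if self.utility_death != 0.0:
            raise ValidationError("the death-state utility is fixed at 0")
        for arm in ARMS:
            for ep in ENDPOINTS:
                if ep not in self.survival_params.get(arm, {}):
                    raise ConfigurationError(f"missing survival params for {arm}/{ep}")

    def validate(self) -> "ParameterSet":
        """Base-case coherence checks (not applied to PSA draws, whose
        independently sampled utilities may legitimately cross)."""
        u_dfs, u_rel = self.value("utility_dfs"), self.value("utility_relapse")
        if not (0.0 <= u_rel <= u_dfs <= 1.0):
            raise ValidationError(
                f"utilities must satisfy 0 <= u_relapse <= u_DFS <= 1 "
                f"(got {u_rel}, {u_dfs})"
            )
        return self

    # -- accessors -----------------------------------------------------

    def value(self, name: str) -> float:
        try:
            return self.entries[name].base
        except KeyError:
            raise ConfigurationError(f"unknown parameter entry {name!r}") from None

    @property
    def annual_discount_rate(self) -> float:
        return self.value("annual_discount_rate")

    def varying_entries(self) -> list[str]:
        """Entries with a non-degenerate range (the one-way analysis set)."""
        return [n for n, e in self.entries.items() if e.high > e.low]

    # -- functional updates -------------------------------------------

    def with_value(self, name: str, value: float) -> "ParameterSet":
        """Copy of this set with one entry's base value replaced.

        The entry's range is widened if needed so the ParamEntry invariant
        keeps holding for out-of-range scenario values.
        """
        entry = self.entries[name] if name in self.entries else None
        if entry is None:
            raise ConfigurationError(f"unknown parameter entry {name!r}")
        new = replace(
            entry,
            base=float(value),
            low=min(entry.low, float(value)),
            high=max(entry.high, float(value)),
        )
        entries = dict(self.entries)
        entries[name] = new
        return replace(self, entries=entries)

    def with_values(self, values: Mapping[str, float]) -> "ParameterSet":
        ps = self
        for name, v in values.items():
            ps = ps.with_value(name, v)
        return ps

    def with_transition_multipliers(
        self, multipliers: Mapping[tuple[str, str], float]
    ) -> "ParameterSet":
        merged = dict(self.transition_multipliers)
        merged.update(multipliers)
        return replace(self, transition_multipliers=merged)

    def with_options(self, **kwargs) -> "ParameterSet":
        return replace(self, options=replace(self.options, **kwargs))


# ---------------------------------------------------------------------------
# discounting / mortality arithmetic


def discount_factor(
    annual_rate: float, cycle_index: int | np.ndarray, cycles_per_year: int = 12
) -> float | np.ndarray:
    """Compound discount factor (1 + r)^(-cycle / cycles_per_year).

    Exact at annual boundaries; monotone non-increasing in the cycle index.
    """
    cycle = np.asarray(cycle_index)
    if annual_rate < 0:
        raise DomainError("annual_rate must be >= 0")
    if np.any(cycle < 0):
        raise DomainError("cycle_index must be >= 0")
    out = (1.0 + annual_rate) ** (-cycle / cycles_per_year)
    return float(out) if np.isscalar(cycle_index) else out


@dataclass(frozen=True)
class LifeTable:
    """Age-indexed annual death probabilities (integer-age bands)."""

    ages: np.ndarray
    annual_probabilities: np.ndarray

    def __post_init__(self) -> None:
        ages = np.asarray(self.ages, dtype=int)
        probs = np.asarray(self.annual_probabilities, dtype=float)
        if ages.ndim != 1 or ages.shape != probs.shape or len(ages) == 0:
            raise ValidationError("life table must be two equal-length 1-d columns")
        if np.any(np.diff(ages) != 1):
            raise ValidationError("life-table ages must be contiguous integers")
        if np.any((probs < 0) | (probs > 1)):
            raise ValidationError("annual death probabilities must lie in [0, 1]")
        object.__setattr__(self, "ages", ages)
        object.__setattr__(self, "annual_probabilities", probs)

    @classmethod
    def from_csv(cls, path_or_buffer) -> "LifeTable":
        df = pd.read_csv(path_or_buffer)
        expected = {"age", "annual_death_probability"}
        if not expected.issubset(df.columns):
            raise ConfigurationError(
                f"life-table CSV must have columns {sorted(expected)}"
            )
        df = df.sort_values("age")
        return cls(df["age"].to_numpy(), df["annual_death_probability"].to_numpy())

    def annual_probability(self, age: float) -> float:
        """Annual q for the integer age band containing ``age``.

        Below the table span is a domain error; beyond the last age the final
        probability is carried forward (bounded extrapolation).
        """
        if age < self.ages[0]:
            raise DomainError(f"age {age} below life-table span ({self.ages[0]})")
        idx = min(int(np.floor(age)) - int(self.ages[0]), len(self.ages) - 1)
        return float(self.annual_probabilities[idx])

    def monthly_probability(self, age: float) -> float:
        q = self.annual_probability(age)
        return monthly_background_mortality_from_annual(q)


def monthly_background_mortality_from_annual(annual_q: float) -> float:
    """Constant-hazard-within-year conversion q_m = 1 - (1 - q)^(1/12)."""
    if not 0.0 <= annual_q <= 1.0:
        raise DomainError(f"annual probability {annual_q} outside [0, 1]")
    return 1.0 - (1.0 - annual_q) ** (1.0 / 12.0)


def monthly_background_mortality(life_table: LifeTable, age: float) -> float:
    """Monthly background (all-cause) death probability at a given age."""
    return life_table.monthly_probability(age)


# ---------------------------------------------------------------------------
# config I/O


def _entry_from_mapping(name: str, raw: Mapping) -> ParamEntry:
    try:
        return ParamEntry(
            name=name,
            base=float(raw["base"]),
            low=float(raw.get("low", raw["base"])),
            high=float(raw.get("high", raw["base"])),
            psa_distribution=str(raw.get("distribution", "fixed")),
            kind=str(raw.get("kind", "cost")),
        )
    except KeyError as exc:
        raise ConfigurationError(f"entry {name!r}: missing field {exc}") from None
    except (TypeError, ValueError) as exc:
        raise ConfigurationError(f"entry {name!r}: {exc}") from None


def load_parameters(config: str | dict | None = None) -> ParameterSet:
    """Parse a YAML/JSON parameter configuration into a ParameterSet.

    ``config`` may be YAML text, a pre-parsed mapping, a path to a file, or
    ``None`` for the bundled default configuration. Missing optional entries
    take the bundled defaults; structural keys default to the base case.
    """
    defaults = _default_config_dict()
    if config is None:
        raw = defaults
    else:
        if isinstance(config, dict):
            user = copy.deepcopy(config)
        else:
            text = config
            if "\n" not in str(config) and str(config).endswith((".yaml", ".yml", ".json")):
                with open(config, "r", encoding="utf-8") as fh:
                    text = fh.read()
            user = yaml.safe_load(io.StringIO(str(text)))
        if not isinstance(user, dict):
            raise ConfigurationError("top-level config must be a mapping")
        raw = _merge(defaults, user)

    entries = {}
    for name, raw_entry in raw.get("entries", {}).items():
        if not isinstance(raw_entry, Mapping):
            raise ConfigurationError(f"entry {name!r}: must be a mapping")
        entries[name] = _entry_from_mapping(name, raw_entry)

    surv = {}
    for arm in ARMS:
        arm_raw = raw.get("survival", {}).get(arm)
        if arm_raw is None:
            raise ConfigurationError(f"survival: missing arm {arm!r}")
        surv[arm] = {}
        for ep in ENDPOINTS:
            ep_raw = arm_raw.get(ep)
            if ep_raw is None:
                raise ConfigurationError(f"survival.{arm}: missing endpoint {ep!r}")
            surv[arm][ep] = SurvivalParams(
                distribution=str(ep_raw.get("distribution", "lognormal")),
                mu=float(ep_raw["mu"]),
                sigma=float(ep_raw["sigma"]),
                time_unit=str(ep_raw.get("time_unit", "model-fit")),
            )

    anchors = {}
    for arm in ARMS:
        anchors[arm] = {}
        for ep in ENDPOINTS:
            pairs = raw.get("anchors", {}).get(arm, {}).get(ep, [])
            anchors[arm][ep] = tuple((float(t), float(s)) for t, s in pairs)

    model = raw.get("model", {})
    options = raw.get("options", {})
    try:
        opts = ModelOptions(**options)
    except TypeError as exc:
        raise ConfigurationError(f"options: {exc}") from None

    return ParameterSet(
        entries=entries,
        survival_params=surv,
        anchors=anchors,
        wtp_threshold=float(model.get("wtp_threshold", 28130.0)),
        horizon=int(model.get("horizon_cycles", 360)),
        cycles_per_year=int(model.get("cycles_per_year", 12)),
        start_age=float(model.get("start_age", 45.0)),
        retirement_age=float(model.get("retirement_age", 55.0)),
        treatment_cycles=int(model.get("treatment_cycles", 12)),
        options=opts,
    ).validate()


def serialize(params: ParameterSet) -> str:
    """YAML round-trip serialization (load_parameters(serialize(p)) == p)."""
    doc = {
        "entries": {
            n: {
                "base": e.base,
                "low": e.low,
                "high": e.high,
                "distribution": e.psa_distribution,
                "kind": e.kind,
            }
            for n, e in params.entries.items()
        },
        "survival": {
            arm: {
                ep: {
                    "distribution": sp.distribution,
                    "mu": sp.mu,
                    "sigma": sp.sigma,
                    "time_unit": sp.time_unit,
                }
                for ep, sp in params.survival_params[arm].items()
            }
            for arm in ARMS
        },
        "anchors": {
            arm: {ep: [list(p) for p in params.anchors[arm][ep]] for ep in ENDPOINTS}
            for arm in ARMS
        },
        "model": {
            "wtp_threshold": params.wtp_threshold,
            "horizon_cycles": params.horizon,
            "cycles_per_year": params.cycles_per_year,
            "start_age": params.start_age,
            "retirement_age": params.retirement_age,
            "treatment_cycles": params.treatment_cycles,
        },
        "options": {
            "relapse_death_mode": params.options.relapse_death_mode,
            "survival_input_mode": params.options.survival_input_mode,
            "followup_during_treatment": params.options.followup_during_treatment,
            "half_cycle_correction": params.options.half_cycle_correction,
            "relapse_cost_mode": params.options.relapse_cost_mode,
        },
    }
    return yaml.safe_dump(doc, sort_keys=True)


def _merge(base: dict, override: dict) -> dict:
    out = copy.deepcopy(base)
    for key, value in override.items():
        if isinstance(value, dict) and isinstance(out.get(key), dict):
            out[key] = _merge(out[key], value)
        else:
            out[key] = copy.deepcopy(value)
    return out


def _default_config_dict() -> dict:
    with resources.files("capecea.data").joinpath("default_params.yaml").open(
        "r", encoding="utf-8"
    ) as fh:
        return yaml.safe_load(fh)


def default_parameters() -> ParameterSet:
    """The bundled base-case parameterization."""
    return load_parameters(None)


def default_life_table() -> LifeTable:
    """Bundled synthetic approximation of 2020 Chinese female mortality.

    A Gompertz curve anchored to plausible adult female rates; it stands in
    for the national life table and is replaceable via ``LifeTable.from_csv``.
    """
    with resources.files("capecea.data").joinpath(
        "life_table_cn_female_2020_synthetic.csv"
    ).open("r", encoding="utf-8") as fh:
        return LifeTable.from_csv(fh)
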