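"""Monthly-cycle three-state cohort engine (DFS / relapse / death).

Transition construction per cycle t (months since model start, cohort age
45 + t/12):

* DFS -> death: the age-specific background mortality q_m from the life
  table (constant-hazard annual->monthly conversion);
* DFS -> relapse: the DFS-curve exit probability 1 - S(t+1)/S(t) net of
  background mortality, floored at 0 (DFS events comprise relapse AND
  death, so background deaths are removed from the relapse inflow);
* relapse -> death: two switchable conventions. ``os_formula`` (default)
  applies the same exit formula to the fitted OS curve, floored at q_m.
  ``os_matching`` decomposes the fitted OS decrement OS(t) - OS(t+1) into
  background deaths from DFS and relapse deaths, so the modeled OS tracks
  the fitted OS trajectory while the relapse pool lasts;
* death is absorbing.

All probabilities are clipped to [0, 1]; clip events are counted in the
trace diagnostics rather than raised.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

from .errors import DomainError, ValidationError
from .parameters import LifeTable, ParameterSet, SurvivalParams
from .survival_models import SurvivalFit, engine_survival_inputs, survival_at

_CONSERVATION_TOL = 1e-12


@dataclass(frozen=True)
class StateVector:
    dfs: float
    relapse: float
    dead: float

    def __post_init__(self) -> None:
        if min(self.dfs, self.relapse, self.dead) < -_CONSERVATION_TOL:
            raise ValidationError("state fractions must be non-negative")
        if abs(self.dfs + self.relapse + self.dead - 1.0) > 1e-9:
            raise ValidationError("state fractions must sum to 1")

    def as_array(self) -> np.ndarray:
        return np.array([self.dfs, self.relapse, self.dead])


@dataclass(frozen=True)
class CohortTrace:
    """Per-cycle occupancy and transition diagnostics for one arm."""

    arm: str
    dfs: np.ndarray        # length horizon + 1
    relapse: np.ndarray
    dead: np.ndarray
    ages: np.ndarray
    p_dfs_relapse: np.ndarray   # length horizon
    p_dfs_death: np.ndarray
    p_relapse_death: np.ndarray
    n_clipped: int = 0

    @property
    def horizon(self) -> int:
        return len(self.dfs) - 1

    def state(self, cycle: int) -> StateVector:
        return StateVector(
            float(self.dfs[cycle]), float(self.relapse[cycle]), float(self.dead[cycle])
        )

    def to_frame(self):
        import pandas as pd

        h = self.horizon
        return pd.DataFrame(
            {
                "cycle": np.arange(h + 1),
                "age": self.ages,
                "dfs": self.dfs,
                "relapse": self.relapse,
                "dead": self.dead,
                "p_dfs_relapse": np.append(self.p_dfs_relapse, np.nan),
                "p_dfs_death": np.append(self.p_dfs_death, np.nan),
                "p_relapse_death": np.append(self.p_relapse_death, np.nan),
            }
        )


# ---------------------------------------------------------------------------
# probability construction


def exit_probability(fit, t: float) -> float:
    """Per-cycle exit probability 1 - S(t+1)/S(t), clipped to [0, 1].

    By convention an exhausted state (S(t) = 0) exits with probability 1.
    """
    s_t = survival_at(fit, t)
    if s_t <= 0.0:
        return 1.0
    s_next = survival_at(fit, t + 1.0)
    return float(np.clip(1.0 - s_next / s_t, 0.0, 1.0))


def survival_curve(fit, horizon: int) -> np.ndarray:
    """S evaluated on the cycle grid 0..horizon."""
    return np.asarray(survival_at(fit, np.arange(horizon + 1, dtype=float)))


def _exit_array(surv: np.ndarray) -> np.ndarray:
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(surv[:-1] > 0.0, surv[1:] / np.maximum(surv[:-1], 1e-300), 0.0)
    return np.clip(1.0 - ratio, 0.0, 1.0)


def background_mortality_curve(
    params: ParameterSet, life_table: LifeTable
) -> np.ndarray:
    """Monthly background death probability at each cycle's cohort age."""
    ages = params.start_age + np.arange(params.horizon) / params.cycles_per_year
    return np.array([life_table.monthly_probability(a) for a in ages])


def build_transitions(
    arm: str,
    cycle: int,
    cohort_age: float,
    params: ParameterSet,
    dfs_fit,
    os_fit,
    life_table: LifeTable,
    state: StateVector | None = None,
) -> np.ndarray:
    """Row-stochastic 3x3 matrix (rows/cols: DFS, relapse, death) at one cycle.

    ``state`` is only needed by the os_matching relapse-death rule; without it
    the relapse pool is treated as empty (relapse->death falls back to q_m).
    """
    q = life_table.monthly_probability(cohort_age)
    p_exit = exit_probability(dfs_fit, float(cycle))
    mult_dfs = params.transition_multipliers.get((arm, "dfs"), 1.0)
    mult_os = params.transition_multipliers.get((arm, "os"), 1.0)
    p_exit = float(np.clip(mult_dfs * p_exit, 0.0, 1.0))
    p_dr = float(np.clip(p_exit - q, 0.0, 1.0 - q))

    if params.options.relapse_death_mode == "os_matching" and state is not None and state.relapse > 1e-12:
        s_t = survival_at(os_fit, float(cycle))
        s_next = survival_at(os_fit, float(cycle) + 1.0)
        d_os = mult_os * (s_t - s_next)
        p_rd = float(np.clip((d_os - q * state.dfs) / state.relapse, q, 1.0))
    else:
        p_exit_os = float(np.clip(mult_os * exit_probability(os_fit, float(cycle)), 0.0, 1.0))
        p_rd = max(p_exit_os, q) if params.options.relapse_death_mode == "os_formula" else q

    mat = np.array(
        [
            [1.0 - p_dr - q, p_dr, q],
            [0.0, 1.0 - p_rd, p_rd],
            [0.0, 0.0, 1.0],
        ]
    )
    if np.any(mat < -1e-15):
        raise ValidationError("transition probabilities escaped [0, 1]")
    return mat


# ---------------------------------------------------------------------------
# cohort iteration


def _iterate(
    exd: np.ndarray,
    os_surv: np.ndarray,
    qm: np.ndarray,
    mode: str,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray, int]:
    """Shared cohort recursion; returns occupancies, relapse-death probs, clip count."""
    h = len(exd)
    dfs = np.zeros(h + 1)
    rel = np.zeros(h + 1)
    dead = np.zeros(h + 1)
    prd_out = np.zeros(h)
    dfs[0] = 1.0
    clipped = 0
    exo = _exit_array(os_surv)
    d_os = os_surv[:-1] - os_surv[1:]
    for t in range(h):
        q = qm[t]
        pdr = min(max(exd[t] - q, 0.0), 1.0 - q)
        if mode == "os_matching":
            if rel[t] > 1e-12:
                raw = (d_os[t] - q * dfs[t]) / rel[t]
                prd = min(max(raw, q), 1.0)
                if raw < q - 1e-15 or raw > 1.0 + 1e-15:
                    clipped += 1
            else:
                prd = q
        else:
            prd = max(exo[t], q)
        prd_out[t] = prd
        dfs[t + 1] = dfs[t] * (1.0 - pdr - q)
        rel[t + 1] = rel[t] * (1.0 - prd) + dfs[t] * pdr
        dead[t + 1] = dead[t] + dfs[t] * q + rel[t] * prd
    return dfs, rel, dead, prd_out, clipped


def run_cohort(
    arm: str,
    params: ParameterSet,
    life_table: LifeTable,
    dfs_fit=None,
    os_fit=None,
) -> CohortTrace:
    """Run the cohort for one arm over the configured horizon.

    Fits default to the configured survival inputs (anchor-calibrated unless
    ``survival_input_mode`` says otherwise); the arm's transition multipliers
    scale the monthly exit probabilities of each curve (PSA perturbation).
    """
    if params.horizon < 0:
        raise DomainError("horizon must be >= 0")
    if dfs_fit is None or os_fit is None:
        inputs = engine_survival_inputs(params)[arm]
        dfs_fit = dfs_fit or inputs["dfs"]
        os_fit = os_fit or inputs["os"]

    h = params.horizon
    qm = background_mortality_curve(params, life_table)
    exd = _exit_array(survival_curve(dfs_fit, h))
    exd = np.clip(params.transition_multipliers.get((arm, "dfs"), 1.0) * exd, 0.0, 1.0)
    exo_base = _exit_array(survival_curve(os_fit, h))
    exo = np.clip(params.transition_multipliers.get((arm, "os"), 1.0) * exo_base, 0.0, 1.0)
    # reconstruct the (possibly perturbed) OS trajectory from its exit probs
    os_surv = np.concatenate([[1.0], np.cumprod(1.0 - exo)])

    dfs, rel, dead, prd, clipped = _iterate(
        exd, os_surv, qm, params.options.relapse_death_mode
    )

    total = dfs + rel + dead
    if np.max(np.abs(total - 1.0)) > _CONSERVATION_TOL * max(1, h):
        raise ValidationError("cohort trace lost probability mass")
    # enforce exact conservation in the stored trace
    dead = 1.0 - dfs - rel

    pdr = np.clip(exd - qm, 0.0, 1.0 - qm)
    return CohortTrace(
        arm=arm,
        dfs=dfs,
        relapse=rel,
        dead=dead,
        ages=params.start_age + np.arange(h + 1) / params.cycles_per_year,
        p_dfs_relapse=pdr,
        p_dfs_death=qm.copy(),
        p_relapse_death=prd,
        n_clipped=clipped,
    )


def modeled_survival(trace: CohortTrace, endpoint: str) -> np.ndarray:
    """Model-implied survival on the cycle grid: OS = 1 - dead, DFS = dfs."""
    endpoint = endpoint.lower()
    if endpoint == "os":
        return 1.0 - trace.dead
    if endpoint == "dfs":
        return trace.dfs.copy()
    raise DomainError(f"unknown endpoint {endpoint!r}")
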