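"""Cost and QALY accounting over a cohort trace, and incremental results.

Accrual conventions (base case): costs and utilities attach to the state
occupancy at cycle start (no half-cycle correction unless enabled); drug and
safety monitoring are charged on DFS occupancy during the 12 treatment
cycles of the capecitabine arm, with routine follow-up charged concurrently;
time costs stop once the cohort reaches the retirement age; the expected
adverse-event cost and disutility are incurred once in the first cycle of
the capecitabine arm; relapse treatment is charged per month of relapse
occupancy. Band boundaries (months): follow-up [0,36)/[36,60)/[60,...),
time and travel [0,12)/[12,36)/[36,60)/[60,...).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np

from .errors import DomainError, ValidationError
from .markov_engine import CohortTrace, StateVector
from .parameters import ParameterSet, discount_factor

COST_CATEGORIES = (
    "drug",
    "monitoring",
    "followup",
    "time",
    "travel",
    "adverse_events",
    "relapse_treatment",
)

_BREAKDOWN_RTOL = 1e-6


@dataclass(frozen=True)
class ArmResult:
    arm: str
    total_cost: float
    total_qaly: float
    breakdown: Mapping[str, float]
    total_cost_undiscounted: float
    total_qaly_undiscounted: float
    breakdown_undiscounted: Mapping[str, float]

    def __post_init__(self) -> None:
        for label, total, bd in (
            ("discounted", self.total_cost, self.breakdown),
            ("undiscounted", self.total_cost_undiscounted, self.breakdown_undiscounted),
        ):
            s = sum(bd.values())
            if abs(s - total) > _BREAKDOWN_RTOL * max(1.0, abs(total)):
                raise ValidationError(
                    f"{label} breakdown ({s}) does not reproduce the total ({total})"
                )
            if any(v < -1e-12 for v in bd.values()):
                raise ValidationError("cost components must be non-negative")


@dataclass(frozen=True)
class CEResult:
    delta_cost: float
    delta_qaly: float
    icer: float | None
    flag: str  # "" | "dominant" | "dominated" | "undefined"
    nmb_at_wtp: float
    wtp: float

    @property
    def cost_effective(self) -> bool:
        if self.flag == "dominant":
            return True
        if self.flag == "dominated":
            return False
        return self.icer is not None and self.icer < self.wtp


# ---------------------------------------------------------------------------
# per-cycle schedules


def _band_value(cycle: int, edges: tuple[int, ...], values: tuple[float, ...]) -> float:
    for edge, value in zip(edges, values):
        if cycle < edge:
            return value
    return values[-1]


def followup_cost(params: ParameterSet, cycle: int) -> float:
    return _band_value(
        cycle,
        (36, 60),
        (
            params.value("cost_followup_lt3y"),
            params.value("cost_followup_3to5y"),
            params.value("cost_followup_gt5y"),
        ),
    )


def time_cost(params: ParameterSet, arm: str, cycle: int) -> float:
    age = params.start_age + cycle / params.cycles_per_year
    if age >= params.retirement_age:
        return 0.0
    first_year = params.value(f"cost_time_y1_{arm}")
    return _band_value(
        cycle,
        (12, 36, 60),
        (
            first_year,
            params.value("cost_time_1to2y"),
            params.value("cost_time_3to5y"),
            params.value("cost_time_gt5y"),
        ),
    )


def travel_cost(params: ParameterSet, arm: str, cycle: int) -> float:
    return _band_value(
        cycle,
        (12, 36, 60),
        (
            params.value(f"cost_travel_y1_{arm}"),
            params.value("cost_travel_1to2y"),
            params.value("cost_travel_3to5y"),
            params.value("cost_travel_gt5y"),
        ),
    )


def expected_ae_cost(params: ParameterSet) -> float:
    return params.value("incidence_hand_foot") * params.value("cost_ae_hand_foot") + params.value(
        "incidence_diarrhea"
    ) * params.value("cost_ae_diarrhea")


def expected_ae_disutility(params: ParameterSet) -> float:
    return params.value("incidence_hand_foot") * params.value(
        "disutility_hand_foot"
    ) + params.value("incidence_diarrhea") * params.value("disutility_diarrhea")


def _cycle_cost_components(
    arm: str, cycle: int, state: StateVector, params: ParameterSet, relapse_inflow: float = 0.0
) -> dict[str, float]:
    on_treatment = arm == "capecitabine" and cycle < params.treatment_cycles
    comp = dict.fromkeys(COST_CATEGORIES, 0.0)
    comp["drug"] = state.dfs * params.value("cost_capecitabine_month") if on_treatment else 0.0
    comp["monitoring"] = (
        state.dfs * params.value("cost_monitoring_month") if on_treatment else 0.0
    )
    charge_fu = not on_treatment or params.options.followup_during_treatment
    comp["followup"] = state.dfs * followup_cost(params, cycle) if charge_fu else 0.0
    comp["time"] = state.dfs * time_cost(params, arm, cycle)
    comp["travel"] = state.dfs * travel_cost(params, arm, cycle)
    if arm == "capecitabine" and cycle == 0:
        comp["adverse_events"] = expected_ae_cost(params)
    if params.options.relapse_cost_mode == "per_case":
        comp["relapse_treatment"] = relapse_inflow * params.value("cost_relapse_month")
    else:
        comp["relapse_treatment"] = state.relapse * params.value("cost_relapse_month")
    return comp


def cycle_cost(
    arm: str, cycle: int, state: StateVector, params: ParameterSet, relapse_inflow: float = 0.0
) -> float:
    """Undiscounted cost accrued during one cycle, weighted by occupancy."""
    if cycle < 0:
        raise DomainError("cycle must be >= 0")
    return sum(_cycle_cost_components(arm, cycle, state, params, relapse_inflow).values())


def cycle_qaly(cycle: int, state: StateVector, params: ParameterSet, arm: str) -> float:
    """Undiscounted QALYs accrued during one cycle (utility-weighted months/12)."""
    if cycle < 0:
        raise DomainError("cycle must be >= 0")
    q = (
        state.dfs * params.value("utility_dfs")
        + state.relapse * params.value("utility_relapse")
    ) / params.cycles_per_year
    if arm == "capecitabine" and cycle == 0:
        q -= expected_ae_disutility(params) / params.cycles_per_year
    return q


# ---------------------------------------------------------------------------
# accumulation


def accumulate(trace: CohortTrace, params: ParameterSet) -> ArmResult:
    """Discount and sum per-cycle costs and QALYs over the trace (vectorized).

    Agrees with summing :func:`cycle_cost` / :func:`cycle_qaly` cycle by
    cycle; the vectorized path exists so the 10,000-iteration PSA stays fast.
    """
    h = trace.horizon
    arm = trace.arm
    cycles = np.arange(h)
    if params.options.half_cycle_correction:
        dfs = 0.5 * (trace.dfs[:-1] + trace.dfs[1:])
        rel = 0.5 * (trace.relapse[:-1] + trace.relapse[1:])
    else:
        dfs = trace.dfs[:-1]
        rel = trace.relapse[:-1]
    disc = discount_factor(params.annual_discount_rate, cycles, params.cycles_per_year) if h else np.zeros(0)

    fu = np.array([followup_cost(params, int(t)) for t in cycles])
    tm = np.array([time_cost(params, arm, int(t)) for t in cycles])
    tv = np.array([travel_cost(params, arm, int(t)) for t in cycles])

    comp = {}
    on_rx = np.zeros(h, dtype=bool)
    if arm == "capecitabine":
        on_rx[: params.treatment_cycles] = True
    comp["drug"] = dfs * params.value("cost_capecitabine_month") * on_rx
    comp["monitoring"] = dfs * params.value("cost_monitoring_month") * on_rx
    fu_mask = np.ones(h) if params.options.followup_during_treatment else (~on_rx).astype(float)
    comp["followup"] = dfs * fu * fu_mask
    comp["time"] = dfs * tm
    comp["travel"] = dfs * tv
    ae = np.zeros(h)
    if arm == "capecitabine" and h > 0:
        ae[0] = expected_ae_cost(params)
    comp["adverse_events"] = ae
    if params.options.relapse_cost_mode == "per_case":
        inflow = trace.dfs[:-1] * trace.p_dfs_relapse
        comp["relapse_treatment"] = inflow * params.value("cost_relapse_month")
    else:
        comp["relapse_treatment"] = rel * params.value("cost_relapse_month")

    qal = (
        dfs * params.value("utility_dfs") + rel * params.value("utility_relapse")
    ) / params.cycles_per_year
    if arm == "capecitabine" and h > 0:
        qal[0] -= expected_ae_disutility(params) / params.cycles_per_year

    breakdown = {k: float(np.sum(v * disc)) for k, v in comp.items()}
    breakdown_undisc = {k: float(np.sum(v)) for k, v in comp.items()}
    return ArmResult(
        arm=arm,
        total_cost=sum(breakdown.values()),
        total_qaly=float(np.sum(qal * disc)),
        breakdown=breakdown,
        total_cost_undiscounted=sum(breakdown_undisc.values()),
        total_qaly_undiscounted=float(np.sum(qal)),
        breakdown_undiscounted=breakdown_undisc,
    )


def compare(arm_a: ArmResult, arm_b: ArmResult, wtp: float) -> CEResult:
    """Incremental result a - b: ICER, dominance flags and NMB at the WTP."""
    dc = arm_a.total_cost - arm_b.total_cost
    dq = arm_a.total_qaly - arm_b.total_qaly
    nmb = wtp * dq - dc
    if dq == 0.0:
        return CEResult(dc, dq, None, "undefined", nmb, wtp)
    if dq > 0.0 and dc < 0.0:
        return CEResult(dc, dq, dc / dq, "dominant", nmb, wtp)
    if dq < 0.0 and dc > 0.0:
        return CEResult(dc, dq, dc / dq, "dominated", nmb, wtp)
    return CEResult(dc, dq, dc / dq, "", nmb, wtp)
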