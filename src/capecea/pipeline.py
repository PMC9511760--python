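"""Base-case orchestration: run both arms and compare them."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

from .economics import ArmResult, CEResult, accumulate, compare
from .markov_engine import CohortTrace, run_cohort
from .parameters import ARMS, LifeTable, ParameterSet, default_life_table, default_parameters


@dataclass(frozen=True)
class BaseCaseResult:
    traces: Mapping[str, CohortTrace]
    arm_results: Mapping[str, ArmResult]
    ce: CEResult


def base_case(
    params: ParameterSet | None = None, life_table: LifeTable | None = None
) -> BaseCaseResult:
    """Calibrate survival inputs, run both arms, accumulate and compare."""
    params = params or default_parameters()
    life_table = life_table or default_life_table()
    traces = {arm: run_cohort(arm, params, life_table) for arm in ARMS}
    results = {arm: accumulate(traces[arm], params) for arm in ARMS}
    ce = compare(results["capecitabine"], results["observation"], params.wtp_threshold)
    return BaseCaseResult(traces=traces, arm_results=results, ce=ce)


def icer_for(params: ParameterSet, life_table: LifeTable) -> CEResult:
    return base_case(params, life_table).ce
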