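"""Cost/QALY accrual, discounting, incremental comparison."""

import dataclasses

import numpy as np
import pytest

from capecea import StateVector, accumulate, base_case, compare, cycle_cost, cycle_qaly
from capecea.economics import ArmResult
from capecea.errors import ValidationError
from capecea.markov_engine import run_cohort
from capecea.parameters import discount_factor

FULL_DFS = StateVector(1.0, 0.0, 0.0)
ALL_DEAD = StateVector(0.0, 0.0, 1.0)


class TestCycleAccrual:
    def test_capecitabine_first_cycle_cost(self, params):
        # drug + monitoring + follow-up + time + travel + expected AE cost
        expected = 306.48 + 46.83 + 38.39 + 49.97 + 12.37 + (
            0.1345 * 15.46 + 0.0319 * 44.30
        )
        assert cycle_cost("capecitabine", 0, FULL_DFS, params) == pytest.approx(
            expected, abs=1e-9
        )
        assert expected == pytest.approx(457.53, abs=0.01)

    def test_observation_first_cycle_cost(self, params):
        assert cycle_cost("observation", 0, FULL_DFS, params) == pytest.approx(
            38.39 + 16.66 + 4.12, abs=1e-9
        )

    def test_dead_cohort_accrues_nothing(self, params):
        assert cycle_cost("observation", 5, ALL_DEAD, params) == 0.0
        assert cycle_qaly(5, ALL_DEAD, params, "observation") == 0.0

    def test_time_cost_stops_at_retirement_age(self, params):
        before = cycle_cost("observation", 119, FULL_DFS, params)
        after = cycle_cost("observation", 120, FULL_DFS, params)
        assert before - after == pytest.approx(params.value("cost_time_gt5y"))

    def test_followup_band_boundaries(self, params):
        # follow-up, time and travel all step down at month 36
        c35 = cycle_cost("observation", 35, FULL_DFS, params)
        c36 = cycle_cost("observation", 36, FULL_DFS, params)
        assert c35 - c36 == pytest.approx(
            (38.39 - 21.32) + (16.66 - 8.33) + (4.12 - 2.06)
        )

    def test_full_dfs_qaly(self, params):
        assert cycle_qaly(3, FULL_DFS, params, "observation") == pytest.approx(0.8 / 12)

    def test_first_cycle_ae_disutility(self, params):
        q_obs = cycle_qaly(0, FULL_DFS, params, "observation")
        q_cape = cycle_qaly(0, FULL_DFS, params, "capecitabine")
        assert q_obs - q_cape == pytest.approx(
            (0.1345 * 0.12 + 0.0319 * 0.10) / 12, abs=1e-12
        )
        assert q_obs - q_cape == pytest.approx(0.001611, abs=1e-6)

    def test_relapse_state_cost_and_utility(self, params):
        st = StateVector(0.0, 1.0, 0.0)
        assert cycle_cost("observation", 40, st, params) == pytest.approx(1546.43)
        assert cycle_qaly(40, st, params, "observation") == pytest.approx(0.73 / 12)


class TestAccumulate:
    def test_zero_horizon_gives_zeros(self, params, life_table):
        ps = dataclasses.replace(params, horizon=0)
        res = accumulate(run_cohort("capecitabine", ps, life_table), ps)
        assert res.total_cost == 0.0 and res.total_qaly == 0.0

    def test_vectorized_accumulation_matches_cycle_functions(
        self, short_params, life_table
    ):
        for arm in ("capecitabine", "observation"):
            tr = run_cohort(arm, short_params, life_table)
            res = accumulate(tr, short_params)
            rate = short_params.annual_discount_rate
            cost = qaly = 0.0
            for t in range(short_params.horizon):
                d = discount_factor(rate, t)
                cost += d * cycle_cost(arm, t, tr.state(t), short_params)
                qaly += d * cycle_qaly(t, tr.state(t), short_params, arm)
            assert res.total_cost == pytest.approx(cost, rel=1e-10)
            assert res.total_qaly == pytest.approx(qaly, rel=1e-10)

    def test_discounting_reduces_totals(self, base_result):
        for res in base_result.arm_results.values():
            assert res.total_cost < res.total_cost_undiscounted
            assert res.total_qaly < res.total_qaly_undiscounted

    def test_breakdown_conserves_total(self, base_result):
        for res in base_result.arm_results.values():
            assert sum(res.breakdown.values()) == pytest.approx(
                res.total_cost, rel=1e-9
            )
            assert all(v >= 0 for v in res.breakdown.values())

    def test_qaly_bounded_by_utility_weighted_life_expectancy(
        self, base_result, params
    ):
        for arm, res in base_result.arm_results.items():
            tr = base_result.traces[arm]
            disc = discount_factor(
                params.annual_discount_rate, np.arange(params.horizon)
            )
            life = float(np.sum(disc * (tr.dfs[:-1] + tr.relapse[:-1])) / 12)
            assert res.total_qaly <= 0.8 * life + 1e-9

    def test_inconsistent_breakdown_rejected(self):
        with pytest.raises(ValidationError):
            ArmResult(
                arm="observation",
                total_cost=100.0,
                total_qaly=1.0,
                breakdown={"followup": 50.0},
                total_cost_undiscounted=100.0,
                total_qaly_undiscounted=1.0,
                breakdown_undiscounted={"followup": 100.0},
            )


class TestCompare:
    def _result(self, cost, qaly):
        return ArmResult(
            "x", cost, qaly, {"followup": cost}, cost, qaly, {"followup": cost}
        )

    def test_identical_arms_undefined_icer(self):
        ce = compare(self._result(10.0, 1.0), self._result(10.0, 1.0), wtp=100.0)
        assert ce.delta_cost == 0.0 and ce.delta_qaly == 0.0
        assert ce.icer is None and ce.flag == "undefined"

    def test_dominant_and_dominated_flags(self):
        better_cheaper = compare(self._result(5.0, 2.0), self._result(10.0, 1.0), 100.0)
        assert better_cheaper.flag == "dominant" and better_cheaper.cost_effective
        worse_dearer = compare(self._result(10.0, 1.0), self._result(5.0, 2.0), 100.0)
        assert worse_dearer.flag == "dominated" and not worse_dearer.cost_effective

    def test_icer_identity_and_nmb(self, base_result):
        ce = base_result.ce
        assert ce.icer * ce.delta_qaly == pytest.approx(ce.delta_cost, rel=1e-12)
        assert ce.nmb_at_wtp == pytest.approx(
            ce.wtp * ce.delta_qaly - ce.delta_cost, rel=1e-12
        )

    def test_raising_drug_cost_raises_icer(self, params, life_table):
        low = base_case(params.with_value("cost_capecitabine_month", 100.0), life_table)
        high = base_case(params.with_value("cost_capecitabine_month", 306.48), life_table)
        assert high.ce.icer > low.ce.icer


class TestConventionSwitches:
    def test_followup_concurrency_flag_lowers_treatment_year_cost(
        self, params, life_table
    ):
        off = params.with_options(followup_during_treatment=False)
        cost_on = base_case(params, life_table).arm_results["capecitabine"].total_cost
        cost_off = base_case(off, life_table).arm_results["capecitabine"].total_cost
        assert cost_on > cost_off
        # observation arm is never on treatment, so it is unaffected
        assert base_case(off, life_table).arm_results["observation"].total_cost == (
            pytest.approx(
                base_case(params, life_table).arm_results["observation"].total_cost
            )
        )

    def test_per_case_relapse_costing_is_cheaper(self, params, life_table):
        per_case = params.with_options(relapse_cost_mode="per_case")
        for arm in ("capecitabine", "observation"):
            occ = base_case(params, life_table).arm_results[arm]
            one = base_case(per_case, life_table).arm_results[arm]
            assert one.breakdown["relapse_treatment"] < occ.breakdown["relapse_treatment"]

    def test_half_cycle_correction_changes_totals_slightly(self, params, life_table):
        hcc = params.with_options(half_cycle_correction=True)
        a = base_case(params, life_table).arm_results["observation"]
        b = base_case(hcc, life_table).arm_results["observation"]
        assert a.total_qaly != b.total_qaly
        assert abs(a.total_qaly - b.total_qaly) / a.total_qaly < 0.02
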