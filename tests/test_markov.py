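import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from hipce.markov import (
    Comparison,
    ModelInputs,
    StrategyCosts,
    StrategyResult,
    Utilities,
    compare_strategies,
    discount_factor,
    run_cohort,
)
from hipce.registry import LifeTable
from hipce.survival import AnnualRevisionSchedule

from oracles import enumerate_cohort


def flat_life_table(qx: float, sexes=("male", "female")) -> LifeTable:
    rows = [(s, a, qx) for s in sexes for a in range(30, 101)]
    return LifeTable(pd.DataFrame(rows, columns=["sex", "age", "qx"]))


def life_table_from_list(qx_by_cycle, start_age: int) -> LifeTable:
    rows = []
    for a in range(30, 101):
        idx = a - start_age
        qx = qx_by_cycle[idx] if 0 <= idx < len(qx_by_cycle) else 0.0
        rows.append(("male", a, qx))
    return LifeTable(pd.DataFrame(rows, columns=["sex", "age", "qx"]))


def make_inputs(
    schedule,
    qx=0.0,
    m=0.0,
    r=0.0,
    u_succ=0.8,
    u_rev=0.5,
    costs=None,
    rate=0.035,
    life_table=None,
):
    return ModelInputs(
        surgical_mortality=m,
        rerevision_prob=r,
        revision_schedule=schedule,
        life_table=life_table if life_table is not None else flat_life_table(qx),
        utilities=Utilities.constant(u_succ, u_rev),
        costs=costs
        or StrategyCosts(
            prosthesis=2808,
            surgery=1738,
            inpatient=1628,
            followup_primary=509,
            revision_surgery=16794,
            followup_postrevision=400,
        ),
        discount_rate=rate,
    )


class TestDiscountFactor:
    def test_cycle_zero_is_one(self):
        assert discount_factor(0, 0.035) == 1.0
        assert discount_factor(0, 0.9) == 1.0

    def test_closed_form(self):
        assert discount_factor(2, 0.035) == pytest.approx(1 / 1.035**2, abs=1e-12)

    def test_zero_rate(self):
        assert all(discount_factor(t, 0.0) == 1.0 for t in range(10))

    def test_invalid_args(self):
        with pytest.raises(ValueError):
            discount_factor(-1, 0.035)
        with pytest.raises(ValueError):
            discount_factor(1, -0.01)


class TestRunCohort:
    def test_annuity_closed_form(self):
        u = 0.8
        inputs = make_inputs(AnnualRevisionSchedule.zero(10), u_succ=u)
        res = run_cohort(inputs, 50, "male", "10y")
        expected_qalys = u * sum(1 / 1.035**t for t in range(10))
        assert res.total_qalys == pytest.approx(expected_qalys, abs=1e-10)
        expected_cost = inputs.costs.primary_procedure + 509 * sum(
            1 / 1.035**t for t in range(10)
        )
        assert res.total_cost == pytest.approx(expected_cost, abs=1e-9)

    def test_three_cycle_trace_matches_path_enumeration(self):
        m, r, rate = 0.02, 0.08, 0.035
        p = [0.15, 0.25]
        qx = [0.0, 0.01, 0.03]
        inputs = make_inputs(
            AnnualRevisionSchedule(np.array(p)),
            m=m,
            r=r,
            rate=rate,
            life_table=life_table_from_list(qx, start_age=50),
        )
        res = run_cohort(inputs, 50, "male", 3)
        oracle = enumerate_cohort(
            m=m, r=r, p=p, qx=qx, u_succ=0.8, u_rev=0.5,
            fu_primary=509, fu_postrev=400,
            c_primary=inputs.costs.primary_procedure, c_revision=16794,
            rate=rate, cycles=3,
        )
        assert res.total_cost == pytest.approx(oracle["cost"], abs=1e-12 * 1e5)
        assert res.total_qalys == pytest.approx(oracle["qaly"], abs=1e-12)
        for t in range(3):
            row = res.trace.iloc[t]
            assert row["successful_primary"] == pytest.approx(
                oracle["occupancy"][t]["SP"], abs=1e-12
            )
            assert row["revision_surgery"] == pytest.approx(
                oracle["occupancy"][t]["RV"], abs=1e-12
            )
            assert row["successful_revision"] == pytest.approx(
                oracle["occupancy"][t]["SR"], abs=1e-12
            )
            assert row["dead"] == pytest.approx(oracle["occupancy"][t]["D"], abs=1e-12)

    def test_four_cycle_oracle_with_rerevision(self):
        m, r, rate = 0.05, 0.3, 0.05
        p = [0.2, 0.1, 0.3]
        qx = [0.0, 0.02, 0.02, 0.05]
        inputs = make_inputs(
            AnnualRevisionSchedule(np.array(p)),
            m=m, r=r, rate=rate, u_succ=0.75, u_rev=0.4,
            life_table=life_table_from_list(qx, start_age=60),
        )
        res = run_cohort(inputs, 60, "male", 4)
        oracle = enumerate_cohort(
            m=m, r=r, p=p, qx=qx, u_succ=0.75, u_rev=0.4,
            fu_primary=509, fu_postrev=400,
            c_primary=inputs.costs.primary_procedure, c_revision=16794,
            rate=rate, cycles=4,
        )
        assert res.total_cost == pytest.approx(oracle["cost"], rel=1e-12)
        assert res.total_qalys == pytest.approx(oracle["qaly"], rel=1e-12)

    def test_total_surgical_mortality_absorbs_everyone(self):
        inputs = make_inputs(AnnualRevisionSchedule.zero(10), m=1.0)
        res = run_cohort(inputs, 50, "male", "10y")
        assert res.total_qalys == 0.0
        assert res.total_cost == pytest.approx(inputs.costs.primary_procedure)
        assert res.trace["dead"].iloc[0] == 1.0

    def test_occupancy_conservation(self):
        inputs = make_inputs(
            AnnualRevisionSchedule.constant(0.05, 60), qx=0.02, m=0.01, r=0.05
        )
        res = run_cohort(inputs, 40, "male", "lifetime")
        occ = res.trace[
            ["successful_primary", "revision_surgery", "successful_revision", "dead"]
        ].sum(axis=1)
        np.testing.assert_allclose(occ, 1.0, atol=1e-10)

    def test_dead_occupancy_non_decreasing(self):
        inputs = make_inputs(
            AnnualRevisionSchedule.constant(0.05, 60), qx=0.02, m=0.01, r=0.05
        )
        res = run_cohort(inputs, 40, "male", "lifetime")
        assert (res.trace["dead"].diff().dropna() >= -1e-14).all()

    def test_discounted_not_above_undiscounted(self):
        inputs = make_inputs(AnnualRevisionSchedule.constant(0.03, 20), qx=0.01)
        res = run_cohort(inputs, 50, "male", 20)
        assert (res.trace["disc_cost"] <= res.trace["cost"] + 1e-12).all()
        assert (res.trace["disc_qaly"] <= res.trace["qaly"] + 1e-12).all()

    def test_zero_discount_dominates_discounted_totals(self):
        sched = AnnualRevisionSchedule.constant(0.03, 60)
        res0 = run_cohort(make_inputs(sched, qx=0.01, rate=0.0), 40, "male", "lifetime")
        res35 = run_cohort(
            make_inputs(sched, qx=0.01, rate=0.035), 40, "male", "lifetime"
        )
        assert res0.total_cost > res35.total_cost
        assert res0.total_qalys > res35.total_qalys

    def test_higher_revision_rate_costs_more_fewer_qalys(self):
        lo = run_cohort(
            make_inputs(AnnualRevisionSchedule.constant(0.01, 60), qx=0.01, r=0.05),
            50, "male", "lifetime",
        )
        hi = run_cohort(
            make_inputs(AnnualRevisionSchedule.constant(0.10, 60), qx=0.01, r=0.05),
            50, "male", "lifetime",
        )
        assert hi.total_cost > lo.total_cost
        assert hi.total_qalys < lo.total_qalys

    def test_qalys_bounded_by_horizon(self):
        inputs = make_inputs(AnnualRevisionSchedule.zero(10), u_succ=1.0, rate=0.0)
        res = run_cohort(inputs, 50, "male", "10y")
        assert res.total_qalys <= 10.0 + 1e-12

    def test_totals_equal_trace_sums(self):
        inputs = make_inputs(AnnualRevisionSchedule.constant(0.04, 60), qx=0.02)
        res = run_cohort(inputs, 45, "male", "lifetime")
        assert res.total_cost == pytest.approx(res.trace["disc_cost"].sum(), abs=1e-9)
        assert res.total_qalys == pytest.approx(res.trace["disc_qaly"].sum(), abs=1e-9)

    def test_short_schedule_rejected(self):
        inputs = make_inputs(AnnualRevisionSchedule.zero(5))
        with pytest.raises(ValueError, match="schedule"):
            run_cohort(inputs, 50, "male", "10y")

    @given(
        p=st.floats(0.0, 0.5),
        qx=st.floats(0.0, 0.3),
        m=st.floats(0.0, 0.2),
        r=st.floats(0.0, 0.4),
        cycles=st.integers(1, 15),
    )
    @settings(max_examples=40, deadline=None)
    def test_conservation_property(self, p, qx, m, r, cycles):
        inputs = make_inputs(
            AnnualRevisionSchedule.constant(p, max(cycles, 1)), qx=qx, m=m, r=r
        )
        res = run_cohort(inputs, 50, "male", cycles)
        occ = res.trace[
            ["successful_primary", "revision_surgery", "successful_revision", "dead"]
        ].sum(axis=1)
        np.testing.assert_allclose(occ, 1.0, atol=1e-10)


class TestCompareStrategies:
    def test_printed_incremental_cost_age_40_ten_year(self):
        a = StrategyResult.from_totals("BHIP", "10y", 12_211, 7.326)
        b = StrategyResult.from_totals("CeMoP", "10y", 10_348, 7.321)
        comp = compare_strategies(a, b)
        assert comp.delta_cost == pytest.approx(1863)

    def test_dominated_classification(self):
        a = StrategyResult.from_totals("BHIP", "lifetime", 16_421, 12.109)
        b = StrategyResult.from_totals("CeMoP", "lifetime", 13_130, 12.110)
        comp = compare_strategies(a, b)
        assert comp.delta_cost == pytest.approx(3291)
        assert comp.label == "dominated"
        assert comp.icer is None

    def test_identical_results_undefined_icer(self):
        a = StrategyResult.from_totals("A", "10y", 1000.0, 5.0)
        b = StrategyResult.from_totals("B", "10y", 1000.0, 5.0)
        comp = compare_strategies(a, b)
        assert comp.delta_cost == 0.0 and comp.delta_qalys == 0.0
        assert comp.icer is None
        assert comp.label == "equivalent"

    def test_icer_and_nmb(self):
        a = StrategyResult.from_totals("A", "10y", 1863.0 + 100, 5.0054)
        b = StrategyResult.from_totals("B", "10y", 100.0, 5.0)
        comp = compare_strategies(a, b, wtp=20_000)
        assert comp.icer == pytest.approx(1863.0 / 0.0054, rel=1e-10)
        assert comp.label == "icer"
        assert comp.nmb == pytest.approx(20_000 * 0.0054 - 1863.0, rel=1e-9)

    def test_dominant_classification(self):
        a = StrategyResult.from_totals("A", "10y", 900.0, 5.1)
        b = StrategyResult.from_totals("B", "10y", 1000.0, 5.0)
        assert compare_strategies(a, b).label == "dominant"

    def test_horizon_mismatch_rejected(self):
        a = StrategyResult.from_totals("A", "10y", 1.0, 1.0)
        b = StrategyResult.from_totals("B", "lifetime", 1.0, 1.0)
        with pytest.raises(ValueError, match="horizon"):
            compare_strategies(a, b)

    def test_qaly_tie_with_cost_difference_reports_undefined(self):
        a = StrategyResult.from_totals("A", "10y", 1100.0, 5.0)
        b = StrategyResult.from_totals("B", "10y", 1000.0, 5.0)
        comp = compare_strategies(a, b)
        assert comp.icer is None
        assert comp.label == Comparison.ICER_UNDEFINED
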