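"""Discounting, effect accrual, cost categories, incremental results."""

import numpy as np
import pytest

from ptcl_cua.cea_accounting import (
    COST_CATEGORIES,
    CEAResult,
    accrue_costs,
    accrue_effects,
    discount_factor,
    incremental,
    run_cea,
    table2_frame,
)
from ptcl_cua.markov_engine import (
    TRACE_COLUMNS,
    CohortTrace,
    PhaseSchedule,
    build_schedule,
    run_cohort,
)
from ptcl_cua.synthetic_data import default_parameters


class TestDiscountFactor:
    def test_anchors_and_zero_rate(self):
        assert discount_factor(0, 0.05) == 1.0
        assert discount_factor(520, 0.0) == 1.0
        assert discount_factor(52, 0.05) == pytest.approx(
            1.05 ** (-52 / 52.1), rel=1e-12
        )
        assert discount_factor(52, 0.05) == pytest.approx(0.95247, abs=5e-6)

    def test_monotone_decreasing_in_week(self):
        f = [discount_factor(w, 0.05) for w in range(0, 800, 7)]
        assert np.all(np.diff(f) < 0)

    def test_annual_step_convention_close_to_fractional(self):
        frac = sum(discount_factor(w, 0.05) for w in range(782))
        step = sum(discount_factor(w, 0.05, convention="annual_step") for w in range(782))
        assert step == pytest.approx(frac, rel=0.03)
        assert step >= frac  # step discounts later within each year

    def test_invalid_arguments(self):
        with pytest.raises(ValueError):
            discount_factor(-1, 0.05)
        with pytest.raises(ValueError):
            discount_factor(1, -0.05)
        with pytest.raises(ValueError):
            discount_factor(1, 0.05, convention="monthly")


def _hand_trace(occupancy_rows, arm="cc"):
    occ = np.array(occupancy_rows, dtype=float)
    cycles = occ.shape[0] - 1
    return CohortTrace(
        arm=arm,
        occupancy=occ,
        pause1=np.zeros((cycles + 1, 4)),
        pause2=np.zeros((cycles + 1, 4)),
        ages=48.0 + np.arange(cycles + 1) / 52.1,
        sct_transplants={},
    )


def _pause_schedule(cycles, arm="cc"):
    # tiny schedule whose first weeks are all pause (no AE decrement)
    return PhaseSchedule(
        arm=arm, cycles=cycles, initial_tx_end=0, subsequent_start=cycles + 10,
        subsequent_end=cycles + 11, sct_week_initial=cycles + 5,
        sct_week_subsequent=cycles + 20, initial_cycle_weeks=3,
    )


class TestAccrueEffects:
    def test_two_week_hand_trace(self, params):
        """Mass 1.0 in PD week 1 and 0.5 week 2, no discounting:
        LY = 1.5/52.1 and QALY = 0.567 x 1.5/52.1."""
        pd_col = TRACE_COLUMNS.index("pause_PD")
        dead_col = TRACE_COLUMNS.index("dead")
        rows = np.zeros((3, len(TRACE_COLUMNS)))
        rows[0, pd_col] = 1.0
        rows[1, pd_col], rows[1, dead_col] = 0.5, 0.5
        rows[2, pd_col], rows[2, dead_col] = 0.5, 0.5
        trace = _hand_trace(rows)
        lys, qalys = accrue_effects(trace, params, _pause_schedule(2), discount=False)
        assert lys == pytest.approx(1.5 / 52.1, abs=1e-12)
        assert qalys == pytest.approx(0.567 * 1.5 / 52.1, abs=1e-12)

    def test_year_in_complete_response(self, params):
        """52 undiscounted weeks all in CR accrue ~1 LY and ~0.885 QALY."""
        cr_col = TRACE_COLUMNS.index("pause_CR")
        rows = np.zeros((53, len(TRACE_COLUMNS)))
        rows[:, cr_col] = 1.0
        lys, qalys = accrue_effects(
            _hand_trace(rows), params, _pause_schedule(52), discount=False
        )
        assert lys == pytest.approx(52 / 52.1, abs=1e-12)
        assert qalys == pytest.approx(0.885 * 52 / 52.1, abs=1e-12)

    def test_unit_utilities_make_qalys_equal_lys(self, params, life_table):
        params.utilities = {r: 1.0 for r in params.utilities}
        params.sct_success_utility_bands = [(45, 64, 1.0)]
        for it in params.ae_items:
            it.disutility = 0.0
        sched = build_schedule("cc", params)
        trace = run_cohort("cc", params, lambda w: 0.01, life_table)
        lys, qalys = accrue_effects(trace, params, sched)
        assert qalys == pytest.approx(lys, abs=1e-12)

    def test_qaly_never_exceeds_ly(self, params, life_table):
        sched = build_schedule("pralatrexate", params)
        trace = run_cohort("pralatrexate", params, lambda w: 0.005, life_table)
        lys, qalys = accrue_effects(trace, params, sched)
        assert 0.0 <= qalys <= lys

    def test_zero_hazard_limit(self, params, zero_life_table):
        """All death probabilities zero: undiscounted LYs = 782/52.1."""
        sched = build_schedule("cc", params)
        trace = run_cohort("cc", params, lambda w: 0.0, zero_life_table)
        lys, _ = accrue_effects(trace, params, sched, discount=False)
        assert lys == pytest.approx(782 / 52.1, abs=1e-9)


class TestAccrueCosts:
    def test_single_week_pralatrexate_medication(self, params):
        """Mass 1 in initial treatment for one undiscounted week costs
        $2,465 of medication."""
        it_cols = [TRACE_COLUMNS.index(f"initial_tx_{r}") for r in ("CR", "PR")]
        rows = np.zeros((2, len(TRACE_COLUMNS)))
        rows[:, it_cols[0]] = 0.4
        rows[:, it_cols[1]] = 0.6
        sched = PhaseSchedule(
            arm="pralatrexate", cycles=1, initial_tx_end=1, subsequent_start=5,
            subsequent_end=6, sct_week_initial=3, sct_week_subsequent=8,
            initial_cycle_weeks=7,
        )
        costs = accrue_costs(_hand_trace(rows, "pralatrexate"), params, sched,
                             discount=False)
        assert costs["initial_tx_medication"] == pytest.approx(2465.0, abs=1e-9)
        assert costs["concomitant_initial"] == pytest.approx(4.0)  # first cycle
        assert costs["monitoring_initial"] == pytest.approx(106.0)

    def test_cc_initial_ae_expectation(self, params):
        """Hand sum over the AE table: 0.0365x1288 + 0.1122x2859 +
        0.0257x2877 + 0.1250x2760 + 0.0053x707 + 0.0063x643 = 794.53/wk."""
        assert params.ae_expected_weekly_cost("cc_initial") == pytest.approx(
            794.5287, abs=1e-4
        )

    def test_sct_cost_charged_to_all_transplanted(self, params):
        rows = np.zeros((2, len(TRACE_COLUMNS)))
        rows[:, TRACE_COLUMNS.index("pause_CR")] = 1.0
        trace = _hand_trace(rows)
        trace.sct_transplants = {0: 0.1}
        params.discount_annual = 0.0
        costs = accrue_costs(trace, params, _pause_schedule(1), discount=False)
        assert costs["sct"] == pytest.approx(0.1 * 27343.0)

    def test_category_additivity_and_scale_equivariance(self, params, life_table):
        sched = build_schedule("cc", params)
        trace = run_cohort("cc", params, lambda w: 0.01, life_table)
        res = run_cea(trace, params, sched)
        assert res.total_cost == pytest.approx(sum(res.costs.values()), abs=1e-6)
        c = 3.0
        scaled = params.copy()
        scaled.medication_weekly = {k: c * v for k, v in scaled.medication_weekly.items()}
        scaled.concomitant_weekly = {k: c * v for k, v in scaled.concomitant_weekly.items()}
        scaled.monitoring_weekly = {k: c * v for k, v in scaled.monitoring_weekly.items()}
        scaled.sct_cost *= c
        for it in scaled.ae_items:
            it.cost *= c
        res_c = run_cea(trace, scaled, sched)
        assert res_c.total_cost == pytest.approx(c * res.total_cost, rel=1e-12)
        assert res_c.lys == pytest.approx(res.lys) and res_c.qalys == pytest.approx(res.qalys)

    def test_discounting_lowers_every_category(self, params, life_table):
        sched = build_schedule("pralatrexate", params)
        trace = run_cohort("pralatrexate", params, lambda w: 0.01, life_table)
        disc = accrue_costs(trace, params, sched, discount=True)
        undisc = accrue_costs(trace, params, sched, discount=False)
        for cat in COST_CATEGORIES:
            assert disc[cat] <= undisc[cat] + 1e-12

    def test_ae_cost_magnitude_structural_crosscheck(self, params, life_table):
        """Weekly AE probabilities applied over 14 treatment weeks put the
        comparator's undiscounted AE cost at the order of 794.53 x 14 plus
        the subsequent-phase contribution, net of mortality weighting: it
        must land between 30% and 100% of the no-mortality bound."""
        sched = build_schedule("cc", params)
        trace = run_cohort("cc", params, lambda w: 0.02, life_table)
        costs = accrue_costs(trace, params, sched, discount=False)
        bound = (
            params.ae_expected_weekly_cost("cc_initial") * 14
            + params.ae_expected_weekly_cost("cc_subsequent") * 13
        )
        assert 0.3 * bound < costs["ae_treatment"] < bound

    def test_mismatched_horizon_rejected(self, params):
        rows = np.zeros((3, len(TRACE_COLUMNS)))
        with pytest.raises(ValueError):
            accrue_costs(_hand_trace(rows), params, _pause_schedule(5))


def _stub_result(arm, cost, lys, qalys):
    return CEAResult(
        arm=arm, costs={"initial_tx_medication": cost}, lys=lys, qalys=qalys,
        discount_annual=0.05, horizon_years=15.0,
    )


class TestIncremental:
    def test_printed_totals_arithmetic(self):
        """From the published per-arm totals: Dcost 28,632, DQALY 0.731,
        ICER/QALY ~39,168 from the rounded inputs."""
        a = _stub_result("pralatrexate", 48677.0, 3.499, 1.075)
        b = _stub_result("cc", 20045.0, 1.932, 0.344)
        inc = incremental(a, b)
        assert inc.delta_cost == pytest.approx(28632.0)
        assert inc.delta_ly == pytest.approx(1.567)
        assert inc.delta_qaly == pytest.approx(0.731)
        assert inc.icer_per_qaly == pytest.approx(28632.0 / 0.731, rel=1e-12)

    def test_identical_results_undefined_icer(self):
        a = _stub_result("a", 100.0, 1.0, 0.8)
        inc = incremental(a, _stub_result("b", 100.0, 1.0, 0.8))
        assert inc.icer_per_qaly is None and inc.icer_per_ly is None
        assert inc.dominance is None

    def test_simple_ratio(self):
        inc = incremental(
            _stub_result("a", 1500.0, 1.5, 1.0), _stub_result("b", 500.0, 1.0, 0.5)
        )
        assert inc.icer_per_qaly == pytest.approx(2000.0)

    def test_dominance_flags(self):
        cheap_good = _stub_result("a", 50.0, 2.0, 1.5)
        dear_bad = _stub_result("b", 100.0, 1.0, 0.5)
        assert incremental(cheap_good, dear_bad).dominance == "dominant"
        assert incremental(dear_bad, cheap_good).dominance == "dominated"

    def test_mismatched_settings_rejected(self):
        a = _stub_result("a", 1.0, 1.0, 1.0)
        b = _stub_result("b", 1.0, 1.0, 1.0)
        b.discount_annual = 0.03
        with pytest.raises(ValueError):
            incremental(a, b)

    def test_table_frame_shape(self):
        a = _stub_result("pralatrexate", 48677.0, 3.499, 1.075)
        b = _stub_result("cc", 20045.0, 1.932, 0.344)
        df = table2_frame(a, b, incremental(a, b))
        assert list(df.columns) == ["quantity", "pralatrexate", "cc", "incremental"]
        total = df.set_index("quantity").loc["total_cost"]
        assert total["incremental"] == pytest.approx(28632.0)
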