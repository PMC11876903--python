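"""Micro-costing ledger arithmetic, patient costs, and accrual cross-checks."""

import dataclasses

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from hccsim.costing import (
    CostLedger,
    LineItem,
    PatientCostParams,
    accrue_costs,
    accrue_qalys,
    annualize,
    default_ledger,
    expected_annual_oop,
    load_ledger,
    patient_oop_per_screen,
    per_patient_total,
)
from hccsim.engine import simulate_arm, draw_substrate
from hccsim.parameters import (
    ModelParams,
    SimulationConfig,
    UnprintedParams,
    ValidationError,
)


class TestLedger:
    def test_program_ledger_reproduces_published_totals_to_the_cent(self):
        ledger = default_ledger()
        assert round(ledger.total_cost, 2) == 69_905.32
        assert round(per_patient_total(ledger), 2) == 48.68
        first, later = annualize(ledger)
        assert round(first, 2) == 32.45
        assert round(later, 2) == 21.90

    def test_empty_ledger_costs_nothing(self):
        ledger = CostLedger(items=[])
        assert per_patient_total(ledger) == 0.0
        assert annualize(ledger) == (0.0, 0.0)

    def test_per_patient_total_is_linear_in_the_ledger(self):
        ledger = default_ledger()
        doubled = ledger.scaled(2.0)
        assert per_patient_total(doubled) == pytest.approx(2 * per_patient_total(ledger))
        f2, l2 = annualize(doubled)
        f1, l1 = annualize(ledger)
        assert (f2, l2) == pytest.approx((2 * f1, 2 * l1))

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(factor=st.floats(0.01, 100.0))
    def test_annualize_homogeneous_of_degree_one(self, factor):
        f1, l1 = annualize(default_ledger())
        f2, l2 = annualize(default_ledger().scaled(factor))
        assert f2 == pytest.approx(factor * f1, rel=1e-9)
        assert l2 == pytest.approx(factor * l1, rel=1e-9)

    def test_only_one_time_items_leave_no_recurring_cost(self):
        ledger = CostLedger(items=[LineItem("setup", 900.0, one_time=True)],
                            outreach_arm_n=100, window_months=18)
        first, later = annualize(ledger)
        assert first == pytest.approx(9.0 * 12 / 18)
        assert later == 0.0

    def test_zero_denominator_is_rejected(self):
        ledger = CostLedger(items=[LineItem("x", 1.0)], outreach_arm_n=0)
        with pytest.raises(ValidationError):
            per_patient_total(ledger)

    def test_csv_round_trip(self, tmp_path):
        path = tmp_path / "ledger.csv"
        default_ledger().to_frame().assign(
            one_time=lambda d: d.one_time.astype(int)).to_csv(path, index=False)
        again = load_ledger(path)
        assert again.total_cost == pytest.approx(default_ledger().total_cost)
        assert round(per_patient_total(again), 2) == 48.68

    def test_malformed_csv_names_the_row(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text("activity,total_cost,one_time\nok,10,0\nbroken,abc,0\n")
        with pytest.raises(ValidationError, match="broken"):
            load_ledger(path)


class TestPatientCosts:
    def test_travel_component_alone(self):
        p = PatientCostParams(employment_rate=0.0)
        assert patient_oop_per_screen(p) == pytest.approx(0.16 * 20)  # $3.20

    def test_no_travel_no_employment_costs_nothing(self):
        p = PatientCostParams(employment_rate=0.0, roundtrip_miles=0.0)
        assert patient_oop_per_screen(p) == 0.0

    def test_loaded_wage_formula(self):
        p = PatientCostParams()
        expected = 0.16 * 20 + 0.30 * 3 * p.hourly_wage * 1.276
        assert patient_oop_per_screen(p) == pytest.approx(expected)

    def test_annual_out_of_pocket_near_published_figure(self):
        """At outreach adherence and the default wage the annual patient
        out-of-pocket cost is approximately $13."""
        annual = expected_annual_oop(PatientCostParams(), adherence=0.35)
        assert annual == pytest.approx(13.0, rel=0.2)


class TestAccrual:
    def _single_detection_trace(self, config, detect_cycle, stage, n_before=0):
        # COMP until detection, detected stage afterwards
        from hccsim.engine import HealthState as S
        trace = [int(S.COMP_CIRRHOSIS)] * (config.n_cycles + 1)
        det_state = int(S.HCC_EARLY_DETECTED) if stage == 1 else int(S.HCC_LATE_DETECTED)
        for t in range(detect_cycle + 1, config.n_cycles + 1):
            trace[t] = det_state
        return trace

    def test_zero_cost_parameters_accrue_nothing(self):
        mp = ModelParams(cost_treat_early=0, cost_treat_late=0,
                         outreach_cost_y1=0, outreach_cost_later=0)
        up = UnprintedParams(cost_care_comp_annual=0, cost_care_decomp_annual=0,
                             cost_diagnostic_workup=0)
        config = SimulationConfig(n_patients=1)
        trace = self._single_detection_trace(config, 4, 1)
        assert accrue_costs(trace, 4, 1, "outreach", mp, up, config) == 0.0

    def test_detection_cost_discounts_at_three_percent_per_year(self):
        """Moving the same early detection one year later divides the
        treatment cost by exactly 1.03."""
        mp = ModelParams(outreach_cost_y1=0, outreach_cost_later=0)
        up = UnprintedParams(cost_care_comp_annual=0, cost_care_decomp_annual=0,
                             cost_diagnostic_workup=0)
        config = SimulationConfig(n_patients=1)
        c0 = accrue_costs(self._single_detection_trace(config, 0, 1), 0, 1,
                          "usual_care", mp, up, config)
        c2 = accrue_costs(self._single_detection_trace(config, 2, 1), 2, 1,
                          "usual_care", mp, up, config)
        assert c2 / c0 == pytest.approx(1 / 1.03, rel=1e-12)
        assert c0 == pytest.approx(174_981.0 * 1.03 ** -0.25, rel=1e-12)

    def test_discounted_accrual_never_exceeds_undiscounted(self, base_params,
                                                           calib_unprinted):
        config = SimulationConfig(n_patients=1)
        mp0 = dataclasses.replace(base_params, discount_cost=0.0, discount_qaly=0.0)
        trace = self._single_detection_trace(config, 6, 2)
        disc = accrue_costs(trace, 6, 2, "outreach", base_params, calib_unprinted, config)
        undisc = accrue_costs(trace, 6, 2, "outreach", mp0, calib_unprinted, config)
        assert 0 < disc <= undisc
        q_disc = accrue_qalys(trace, 6, 2, base_params, calib_unprinted, config)
        q_undisc = accrue_qalys(trace, 6, 2, mp0, calib_unprinted, config)
        assert 0 < q_disc <= q_undisc

    @pytest.mark.parametrize("accrual", ["lifetime", "horizon"])
    @pytest.mark.parametrize("arm", ["outreach", "usual_care"])
    def test_engine_accrual_matches_scalar_reference(self, accrual, arm,
                                                     base_params, calib_unprinted):
        """Vectorized engine accrual equals the per-trajectory reference
        implementation for every patient."""
        config = SimulationConfig(n_patients=400, seed=6, accrual=accrual)
        res = simulate_arm(arm, config, base_params, calib_unprinted,
                           draw_substrate(config), record_states=True)
        for i in range(config.n_patients):
            trace = res.states_trace[:, i]
            ref_c = accrue_costs(trace, int(res.detection_cycle[i]),
                                 int(res.detected_stage[i]), arm, base_params,
                                 calib_unprinted, config,
                                 onset_cycle=int(res.onset_cycle[i]),
                                 terminal=bool(res.terminal_dx[i]))
            ref_q = accrue_qalys(trace, int(res.detection_cycle[i]),
                                 int(res.detected_stage[i]), base_params,
                                 calib_unprinted, config,
                                 onset_cycle=int(res.onset_cycle[i]),
                                 terminal=bool(res.terminal_dx[i]))
            assert res.cost[i] == pytest.approx(ref_c, abs=1e-6), f"patient {i}"
            assert res.qaly[i] == pytest.approx(ref_q, abs=1e-9), f"patient {i}"
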