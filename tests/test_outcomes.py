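"""Utilities, costs, and discounted accumulation."""

import numpy as np
import pytest

from lupus_cea import AnalysisSettings
from lupus_cea.engine import CR_BEL, DEATH, N_SUBSTATES, CohortTrace, HealthState, run_cohort
from lupus_cea.outcomes import (
    EQ5D_FLOOR, CostModel, SteroidTrajectory, UtilityModel, accumulate,
    discount_factor, drug_cost_per_cycle, models_from_params, state_utility_at,
)
from lupus_cea.engine import DrugContext


class TestDiscounting:
    def test_cycle_zero_is_one(self):
        assert discount_factor(0.03, 0, 12) == 1.0

    def test_zero_rate_is_flat(self):
        assert all(discount_factor(0.0, c, 12) == 1.0 for c in (0, 7, 500))

    def test_one_year_closed_form(self):
        assert discount_factor(0.03, 12, 12) == pytest.approx(1 / 1.03, rel=1e-14)


@pytest.fixture(scope="module")
def base_models(calibrated_ledger):
    return models_from_params(calibrated_ledger.base_parameter_set())


class TestDrugCosts:
    def test_off_treatment_costs_nothing(self, base_models):
        _, cm, _ = base_models
        assert drug_cost_per_cycle(cm, DrugContext.OFF_TREATMENT, 5) == 0.0

    def test_vial_ceiling_at_80kg(self, base_models):
        # 80 kg * 10 mg/kg = 800 mg = exactly 2 vials; 81 kg tips to 3
        _, cm, _ = base_models
        c80 = drug_cost_per_cycle(cm, DrugContext.BELIMUMAB, 10, patient_weight_kg=80)
        c81 = drug_cost_per_cycle(cm, DrugContext.BELIMUMAB, 10, patient_weight_kg=81)
        per_infusion = 13 / 12 * cm.wac_belimumab_vial * cm.drug_cost_scalar
        assert c80 == pytest.approx(2 * per_infusion, rel=1e-12)
        assert c81 == pytest.approx(3 * per_infusion, rel=1e-12)

    def test_first_induction_month_carries_loading_dose(self, base_models):
        _, cm, _ = base_models
        first = drug_cost_per_cycle(cm, DrugContext.BELIMUMAB, 0)
        steady = drug_cost_per_cycle(cm, DrugContext.BELIMUMAB, 6)
        assert first > steady

    def test_anifrolumab_is_fixed_dose(self, base_models):
        _, cm, _ = base_models
        c70 = drug_cost_per_cycle(cm, DrugContext.ANIFROLUMAB, 3, patient_weight_kg=70)
        c95 = drug_cost_per_cycle(cm, DrugContext.ANIFROLUMAB, 3, patient_weight_kg=95)
        assert c70 == c95 == pytest.approx(
            13 / 12 * cm.wac_anifrolumab_dose * cm.drug_cost_scalar, rel=1e-12)


class TestUtilities:
    def test_reference_dose_gives_pure_state_utility(self):
        um = UtilityModel({HealthState.COMPLETE_RESPONSE: 0.8,
                           HealthState.PARTIAL_RESPONSE: 0.7,
                           HealthState.NONRESPONSE: 0.6,
                           HealthState.NO_TREATMENT: 0.7,
                           HealthState.PRETREATMENT: 0.65},
                          steroid_decrement_per_mg=0.005)
        steroid = SteroidTrajectory({h: 5.0 for h in um.state_utilities},
                                    reference_dose=5.0)
        u = state_utility_at(um, steroid, HealthState.COMPLETE_RESPONSE, "early", 0)
        assert u == 0.8

    def test_ten_mg_above_reference_costs_005(self, base_models):
        um, _, steroid = base_models
        base = state_utility_at(um, steroid, HealthState.COMPLETE_RESPONSE,
                                "delayed", 0)
        plus10 = SteroidTrajectory(
            {h: d + 10 for h, d in steroid.state_doses.items()},
            reference_dose=steroid.reference_dose)
        shifted = state_utility_at(um, plus10, HealthState.COMPLETE_RESPONSE,
                                   "delayed", 0)
        assert base - shifted == pytest.approx(0.05, abs=1e-12)

    def test_decrement_linear_in_dose_gap(self, base_models):
        # pre-clamp, utility difference is exactly 0.005 per mg/day
        um, _, steroid = base_models
        for gap in (1.0, 2.5, 7.0, 20.0):
            a = SteroidTrajectory({h: 10.0 for h in steroid.state_doses})
            b = SteroidTrajectory({h: 10.0 + gap for h in steroid.state_doses})
            ua = state_utility_at(um, a, HealthState.PARTIAL_RESPONSE, "early", 12)
            ub = state_utility_at(um, b, HealthState.PARTIAL_RESPONSE, "early", 12)
            assert ua - ub == pytest.approx(
                um.steroid_decrement_per_mg * gap, abs=1e-12)

    def test_response_states_ordered_at_every_cycle(self, base_models):
        um, _, steroid = base_models
        for cycle in (0, 4, 60, 179):
            u = {s: state_utility_at(um, steroid, s, "early", cycle)
                 for s in (HealthState.COMPLETE_RESPONSE,
                           HealthState.PARTIAL_RESPONSE,
                           HealthState.NONRESPONSE)}
            assert (u[HealthState.NONRESPONSE] < u[HealthState.PARTIAL_RESPONSE]
                    < u[HealthState.COMPLETE_RESPONSE])

    def test_clamped_to_eq5d_range(self):
        um = UtilityModel({h: 0.1 for h in (
            HealthState.COMPLETE_RESPONSE, HealthState.PARTIAL_RESPONSE,
            HealthState.NONRESPONSE, HealthState.NO_TREATMENT,
            HealthState.PRETREATMENT)}, steroid_decrement_per_mg=0.005)
        steroid = SteroidTrajectory({h: 500.0 for h in um.state_utilities})
        u = state_utility_at(um, steroid, HealthState.NONRESPONSE, "early", 0)
        assert u == EQ5D_FLOOR

    def test_unordered_state_utilities_rejected(self):
        with pytest.raises(ValueError, match="order"):
            UtilityModel({HealthState.COMPLETE_RESPONSE: 0.6,
                          HealthState.PARTIAL_RESPONSE: 0.7,
                          HealthState.NONRESPONSE: 0.8,
                          HealthState.NO_TREATMENT: 0.7,
                          HealthState.PRETREATMENT: 0.65},
                         steroid_decrement_per_mg=0.005)


def _single_state_trace(n_cycles: int, substate: int) -> CohortTrace:
    occ = np.zeros((n_cycles + 1, N_SUBSTATES))
    occ[:, substate] = 1.0
    return CohortTrace(occ, "early")


class TestAccumulate:
    def test_all_death_trace_accrues_nothing(self, base_models, settings):
        um, cm, steroid = base_models
        res = accumulate(_single_state_trace(24, DEATH), um, cm, steroid, settings)
        assert res.cost_discounted == 0.0
        assert res.qaly_discounted == 0.0

    def test_constant_utility_closed_form(self, base_models):
        # u * Y QALYs for Y undiscounted years locked in one state
        um, cm, steroid = base_models
        s = AnalysisSettings(discount_rate=0.0, horizon_years=5.0)
        res = accumulate(_single_state_trace(60, CR_BEL), um, cm, steroid, s)
        u = state_utility_at(um, steroid, HealthState.COMPLETE_RESPONSE, "early", 0)
        # time trend varies by year; integrate it explicitly
        expected = sum(
            state_utility_at(um, steroid, HealthState.COMPLETE_RESPONSE,
                             "early", t) for t in range(60)) / 12
        assert res.qaly_undiscounted == pytest.approx(expected, rel=1e-12)
        assert res.qaly_undiscounted <= u * 5.0

    def test_discounting_reduces_totals(self, calibrated_ledger, settings,
                                        life_table, strategies):
        import dataclasses
        params = calibrated_ledger.base_parameter_set()
        um, cm, steroid = models_from_params(params)
        trace = run_cohort(strategies[0], params, settings, life_table)
        res = accumulate(trace, um, cm, steroid, settings)
        assert res.cost_discounted < res.cost_undiscounted
        assert res.qaly_discounted < res.qaly_undiscounted
        flat = accumulate(trace, um, cm, steroid,
                          dataclasses.replace(settings, discount_rate=0.0))
        assert flat.cost_discounted == pytest.approx(res.cost_undiscounted, rel=1e-12)

    def test_qaly_upper_bound(self, calibrated_ledger, settings, life_table,
                              strategies):
        params = calibrated_ledger.base_parameter_set()
        um, cm, steroid = models_from_params(params)
        trace = run_cohort(strategies[0], params, settings, life_table)
        res = accumulate(trace, um, cm, steroid, settings)
        assert res.qaly_undiscounted <= settings.horizon_years * 1.0

    def test_audit_ledger_reproduces_totals(self, calibrated_ledger, settings,
                                            life_table, strategies):
        params = calibrated_ledger.base_parameter_set()
        um, cm, steroid = models_from_params(params)
        trace = run_cohort(strategies[1], params, settings, life_table)
        res = accumulate(trace, um, cm, steroid, settings, audit=True)
        assert res.audit is not None and len(res.audit) == settings.n_cycles
        assert res.audit["cost_discounted"].sum() == pytest.approx(
            res.cost_discounted, abs=1e-9 * max(1.0, res.cost_discounted))
        assert res.audit["qaly_discounted"].sum() == pytest.approx(
            res.qaly_discounted, abs=1e-9)

    def test_raising_a_utility_raises_qalys(self, calibrated_ledger, settings,
                                            life_table, strategies):
        base = calibrated_ledger.base_parameter_set()
        up = calibrated_ledger.with_values(
            {"u_no_treatment": calibrated_ledger["u_no_treatment"].base_value + 0.05}
        ).base_parameter_set()
        trace = run_cohort(strategies[0], base, settings, life_table)
        r0 = accumulate(trace, *models_from_params(base), settings)
        r1 = accumulate(trace, *models_from_params(up), settings)
        assert r1.qaly_discounted >= r0.qaly_discounted

    def test_raising_a_cost_raises_costs(self, calibrated_ledger, settings,
                                         life_table, strategies):
        base = calibrated_ledger.base_parameter_set()
        up = calibrated_ledger.with_values(
            {"c_secondary_complete":
             calibrated_ledger["c_secondary_complete"].base_value + 500}
        ).base_parameter_set()
        trace = run_cohort(strategies[0], base, settings, life_table)
        r0 = accumulate(trace, *models_from_params(base), settings)
        r1 = accumulate(trace, *models_from_params(up), settings)
        assert r1.cost_discounted > r0.cost_discounted

    def test_cost_ordering_enforced(self):
        with pytest.raises(ValueError, match="order"):
            CostModel(2000.0, 2000.0, 70.0, {
                HealthState.COMPLETE_RESPONSE: 9000.0,
                HealthState.PARTIAL_RESPONSE: 7000.0,
                HealthState.NONRESPONSE: 5000.0,
                HealthState.NO_TREATMENT: 6000.0,
                HealthState.PRETREATMENT: 8000.0})
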