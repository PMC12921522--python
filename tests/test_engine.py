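"""Markov engine: probability conversions, mortality, matrices, cohort runs."""

import dataclasses
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings as hyp_settings, strategies as st

from lupus_cea import AnalysisSettings
from lupus_cea.engine import (
    DEATH, N_SUBSTATES, PRE_BEL, EngineError, HealthState, StrategyConfig,
    annual_to_cycle_prob, apply_odds_ratio, build_transition_matrix,
    cycle_death_prob, run_cohort, smr_bands_from_params,
)
from lupus_cea.parameters import draw_parameter_set


class TestAnnualToCycle:
    @pytest.mark.parametrize("p, expected", [(0.0, 0.0), (1.0, 1.0)])
    def test_boundaries(self, p, expected):
        assert annual_to_cycle_prob(p, 12) == expected

    def test_closed_form(self):
        out = annual_to_cycle_prob(0.12, 12)
        assert out == pytest.approx(1 - 0.88 ** (1 / 12), rel=1e-14)
        assert 1 - (1 - out) ** 12 == pytest.approx(0.12, abs=1e-12)

    @given(p=st.floats(0.0, 1.0), k=st.integers(1, 52))
    @hyp_settings(max_examples=200, deadline=None)
    def test_composition_recovers_annual(self, p, k):
        out = annual_to_cycle_prob(p, k)
        assert 1 - (1 - out) ** k == pytest.approx(p, abs=1e-9)

    def test_rejects_out_of_range(self):
        with pytest.raises(EngineError):
            annual_to_cycle_prob(1.2, 12)


class TestOddsRatio:
    def test_unit_or_is_identity(self):
        assert apply_odds_ratio(0.37, 1.0) == pytest.approx(0.37, rel=1e-14)

    def test_even_odds_closed_form(self):
        assert apply_odds_ratio(0.5, 3.47) == pytest.approx(3.47 / 4.47, rel=1e-12)

    def test_boundary_probabilities_pass_through(self):
        assert apply_odds_ratio(0.0, 2.0) == 0.0
        assert apply_odds_ratio(1.0, 2.0) == 1.0

    @given(p=st.floats(0.01, 0.99),
           or1=st.floats(0.1, 10.0), or2=st.floats(0.1, 10.0))
    @hyp_settings(max_examples=200, deadline=None)
    def test_monotone_in_or(self, p, or1, or2):
        lo, hi = sorted([or1, or2])
        assert apply_odds_ratio(p, lo) <= apply_odds_ratio(p, hi)

    def test_rejects_nonpositive_or(self):
        with pytest.raises(EngineError):
            apply_odds_ratio(0.5, 0.0)


class TestMortality:
    def _unit_smr(self):
        return {"female": [(0.0, 1.0)], "male": [(0.0, 1.0)]}

    def test_smr_one_recovers_life_table(self, life_table):
        # all-female mix, SMR 1: monthly prob must match the raw qx conversion
        p = cycle_death_prob(life_table, self._unit_smr(), 41.0, 1.0, 0)
        qx = life_table.query("sex == 'female' and age == 41")["qx"].iloc[0]
        assert p == pytest.approx(annual_to_cycle_prob(qx, 12), rel=1e-12)

    def test_smr_two_doubles_the_hazard(self, life_table):
        smr2 = {"female": [(0.0, 2.0)], "male": [(0.0, 2.0)]}
        p1 = cycle_death_prob(life_table, self._unit_smr(), 41.0, 0.912, 60)
        p2 = cycle_death_prob(life_table, smr2, 41.0, 0.912, 60)
        assert -math.log(1 - p2) == pytest.approx(-2 * math.log(1 - p1), rel=1e-10)

    def test_age_beyond_table_raises(self, life_table):
        with pytest.raises(EngineError, match="does not cover"):
            cycle_death_prob(life_table, self._unit_smr(), 99.0, 0.9, 30)

    def test_smr_adjusted_survival_below_general_population(
            self, calibrated_ledger, settings, life_table, strategies):
        params = calibrated_ledger.base_parameter_set()
        unit = calibrated_ledger.with_values(
            {n: 1.0 for n in ("smr_female_under40", "smr_female_40plus",
                              "smr_male_under40", "smr_male_40plus")}
        ).base_parameter_set()
        sle = run_cohort(strategies[0], params, settings, life_table).survival()
        gen = run_cohort(strategies[0], unit, settings, life_table).survival()
        assert (sle[1:] < gen[1:]).all()


class TestTransitionMatrix:
    def test_zero_params_give_identity(self, default_ledger):
        zeros = default_ledger.with_values({
            n: 0.0 for n in ("p_cr_to_pr", "p_pr_to_cr", "p_pr_to_nr",
                             "p_nr_to_pr", "p_discontinue", "p_ani_discontinue",
                             "p_flare_off_treatment")})
        params = zeros.base_parameter_set()
        params.profiles = {}
        m = build_transition_matrix(params, StrategyConfig("early"), 0, 0.0)
        # pre-induction cycle: pretreatment holds, nothing else moves
        assert np.allclose(np.diag(m.probs)[[0, 1, 2, 3, 8, 9]], 1.0)

    def test_rows_sum_to_one_across_draws(self, default_ledger, strategies):
        rng = np.random.default_rng(5)
        for _ in range(25):
            params = draw_parameter_set(default_ledger, rng)
            for strategy in strategies:
                for cycle in (0, 3, 4, 40, 170):
                    m = build_transition_matrix(params, strategy, cycle, 0.002)
                    assert np.allclose(m.probs.sum(axis=1), 1.0, atol=1e-10)

    def test_death_row_is_absorbing(self, calibrated_ledger, strategies):
        params = calibrated_ledger.base_parameter_set()
        m = build_transition_matrix(params, strategies[0], 10, 0.01).probs
        assert m[DEATH, DEATH] == 1.0
        assert m[DEATH, :DEATH].sum() == 0.0

    def test_arms_differ_only_in_response_split_rows(self, calibrated_ledger,
                                                     strategies):
        params = calibrated_ledger.base_parameter_set()
        early, delayed = strategies
        cycle = early.induction_cycles - 1
        me = build_transition_matrix(params, early, cycle, 0.001).probs
        md = build_transition_matrix(params, delayed, cycle, 0.001).probs
        diff_rows = np.where(~np.isclose(me, md, atol=1e-15).all(axis=1))[0]
        assert set(diff_rows) == {PRE_BEL}

    def test_overfull_row_raises_with_row_name(self, default_ledger):
        bad = default_ledger.with_values({"p_pr_to_cr": 0.7, "p_pr_to_nr": 0.6})
        params = bad.base_parameter_set()
        with pytest.raises(EngineError, match="partial_response"):
            build_transition_matrix(params, StrategyConfig("early"), 10, 0.0)


def _flat_life_table(qx: float) -> pd.DataFrame:
    rows = [{"age": a, "sex": s, "qx": qx}
            for s in ("female", "male") for a in range(0, 101)]
    return pd.DataFrame(rows)


class TestRunCohort:
    def test_trace_shape_and_start_state(self, calibrated_ledger, settings,
                                          life_table, strategies):
        trace = run_cohort(strategies[0], calibrated_ledger.base_parameter_set(),
                           settings, life_table)
        assert trace.occupancy.shape == (settings.n_cycles + 1, N_SUBSTATES)
        assert trace.occupancy[0, PRE_BEL] == 1.0

    def test_certain_death_absorbs_cohort(self, calibrated_ledger, strategies):
        params = calibrated_ledger.base_parameter_set()
        s = AnalysisSettings(horizon_years=1.0)
        trace = run_cohort(strategies[0], params, s, _flat_life_table(1.0))
        assert trace.occupancy[1:, DEATH] == pytest.approx(1.0)

    def test_conservation_and_death_monotone_over_horizon(
            self, calibrated_ledger, settings, life_table, strategies):
        for strategy in strategies:
            trace = run_cohort(strategy, calibrated_ledger.base_parameter_set(),
                               settings, life_table)
            assert np.allclose(trace.occupancy.sum(axis=1), 1.0, atol=1e-9)
            assert (trace.occupancy >= -1e-15).all()
            assert (np.diff(trace.occupancy[:, DEATH]) >= -1e-15).all()

    def test_matrix_power_oracle_equivalence(self, calibrated_ledger, strategies):
        """With constant per-cycle conditions the trace equals the
        closed-form matrix-power solution."""
        params = calibrated_ledger.base_parameter_set()
        params = dataclasses.replace(params, profiles={})
        lt = _flat_life_table(0.01)
        s = AnalysisSettings(horizon_years=3.0, start_age=41.0)
        strategy = strategies[1]
        trace = run_cohort(strategy, params, s, lt)
        ind = strategy.induction_cycles
        smr = smr_bands_from_params(params)
        p_death = cycle_death_prob(lt, smr, 41.0, s.female_fraction, ind)
        m = build_transition_matrix(params, strategy, ind, p_death).probs
        start = trace.occupancy[ind]
        for k in range(1, 25):
            expected = start @ np.linalg.matrix_power(m, k)
            assert np.allclose(trace.occupancy[ind + k], expected, atol=1e-12)

    def test_unit_or_makes_arms_identical(self, calibrated_ledger, settings,
                                          life_table, strategies):
        params = calibrated_ledger.with_values(
            {"or_sri4_early": 1.0}).base_parameter_set()
        early = run_cohort(strategies[0], params, settings, life_table)
        delayed = run_cohort(strategies[1], params, settings, life_table)
        assert (early.occupancy == delayed.occupancy).all()

    def test_collapsed_view_has_six_states(self, calibrated_ledger, settings,
                                           life_table, strategies):
        trace = run_cohort(strategies[0], calibrated_ledger.base_parameter_set(),
                           settings, life_table)
        collapsed = trace.collapsed()
        assert collapsed.shape[1] == len(HealthState)
        assert np.allclose(collapsed.sum(axis=1), 1.0, atol=1e-9)
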