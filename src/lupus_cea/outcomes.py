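"""Utilities, costs, and discounted accumulation over a cohort trace.

Utilities are EQ-5D values by health state with a shared time trend and a
glucocorticoid disutility of ``steroid_utility_decrement_per_mg`` (0.005 by
default) per mg/day of prednisone-equivalent dose above the reference dose.
Costs combine drug acquisition (wholesale acquisition cost per vial/dose,
weight-based belimumab dosing with vial wastage) and state-stratified
secondary monthly costs in 2024 USD.  QALYs and costs are credited with the
state occupied at the beginning of each cycle and discounted at the annual
rate compounded per cycle.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable

import numpy as np
import pandas as pd

from .engine import (
    DEATH, N_SUBSTATES, NO_TX, SUBSTATE_DRUG, SUBSTATE_HEALTH,
    CohortTrace, DrugContext, HealthState, StrategyConfig,
)

EQ5D_FLOOR = -0.594  # worst health state of the EQ-5D value set
BELIMUMAB_VIAL_MG = 400.0
BELIMUMAB_MG_PER_KG = 10.0
INFUSIONS_PER_MONTH = 13.0 / 12.0  # every-4-weeks schedule on a monthly clock

#: ledger names the outcome models read.  Response-state utilities and
#: secondary costs are gap-parameterised (level plus ordered increments) so
#: the state ordering nonresponse <= partial <= complete (utilities) and
#: nonresponse >= partial >= complete (costs) holds for every sampled set.
OUTCOME_PARAMETERS = frozenset({
    "u_complete", "u_decrement_partial", "u_decrement_nonresponse",
    "u_no_treatment", "u_pretreatment", "utility_trend",
    "steroid_utility_decrement_per_mg",
    "pred_dose_complete", "pred_dose_partial", "pred_dose_nonresponse",
    "pred_dose_no_treatment", "pred_dose_pretreatment", "pred_dose_reference",
    "early_pred_offset",
    "wac_belimumab_vial", "wac_anifrolumab_dose", "drug_cost_scalar",
    "patient_weight_kg",
    "c_secondary_complete", "c_increment_partial", "c_increment_nonresponse",
    "c_secondary_no_treatment", "c_secondary_pretreatment",
})


class OutcomeError(ValueError):
    pass


@dataclass
class UtilityModel:
    """Per-state EQ-5D utilities with a shared multiplicative time trend."""

    state_utilities: dict[HealthState, float]
    steroid_decrement_per_mg: float
    trend: Callable[[float], float] = lambda year: 1.0

    def __post_init__(self) -> None:
        u = self.state_utilities
        if any(not EQ5D_FLOOR <= v <= 1.0 for v in u.values()):
            raise OutcomeError(f"state utilities must lie in [{EQ5D_FLOOR}, 1]")
        if not (u[HealthState.NONRESPONSE] <= u[HealthState.PARTIAL_RESPONSE]
                <= u[HealthState.COMPLETE_RESPONSE]):
            raise OutcomeError("utilities must order nonresponse <= partial <= complete")


@dataclass
class SteroidTrajectory:
    """Prednisone-equivalent dose (mg/day) per state, with strategy offsets.

    The early-initiation cohort enters with a higher baseline dose; the
    offset is carried on the pretreatment state, where baseline exposure
    lives, and vanishes once patients respond and taper.
    """

    state_doses: dict[HealthState, float]
    reference_dose: float = 0.0
    strategy_offsets: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if any(v < 0 for v in self.state_doses.values()):
            raise OutcomeError("prednisone doses must be non-negative")

    def dose(self, state: HealthState, strategy_label: str) -> float:
        d = self.state_doses[state]
        if state is HealthState.PRETREATMENT:
            d += self.strategy_offsets.get(strategy_label, 0.0)
        return d


@dataclass
class CostModel:
    """Drug acquisition plus state-stratified secondary monthly costs."""

    wac_belimumab_vial: float
    wac_anifrolumab_dose: float
    patient_weight_kg: float
    secondary_monthly: dict[HealthState, float]
    drug_cost_scalar: float = 1.0
    wac_multiplier: Callable[[int], float] = lambda cycle: 1.0  # scenario hook

    def __post_init__(self) -> None:
        if self.patient_weight_kg <= 0:
            raise OutcomeError("patient weight must be positive")
        if any(v < 0 for v in self.secondary_monthly.values()):
            raise OutcomeError("secondary costs must be non-negative")
        s = self.secondary_monthly
        if not (s[HealthState.NONRESPONSE] >= s[HealthState.PARTIAL_RESPONSE]
                >= s[HealthState.COMPLETE_RESPONSE]):
            raise OutcomeError(
                "secondary costs must order nonresponse >= partial >= complete")


@dataclass
class StrategyResult:
    """Discounted and undiscounted totals for one strategy run."""

    strategy: str
    cost_discounted: float
    qaly_discounted: float
    cost_undiscounted: float
    qaly_undiscounted: float
    audit: pd.DataFrame | None = None

    def as_dict(self) -> dict:
        return {"strategy": self.strategy,
                "cost_discounted": self.cost_discounted,
                "qaly_discounted": self.qaly_discounted,
                "cost_undiscounted": self.cost_undiscounted,
                "qaly_undiscounted": self.qaly_undiscounted}


def discount_factor(annual_rate: float, cycle: int, cycles_per_year: int) -> float:
    """(1+r)^(-cycle/cycles_per_year); 1 at cycle 0 or zero rate."""
    if annual_rate < 0:
        raise OutcomeError("discount rate must be non-negative")
    return (1.0 + annual_rate) ** (-cycle / cycles_per_year)


def drug_cost_per_cycle(cost_model: CostModel, context: DrugContext | None,
                        cycle: int, patient_weight_kg: float | None = None) -> float:
    """Acquisition cost of one model cycle in a drug context.

    Belimumab: 10 mg/kg rounded up to whole 400 mg vials (wastage), one
    infusion per 4 weeks mapped to 13/12 infusions per monthly cycle; the
    first induction month carries the extra week-2 loading dose.
    Anifrolumab: one fixed 300 mg dose per 4 weeks, same 13/12 mapping.
    """
    if context is None or context is DrugContext.OFF_TREATMENT:
        return 0.0
    weight = cost_model.patient_weight_kg if patient_weight_kg is None else patient_weight_kg
    mult = cost_model.drug_cost_scalar * cost_model.wac_multiplier(cycle)
    if context is DrugContext.BELIMUMAB:
        vials = math.ceil(BELIMUMAB_MG_PER_KG * weight / BELIMUMAB_VIAL_MG)
        per_infusion = vials * cost_model.wac_belimumab_vial
        infusions = INFUSIONS_PER_MONTH + (1.0 if cycle == 0 else 0.0)
        return mult * per_infusion * infusions
    if context is DrugContext.ANIFROLUMAB:
        return mult * cost_model.wac_anifrolumab_dose * INFUSIONS_PER_MONTH
    raise OutcomeError(f"unknown drug context {context!r}")


def state_utility_at(utility_model: UtilityModel, steroid: SteroidTrajectory,
                     state: HealthState, strategy: StrategyConfig | str,
                     cycle: int, cycles_per_year: int = 12) -> float:
    """EQ-5D utility of a living state at a cycle, steroid-adjusted.

    Identical across strategies given the same state and dose; arms differ
    only through their steroid offsets and state occupancy.
    """
    if state is HealthState.DEATH:
        return 0.0
    label = strategy if isinstance(strategy, str) else strategy.label
    year = cycle / cycles_per_year
    base = utility_model.state_utilities[state] * utility_model.trend(year)
    dose = steroid.dose(state, label)
    u = base - utility_model.steroid_decrement_per_mg * (dose - steroid.reference_dose)
    return min(max(u, EQ5D_FLOOR), 1.0)


# ---------------------------------------------------------------------------
# model construction from a parameter set

_STATE_KEYS = {
    HealthState.COMPLETE_RESPONSE: "complete",
    HealthState.PARTIAL_RESPONSE: "partial",
    HealthState.NONRESPONSE: "nonresponse",
    HealthState.NO_TREATMENT: "no_treatment",
    HealthState.PRETREATMENT: "pretreatment",
}


def models_from_params(params, wac_multiplier: Callable[[int], float] | None = None
                       ) -> tuple[UtilityModel, CostModel, SteroidTrajectory]:
    """Build the outcome models the accumulator needs from ledger values."""
    u_cr = params["u_complete"]
    u_pr = max(u_cr - params["u_decrement_partial"], EQ5D_FLOOR)
    u_nr = max(u_pr - params["u_decrement_nonresponse"], EQ5D_FLOOR)
    um = UtilityModel(
        state_utilities={
            HealthState.COMPLETE_RESPONSE: u_cr,
            HealthState.PARTIAL_RESPONSE: u_pr,
            HealthState.NONRESPONSE: u_nr,
            HealthState.NO_TREATMENT: params["u_no_treatment"],
            HealthState.PRETREATMENT: params["u_pretreatment"],
        },
        steroid_decrement_per_mg=params["steroid_utility_decrement_per_mg"],
        trend=lambda year: params.at("utility_trend", year),
    )
    doses = {hs: params[f"pred_dose_{key}"] for hs, key in _STATE_KEYS.items()}
    steroid = SteroidTrajectory(
        state_doses=doses,
        reference_dose=params["pred_dose_reference"],
        strategy_offsets={"early": params["early_pred_offset"]},
    )
    c_cr = params["c_secondary_complete"]
    c_pr = c_cr + params["c_increment_partial"]
    c_nr = c_pr + params["c_increment_nonresponse"]
    cm = CostModel(
        wac_belimumab_vial=params["wac_belimumab_vial"],
        wac_anifrolumab_dose=params["wac_anifrolumab_dose"],
        patient_weight_kg=params["patient_weight_kg"],
        secondary_monthly={
            HealthState.COMPLETE_RESPONSE: c_cr,
            HealthState.PARTIAL_RESPONSE: c_pr,
            HealthState.NONRESPONSE: c_nr,
            HealthState.NO_TREATMENT: params["c_secondary_no_treatment"],
            HealthState.PRETREATMENT: params["c_secondary_pretreatment"],
        },
        drug_cost_scalar=params["drug_cost_scalar"],
        wac_multiplier=wac_multiplier or (lambda cycle: 1.0),
    )
    return um, cm, steroid


def _per_cycle_arrays(n_cycles: int, utility_model: UtilityModel,
                      cost_model: CostModel, steroid: SteroidTrajectory,
                      strategy_label: str, cycles_per_year: int
                      ) -> tuple[np.ndarray, np.ndarray]:
    """(cycles, substates) utility and cost arrays, built per distinct year."""
    u = np.zeros((n_cycles, N_SUBSTATES))
    c = np.zeros((n_cycles, N_SUBSTATES))
    cache: dict[tuple, tuple[np.ndarray, np.ndarray]] = {}
    for t in range(n_cycles):
        key = (t // cycles_per_year, cost_model.wac_multiplier(t), t == 0)
        rows = cache.get(key)
        if rows is None:
            ut = np.zeros(N_SUBSTATES)
            ct = np.zeros(N_SUBSTATES)
            for sub in range(N_SUBSTATES):
                if sub == DEATH:
                    continue
                hs = SUBSTATE_HEALTH[sub]
                ut[sub] = state_utility_at(utility_model, steroid, hs,
                                           strategy_label, t, cycles_per_year)
                ct[sub] = (cost_model.secondary_monthly[hs]
                           + drug_cost_per_cycle(cost_model, SUBSTATE_DRUG[sub], t))
            rows = cache[key] = (ut, ct)
        u[t], c[t] = rows
    return u, c


def accumulate(trace: CohortTrace, utility_model: UtilityModel,
               cost_model: CostModel, steroid: SteroidTrajectory,
               settings, audit: bool = False) -> StrategyResult:
    """Discounted cost and QALY totals for one strategy run.

    Each cycle contributes occupancy-weighted cost and utility/12 with the
    beginning-of-cycle state convention; the optional half-cycle correction
    averages adjacent occupancy rows instead.
    """
    n = trace.n_cycles
    occ = trace.occupancy[:-1]
    if settings.half_cycle_correction:
        occ = 0.5 * (trace.occupancy[:-1] + trace.occupancy[1:])
    cpy = settings.cycles_per_year
    u, c = _per_cycle_arrays(n, utility_model, cost_model, steroid,
                             trace.strategy, cpy)
    df = (1.0 + settings.discount_rate) ** (-np.arange(n) / cpy)
    cost_cycle = (occ * c).sum(axis=1)
    qaly_cycle = (occ * u).sum(axis=1) / cpy
    result = StrategyResult(
        strategy=trace.strategy,
        cost_discounted=float(cost_cycle @ df),
        qaly_discounted=float(qaly_cycle @ df),
        cost_undiscounted=float(cost_cycle.sum()),
        qaly_undiscounted=float(qaly_cycle.sum()),
    )
    if audit:
        frame = trace.to_frame().iloc[:n].copy()
        frame.insert(0, "cycle", np.arange(n))
        frame["discount_factor"] = df
        frame["cost"] = cost_cycle
        frame["qaly"] = qaly_cycle
        frame["cost_discounted"] = cost_cycle * df
        frame["qaly_discounted"] = qaly_cycle * df
        result.audit = frame
    return result
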