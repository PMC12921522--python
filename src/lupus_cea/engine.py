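"""Markov cohort engine for the 6-state SLE treatment model.

The reported model has six mutually exclusive health states — pretreatment,
complete response, partial response, nonresponse, no treatment, death
(absorbing) — evaluated on monthly cycles.  Because a memoryless chain over
those six states cannot encode which biologic a patient is currently on
(belimumab first line, anifrolumab after a switch), the engine expands the
state space to HealthState x DrugContext and collapses back to the six
reported states for output.

Cohort mechanics per cycle: the age/sex-blended, SMR-inflated death
probability is applied first from every living state, and the remaining
probability mass follows the disease transitions (death-first competing-risk
convention).  All patients start in pretreatment on the strategy's first
biologic, remain there during the induction period, and split into the three
response states at the induction boundary; for the early-initiation arm the
complete-response (SRI-4) probability is lifted on the odds scale by the
early-treatment odds ratio.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from enum import IntEnum

import numpy as np
import pandas as pd


class HealthState(IntEnum):
    PRETREATMENT = 0
    COMPLETE_RESPONSE = 1
    PARTIAL_RESPONSE = 2
    NONRESPONSE = 3
    NO_TREATMENT = 4
    DEATH = 5


class DrugContext(IntEnum):
    BELIMUMAB = 0
    ANIFROLUMAB = 1
    OFF_TREATMENT = 2


# internal sub-state layout: (HealthState, DrugContext) collapsed for
# NO_TREATMENT (always off-treatment) and DEATH (no drug context)
PRE_BEL, CR_BEL, PR_BEL, NR_BEL = 0, 1, 2, 3
PRE_ANI, CR_ANI, PR_ANI, NR_ANI = 4, 5, 6, 7
NO_TX, DEATH = 8, 9
N_SUBSTATES = 10

#: sub-state index -> reported health state
SUBSTATE_HEALTH = (
    HealthState.PRETREATMENT, HealthState.COMPLETE_RESPONSE,
    HealthState.PARTIAL_RESPONSE, HealthState.NONRESPONSE,
    HealthState.PRETREATMENT, HealthState.COMPLETE_RESPONSE,
    HealthState.PARTIAL_RESPONSE, HealthState.NONRESPONSE,
    HealthState.NO_TREATMENT, HealthState.DEATH,
)

#: sub-state index -> drug context (None for DEATH)
SUBSTATE_DRUG = (
    DrugContext.BELIMUMAB, DrugContext.BELIMUMAB,
    DrugContext.BELIMUMAB, DrugContext.BELIMUMAB,
    DrugContext.ANIFROLUMAB, DrugContext.ANIFROLUMAB,
    DrugContext.ANIFROLUMAB, DrugContext.ANIFROLUMAB,
    DrugContext.OFF_TREATMENT, None,
)

#: ledger names the transition engine reads
ENGINE_PARAMETERS = frozenset({
    "p_response_complete", "p_response_partial", "or_sri4_early",
    "p_cr_to_pr", "p_pr_to_cr", "p_pr_to_nr", "p_nr_to_pr",
    "p_discontinue", "frac_disc_stop", "frac_disc_switch",
    "p_flare_off_treatment",
    "p_ani_response_complete", "p_ani_response_partial", "p_ani_discontinue",
    "smr_female_under40", "smr_female_40plus",
    "smr_male_under40", "smr_male_40plus",
})


class EngineError(ValueError):
    pass


@dataclass(frozen=True)
class StrategyConfig:
    """One initiation strategy (early or delayed belimumab)."""

    label: str
    induction_cycles: int = 4
    first_biologic: DrugContext = DrugContext.BELIMUMAB
    switch_biologic: DrugContext = DrugContext.ANIFROLUMAB
    response_or_applied: bool = False  # early arm: SRI-4 OR lifts response odds

    def __post_init__(self) -> None:
        if self.induction_cycles < 1:
            raise EngineError("induction_cycles must be >= 1")


EARLY = StrategyConfig(label="early", response_or_applied=True)
DELAYED = StrategyConfig(label="delayed", response_or_applied=False)


@dataclass
class TransitionMatrix:
    probs: np.ndarray  # (N_SUBSTATES, N_SUBSTATES)
    cycle_index: int

    def __post_init__(self) -> None:
        p = self.probs
        if p.shape != (N_SUBSTATES, N_SUBSTATES):
            raise EngineError("transition matrix has wrong shape")
        if (p < -1e-12).any() or (p > 1 + 1e-12).any():
            raise EngineError("transition probabilities outside [0,1]")
        if not np.allclose(p.sum(axis=1), 1.0, atol=1e-10):
            raise EngineError("transition matrix rows must sum to 1")


@dataclass
class CohortTrace:
    """State-occupancy fractions over cycles for one strategy."""

    occupancy: np.ndarray  # (cycles+1, N_SUBSTATES)
    strategy: str

    @property
    def n_cycles(self) -> int:
        return self.occupancy.shape[0] - 1

    def collapsed(self) -> np.ndarray:
        """Occupancy over the 6 reported health states."""
        out = np.zeros((self.occupancy.shape[0], len(HealthState)))
        for sub, hs in enumerate(SUBSTATE_HEALTH):
            out[:, hs] += self.occupancy[:, sub]
        return out

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.collapsed(),
                            columns=[s.name.lower() for s in HealthState])

    def survival(self) -> np.ndarray:
        return 1.0 - self.occupancy[:, DEATH]

    def person_years(self, state: HealthState, cycles_per_year: int = 12) -> float:
        """Undiscounted person-time in a reported state (begin-of-cycle)."""
        return float(self.collapsed()[:-1, state].sum() / cycles_per_year)


# ---------------------------------------------------------------------------
# life table & mortality

def load_life_table(path) -> pd.DataFrame:
    """Read a life table CSV with columns age, sex, qx."""
    try:
        lt = pd.read_csv(path)
    except FileNotFoundError:
        raise EngineError(f"life table file not found: {path}") from None
    missing = {"age", "sex", "qx"} - set(lt.columns)
    if missing:
        raise EngineError(f"life table missing columns: {sorted(missing)}")
    return validate_life_table(lt)


def validate_life_table(lt: pd.DataFrame) -> pd.DataFrame:
    if ((lt["qx"] < 0) | (lt["qx"] > 1)).any():
        raise EngineError("life table qx outside [0,1]")
    sexes = set(lt["sex"].unique())
    if not {"female", "male"} <= sexes:
        raise EngineError("life table must contain both 'female' and 'male' rows")
    for sex in ("female", "male"):
        ages = np.sort(lt.loc[lt["sex"] == sex, "age"].to_numpy())
        if len(ages) and not np.array_equal(ages, np.arange(ages[0], ages[-1] + 1)):
            raise EngineError(f"life table ages not contiguous for sex={sex}")
    return lt


def _qx_lookup(life_table: pd.DataFrame) -> dict[str, dict[int, float]]:
    out: dict[str, dict[int, float]] = {}
    for sex, grp in life_table.groupby("sex"):
        out[sex] = dict(zip(grp["age"].astype(int), grp["qx"].astype(float)))
    return out


def smr_at(smr_bands: dict[str, list[tuple[float, float]]], sex: str, age: float) -> float:
    """Standardized mortality ratio for a sex at an age, from age bands."""
    bands = smr_bands[sex]
    smr = bands[0][1]
    for age_lo, value in bands:
        if age >= age_lo:
            smr = value
    return smr


def smr_bands_from_params(params) -> dict[str, list[tuple[float, float]]]:
    """Assemble the sex x age-band SMR map from ledger values."""
    return {
        "female": [(0.0, params["smr_female_under40"]), (40.0, params["smr_female_40plus"])],
        "male": [(0.0, params["smr_male_under40"]), (40.0, params["smr_male_40plus"])],
    }


def annual_to_cycle_prob(p_annual: float, cycles_per_year: int) -> float:
    """Constant-hazard conversion 1 - (1-p)^(1/k) of an annual probability."""
    if not 0.0 <= p_annual <= 1.0:
        raise EngineError(f"annual probability outside [0,1]: {p_annual}")
    if cycles_per_year < 1:
        raise EngineError("cycles_per_year must be >= 1")
    return 1.0 - (1.0 - p_annual) ** (1.0 / cycles_per_year)


def apply_odds_ratio(p_base: float, odds_ratio: float) -> float:
    """Shift a probability on the odds scale: p' = OR*odds / (1 + OR*odds)."""
    if odds_ratio <= 0:
        raise EngineError(f"odds ratio must be positive, got {odds_ratio}")
    if odds_ratio == 1.0 or p_base <= 0.0 or p_base >= 1.0:
        # exact identity: the unit OR must not perturb the last bit, so the
        # two arms coincide bitwise when their parameters coincide
        return p_base
    odds = odds_ratio * p_base / (1.0 - p_base)
    return odds / (1.0 + odds)


def cycle_death_prob(life_table: pd.DataFrame | dict, smr_bands: dict,
                     age0: float, sex_mix: float, cycle: int,
                     cycles_per_year: int = 12) -> float:
    """Monthly death probability at a given cycle.

    Looks up the whole-year age, inflates each sex's annual hazard
    -ln(1-qx) by its SMR, blends the two hazards by the cohort's female
    fraction, and converts the blended annual probability to one cycle.
    """
    lookup = life_table if isinstance(life_table, dict) else _qx_lookup(life_table)
    age = int(math.floor(age0 + cycle / cycles_per_year))
    rates = {}
    for sex in ("female", "male"):
        try:
            qx = lookup[sex][age]
        except KeyError:
            raise EngineError(
                f"life table does not cover age {age} for sex={sex}; "
                "extend the table to cover the analytic horizon") from None
        smr = smr_at(smr_bands, sex, age)
        if smr <= 0:
            raise EngineError("SMR values must be positive")
        rates[sex] = -math.log(max(1.0 - qx, 1e-300)) * smr
    blended = sex_mix * rates["female"] + (1.0 - sex_mix) * rates["male"]
    p_annual = 1.0 - math.exp(-blended)
    return annual_to_cycle_prob(p_annual, cycles_per_year)


# ---------------------------------------------------------------------------
# transition matrices

def _induction_split(params, strategy: StrategyConfig, year: float
                     ) -> tuple[float, float, float]:
    """(complete, partial, non) response probabilities at induction exit.

    The early arm's complete-response probability is lifted on the odds
    scale; the partial probability is rescaled to preserve the partial:non
    ratio among non-complete responders.
    """
    p_cr = params.at("p_response_complete", year)
    p_pr = params.at("p_response_partial", year)
    if p_cr + p_pr > 1.0 + 1e-12:
        raise EngineError("induction response probabilities sum above 1 "
                          "(row pretreatment)")
    if strategy.response_or_applied:
        odds_ratio = params.at("or_sri4_early", year)
        p_cr_adj = apply_odds_ratio(p_cr, odds_ratio)
        scale = (1.0 - p_cr_adj) / (1.0 - p_cr) if p_cr < 1.0 else 0.0
        p_pr_adj = p_pr * scale
    else:
        p_cr_adj, p_pr_adj = p_cr, p_pr
    return p_cr_adj, p_pr_adj, 1.0 - p_cr_adj - p_pr_adj


def build_transition_matrix(params, strategy: StrategyConfig, cycle: int,
                            p_death: float) -> TransitionMatrix:
    """Transition matrix governing the move from `cycle` to `cycle + 1`.

    Death is applied first from every living row; the disease transitions
    receive the remaining 1 - p_death mass.
    """
    if not 0.0 <= p_death <= 1.0:
        raise EngineError(f"p_death outside [0,1]: {p_death}")
    year = cycle / 12.0
    ind = strategy.induction_cycles
    d = np.zeros((N_SUBSTATES, N_SUBSTATES))

    p_cr, p_pr, p_nr = _induction_split(params, strategy, year)

    # pretreatment on first biologic: hold during induction, full split at
    # the boundary, geometric re-induction (mean = induction length) for
    # later restarts
    if cycle < ind - 1:
        d[PRE_BEL, PRE_BEL] = 1.0
    elif cycle == ind - 1:
        d[PRE_BEL, [CR_BEL, PR_BEL, NR_BEL]] = (p_cr, p_pr, p_nr)
    else:
        exit_p = 1.0 / ind
        d[PRE_BEL, [CR_BEL, PR_BEL, NR_BEL]] = (
            exit_p * p_cr, exit_p * p_pr, exit_p * p_nr)
        d[PRE_BEL, PRE_BEL] = 1.0 - exit_p

    def _stepwise(cr, pr, nr, pre_restart, disc_stop, disc_switch, disc_restart):
        p_cr_pr = params.at("p_cr_to_pr", year)
        p_pr_cr = params.at("p_pr_to_cr", year)
        p_pr_nr = params.at("p_pr_to_nr", year)
        p_nr_pr = params.at("p_nr_to_pr", year)
        d[cr, pr] = p_cr_pr
        d[cr, cr] = 1.0 - p_cr_pr
        if p_pr_cr + p_pr_nr > 1.0 + 1e-12:
            raise EngineError("partial-response exits sum above 1 (row partial_response)")
        d[pr, cr] = p_pr_cr
        d[pr, nr] = p_pr_nr
        d[pr, pr] = 1.0 - p_pr_cr - p_pr_nr
        total_disc = disc_stop + disc_switch + disc_restart
        if p_nr_pr + total_disc > 1.0 + 1e-12:
            raise EngineError("nonresponse exits sum above 1 (row nonresponse)")
        d[nr, pr] = p_nr_pr
        d[nr, NO_TX] += disc_stop
        if disc_switch:
            d[nr, PRE_ANI] += disc_switch
        if disc_restart:
            d[nr, pre_restart] += disc_restart
        d[nr, nr] = 1.0 - p_nr_pr - total_disc

    # belimumab context: nonresponders may restart, stop, or switch.
    # frac_disc_switch is conditional on not stopping, so any pair of
    # fractions in [0,1] yields a valid three-way split.
    p_disc = params.at("p_discontinue", year)
    f_stop = params.at("frac_disc_stop", year)
    f_switch = (1.0 - f_stop) * params.at("frac_disc_switch", year)
    f_restart = 1.0 - f_stop - f_switch
    _stepwise(CR_BEL, PR_BEL, NR_BEL, PRE_BEL,
              p_disc * f_stop, p_disc * f_switch, p_disc * f_restart)

    # anifrolumab context: discontinuation leads off treatment only
    p_disc_ani = params.at("p_ani_discontinue", year)
    _stepwise(CR_ANI, PR_ANI, NR_ANI, PRE_ANI, p_disc_ani, 0.0, 0.0)

    # anifrolumab induction: geometric exit into TULIP-derived split,
    # attenuated for biologic-experienced patients
    p_ani_cr = params.at("p_ani_response_complete", year)
    p_ani_pr = params.at("p_ani_response_partial", year)
    if p_ani_cr + p_ani_pr > 1.0 + 1e-12:
        raise EngineError("anifrolumab response probabilities sum above 1 "
                          "(row pretreatment/anifrolumab)")
    exit_p = 1.0 / ind
    d[PRE_ANI, [CR_ANI, PR_ANI, NR_ANI]] = (
        exit_p * p_ani_cr, exit_p * p_ani_pr, exit_p * (1.0 - p_ani_cr - p_ani_pr))
    d[PRE_ANI, PRE_ANI] = 1.0 - exit_p

    # off treatment: severe flare triggers anifrolumab initiation
    p_flare = params.at("p_flare_off_treatment", year)
    d[NO_TX, PRE_ANI] = p_flare
    d[NO_TX, NO_TX] = 1.0 - p_flare

    # death applied first; remaining mass follows disease transitions
    m = (1.0 - p_death) * d
    m[:, DEATH] += p_death
    m[DEATH, :] = 0.0
    m[DEATH, DEATH] = 1.0
    return TransitionMatrix(m, cycle_index=cycle)


def run_cohort(strategy: StrategyConfig, params, settings, life_table) -> CohortTrace:
    """Propagate the full cohort through the model over the analytic horizon.

    Matrices are piecewise-constant over (whole-year age, profile year,
    induction phase), so only a handful of distinct matrices are built per
    run; each is validated once.
    """
    cycles = settings.n_cycles
    if cycles and cycles < strategy.induction_cycles:
        raise EngineError("horizon shorter than the induction period")
    lookup = life_table if isinstance(life_table, dict) else _qx_lookup(life_table)
    smr_bands = smr_bands_from_params(params)

    occ = np.zeros((cycles + 1, N_SUBSTATES))
    occ[0, PRE_BEL] = 1.0
    cache: dict[tuple, np.ndarray] = {}
    ind = strategy.induction_cycles
    for t in range(cycles):
        phase = 0 if t < ind - 1 else (1 if t == ind - 1 else 2)
        age_year = int(math.floor(settings.start_age + t / settings.cycles_per_year))
        key = (age_year, t // 12, phase)
        m = cache.get(key)
        if m is None:
            p_death = cycle_death_prob(lookup, smr_bands, settings.start_age,
                                       settings.female_fraction, t,
                                       settings.cycles_per_year)
            m = build_transition_matrix(params, strategy, t, p_death).probs
            cache[key] = m
        occ[t + 1] = occ[t] @ m
    return CohortTrace(occ, strategy.label)
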