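"""Glue layer: run both strategies on one parameter set and compare them.

The two arms share every parameter value; they differ only through the
strategy configuration (whether the early-initiation SRI-4 odds ratio is
applied) and the early arm's baseline prednisone offset.  This paired design
is what probabilistic and deterministic sensitivity analyses propagate.
"""

from __future__ import annotations

from typing import Callable

from . import economics
from .engine import DELAYED, EARLY, ENGINE_PARAMETERS, StrategyConfig, run_cohort
from .outcomes import OUTCOME_PARAMETERS, StrategyResult, accumulate, models_from_params

#: every ledger name the full pipeline reads; validate_ledger's required set
REQUIRED_PARAMETERS = frozenset(
    ENGINE_PARAMETERS | OUTCOME_PARAMETERS
    | {"discount_rate_annual", "wtp_per_qaly"}
)


def default_strategies(settings) -> tuple[StrategyConfig, StrategyConfig]:
    """Early and delayed configs with the settings' induction length."""
    early = StrategyConfig(label=EARLY.label, induction_cycles=settings.induction_cycles,
                           response_or_applied=True)
    delayed = StrategyConfig(label=DELAYED.label, induction_cycles=settings.induction_cycles,
                             response_or_applied=False)
    return early, delayed


def evaluate_strategy(strategy: StrategyConfig, params, settings, life_table,
                      wac_multiplier: Callable[[int], float] | None = None,
                      audit: bool = False) -> StrategyResult:
    """One full cohort run plus discounted accumulation."""
    trace = run_cohort(strategy, params, settings, life_table)
    um, cm, steroid = models_from_params(params, wac_multiplier)
    result = accumulate(trace, um, cm, steroid, settings, audit=audit)
    return result


def evaluate_comparison(params, settings, life_table,
                        strategies: tuple[StrategyConfig, StrategyConfig] | None = None,
                        wac_multiplier: Callable[[int], float] | None = None,
                        audit: bool = False
                        ) -> tuple[StrategyResult, StrategyResult, economics.CEComparison]:
    """(early result, delayed result, incremental comparison)."""
    early_cfg, delayed_cfg = strategies or default_strategies(settings)
    res_early = evaluate_strategy(early_cfg, params, settings, life_table,
                                  wac_multiplier, audit)
    res_delayed = evaluate_strategy(delayed_cfg, params, settings, life_table,
                                    wac_multiplier, audit)
    ce = economics.compare(res_early.cost_discounted, res_early.qaly_discounted,
                           res_delayed.cost_discounted, res_delayed.qaly_discounted,
                           settings.wtp)
    return res_early, res_delayed, ce
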