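"""Deterministic sensitivity analyses: tornado, horizon sweep, pricing scenarios.

One-way analysis re-runs the full deterministic model with a single
parameter at its low/high bound (published range, or ±30% when none is
available) and reports the incremental net monetary benefit at the settings'
willingness-to-pay.  Two settings-level drivers the published tornado also
varies — the discount rate and the time horizon — are handled as special
parameter names mapped onto the analysis settings.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import pandas as pd

from .economics import CEComparison
from .parameters import ParameterLedger
from .pipeline import evaluate_comparison

#: one_way names routed to AnalysisSettings instead of the ledger
SETTINGS_PARAMETERS = {"discount_rate_annual": "discount_rate",
                       "horizon_years": "horizon_years"}
HORIZON_DSA_BOUNDS = (1.0, 25.0)


class SensitivityError(ValueError):
    pass


@dataclass(frozen=True)
class TornadoEntry:
    parameter: str
    low_setting: float
    high_setting: float
    low_inmb: float
    high_inmb: float

    @property
    def width(self) -> float:
        return abs(self.high_inmb - self.low_inmb)


@dataclass(frozen=True)
class ScenarioSpec:
    """A named what-if run: WAC multiplier path and/or horizon override.

    ``wac_multiplier`` scales the acquisition cost of both biologics in both
    arms from ``start_year`` onward (1.0 before); efficacy parameters are
    never touched.
    """

    scenario_id: str
    description: str = ""
    wac_multiplier: float = 1.0
    start_year: float = 0.0
    horizon_years: float | None = None

    def __post_init__(self) -> None:
        if not 0.0 < self.wac_multiplier <= 1.0:
            raise SensitivityError("WAC multiplier must be in (0, 1]")

    def schedule(self, cycles_per_year: int = 12):
        start_cycle = self.start_year * cycles_per_year
        mult = self.wac_multiplier
        return lambda cycle: mult if cycle >= start_cycle else 1.0


def _inmb_at(ledger: ParameterLedger, settings, life_table, strategies) -> float:
    _, _, ce = evaluate_comparison(ledger.base_parameter_set(), settings,
                                   life_table, strategies)
    return ce.inmb


def one_way(ledger: ParameterLedger, parameter: str, strategies, settings,
            life_table, low: float | None = None, high: float | None = None
            ) -> TornadoEntry:
    """Two full deterministic runs with one parameter at its bounds."""
    if parameter in SETTINGS_PARAMETERS:
        attr = SETTINGS_PARAMETERS[parameter]
        if low is None or high is None:
            if parameter in ledger:
                spec = ledger[parameter]
                low = spec.low if low is None else low
                high = spec.high if high is None else high
            elif parameter == "horizon_years":
                low, high = HORIZON_DSA_BOUNDS
            else:
                raise SensitivityError(f"no bounds available for {parameter!r}")
        inmb_lo = _inmb_at(ledger, replace(settings, **{attr: low}),
                           life_table, strategies)
        inmb_hi = _inmb_at(ledger, replace(settings, **{attr: high}),
                           life_table, strategies)
        return TornadoEntry(parameter, low, high, inmb_lo, inmb_hi)
    if parameter not in ledger:
        raise SensitivityError(f"unknown parameter {parameter!r}")
    spec = ledger[parameter]
    low = spec.low if low is None else low
    high = spec.high if high is None else high
    inmb_lo = _inmb_at(ledger.with_values({parameter: low}), settings,
                       life_table, strategies)
    inmb_hi = _inmb_at(ledger.with_values({parameter: high}), settings,
                       life_table, strategies)
    return TornadoEntry(parameter, low, high, inmb_lo, inmb_hi)


def tornado(entries) -> list[TornadoEntry]:
    """Entries sorted by descending bar width, name-stable on ties."""
    entries = list(entries)
    if not entries:
        raise SensitivityError("tornado needs at least one entry")
    return sorted(entries, key=lambda e: (-e.width, e.parameter))


def tornado_frame(entries) -> pd.DataFrame:
    return pd.DataFrame([{"parameter": e.parameter,
                          "low_setting": e.low_setting,
                          "high_setting": e.high_setting,
                          "low_inmb": e.low_inmb,
                          "high_inmb": e.high_inmb,
                          "width": e.width} for e in entries])


def tornado_report(ledger: ParameterLedger, strategies, settings, life_table,
                   parameters=None, include_horizon: bool = True
                   ) -> list[TornadoEntry]:
    """One-way runs over every ledger parameter with a non-degenerate range."""
    names = list(parameters) if parameters is not None else [
        n for n, s in ledger.specs.items() if s.low < s.high]
    entries = [one_way(ledger, n, strategies, settings, life_table) for n in names]
    if include_horizon and "horizon_years" not in names:
        entries.append(one_way(ledger, "horizon_years", strategies, settings,
                               life_table))
    return tornado(entries)


def horizon_sweep(ledger: ParameterLedger, strategies, settings, life_table,
                  years) -> pd.DataFrame:
    """INMB per analytic horizon, each with its own discounted totals."""
    if any(y < 1 for y in years):
        raise SensitivityError("horizons must be >= 1 year")
    rows = []
    base = ledger.base_parameter_set()
    for y in years:
        s = replace(settings, horizon_years=float(y))
        _, _, ce = evaluate_comparison(base, s, life_table, strategies)
        rows.append({"horizon_years": float(y), "inmb": ce.inmb,
                     "delta_cost": ce.delta_cost, "delta_qaly": ce.delta_qaly})
    return pd.DataFrame(rows)


def biosimilar_scenario(ledger: ParameterLedger, spec: ScenarioSpec,
                        strategies, settings, life_table) -> CEComparison:
    """Full deterministic run with the scenario's WAC discount schedule.

    Only drug-acquisition unit costs change; every efficacy, utility, and
    secondary-cost parameter is untouched.
    """
    s = settings if spec.horizon_years is None else replace(
        settings, horizon_years=spec.horizon_years)
    _, _, ce = evaluate_comparison(ledger.base_parameter_set(), s, life_table,
                                   strategies,
                                   wac_multiplier=spec.schedule(s.cycles_per_year))
    return ce


def default_scenarios(ledger: ParameterLedger, start_age: float = 41.0,
                      life_table_max_age: float = 100.0) -> list[ScenarioSpec]:
    """The published scenario set: lifetime horizon, biosimilar entry at
    years 1 and 5 (synthetic price-erosion multiplier), and 15%/60%
    biosimilar substitution discounts."""
    disc15 = ledger["biosimilar_discount_moderate"].base_value if \
        "biosimilar_discount_moderate" in ledger else 0.15
    disc60 = ledger["biosimilar_discount_deep"].base_value if \
        "biosimilar_discount_deep" in ledger else 0.60
    erosion = ledger["biosimilar_erosion_multiplier"].base_value if \
        "biosimilar_erosion_multiplier" in ledger else 0.75
    lifetime = life_table_max_age - start_age
    return [
        ScenarioSpec("lifetime_horizon", "run to cohort extinction (age cap)",
                     horizon_years=lifetime),
        ScenarioSpec("biosimilar_entry_year1",
                     "originator WAC erosion from year 1",
                     wac_multiplier=erosion, start_year=1.0),
        ScenarioSpec("biosimilar_entry_year5",
                     "originator WAC erosion from year 5",
                     wac_multiplier=erosion, start_year=5.0),
        ScenarioSpec("biosimilar_sub_15", "15% WAC discount, equal efficacy",
                     wac_multiplier=1.0 - disc15),
        ScenarioSpec("biosimilar_sub_60", "60% WAC discount, equal efficacy",
                     wac_multiplier=1.0 - disc60),
    ]
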