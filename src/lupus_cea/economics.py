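"""Incremental cost-effectiveness summaries for the two-strategy comparison.

Conventions: increments are early minus delayed.  A negative ICER is
reported numerically as printed in cost-utility tables but is not compared
with a willingness-to-pay threshold; decision rules use the incremental net
monetary benefit, INMB = dQALY * WTP - dCost.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np


@dataclass(frozen=True)
class CEComparison:
    """Incremental economics of early vs delayed initiation."""

    delta_cost: float
    delta_qaly: float
    icer: float  # nan when delta_qaly == 0
    inmb: float
    dominance: str  # dominant | dominated | tradeoff_ne | tradeoff_sw
    wtp: float

    @property
    def icer_defined(self) -> bool:
        return not math.isnan(self.icer)

    def as_dict(self) -> dict:
        return {"delta_cost": self.delta_cost, "delta_qaly": self.delta_qaly,
                "icer": None if not self.icer_defined else self.icer,
                "inmb": self.inmb, "dominance": self.dominance, "wtp": self.wtp}


@dataclass
class CEAC:
    """Cost-effectiveness acceptability curve over a WTP grid."""

    wtp_grid: np.ndarray
    p_early: np.ndarray
    p_delayed: np.ndarray

    def to_frame(self):
        import pandas as pd
        return pd.DataFrame({"wtp": self.wtp_grid, "p_early": self.p_early,
                             "p_delayed": self.p_delayed})


def icer(cost_early: float, qaly_early: float,
         cost_delayed: float, qaly_delayed: float) -> float:
    """Incremental cost-effectiveness ratio (early - delayed) / (early - delayed).

    Returns nan when the QALY increment is zero (undefined ratio); negative
    values are returned as-is and interpreted via the dominance label.
    """
    dq = qaly_early - qaly_delayed
    if dq == 0.0:
        return math.nan
    return (cost_early - cost_delayed) / dq


def inmb(delta_qaly: float, delta_cost: float, wtp: float) -> float:
    """Incremental net monetary benefit dQALY*WTP - dCost."""
    if wtp < 0:
        raise ValueError("willingness-to-pay must be non-negative")
    return delta_qaly * wtp - delta_cost


def classify_quadrant(delta_cost: float, delta_qaly: float) -> str:
    """Cost-effectiveness plane quadrant of an increment pair.

    NE (+cost, +qaly), SE (-cost, +qaly), SW (-cost, -qaly), NW (+cost, -qaly).
    Boundary convention: zero increments resolve to the positive-QALY side,
    and the double-zero origin to SE.
    """
    if delta_qaly >= 0.0:
        return "SE" if delta_cost <= 0.0 else "NE"
    return "SW" if delta_cost <= 0.0 else "NW"


def dominance_label(delta_cost: float, delta_qaly: float) -> str:
    if delta_cost < 0.0 and delta_qaly > 0.0:
        return "dominant"
    if delta_cost > 0.0 and delta_qaly < 0.0:
        return "dominated"
    return "tradeoff_ne" if delta_qaly >= 0.0 else "tradeoff_sw"


def compare(cost_early: float, qaly_early: float, cost_delayed: float,
            qaly_delayed: float, wtp: float) -> CEComparison:
    """Full incremental summary for one deterministic model evaluation."""
    dc = cost_early - cost_delayed
    dq = qaly_early - qaly_delayed
    return CEComparison(
        delta_cost=dc, delta_qaly=dq,
        icer=icer(cost_early, qaly_early, cost_delayed, qaly_delayed),
        inmb=inmb(dq, dc, wtp),
        dominance=dominance_label(dc, dq),
        wtp=wtp,
    )


def ceac_from_draws(delta_cost, delta_qaly, wtp_grid) -> CEAC:
    """Probability each strategy maximizes NMB at each WTP.

    Early is optimal when its INMB is positive; exact ties (a measure-zero
    event) are split evenly between the strategies.
    """
    dc = np.asarray(delta_cost, dtype=float)
    dq = np.asarray(delta_qaly, dtype=float)
    grid = np.asarray(wtp_grid, dtype=float)
    if dc.size == 0:
        raise ValueError("ceac_from_draws needs at least one draw")
    if grid.size == 0:
        raise ValueError("ceac_from_draws needs a non-empty WTP grid")
    nmb = dq[None, :] * grid[:, None] - dc[None, :]
    p_early = (nmb > 0).mean(axis=1) + 0.5 * (nmb == 0).mean(axis=1)
    return CEAC(grid, p_early, 1.0 - p_early)
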