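"""Probabilistic sensitivity analysis: Monte Carlo propagation of the ledger.

Each simulation draws one parameter set from the ledger's prespecified
distributions and applies it to *both* strategies (common random parameters:
the arms differ only through stated effect parameters, so independent draws
would inflate incremental variance).  Uncertainty intervals are the 2.5th
and 97.5th empirical percentiles of the draw distribution.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import economics
from .parameters import ParameterLedger, draw_parameter_set
from .pipeline import evaluate_comparison

DEFAULT_WTP_GRID = tuple(range(0, 200_001, 5_000))


def percentile_interval(values, lo_pct: float = 2.5, hi_pct: float = 97.5
                        ) -> tuple[float, float]:
    """Empirical percentile interval, linear interpolation between order
    statistics (position (n-1)*q, the numpy 'linear' definition)."""
    arr = np.asarray(values, dtype=float)
    if arr.size == 0:
        raise ValueError("percentile_interval needs a non-empty sample")
    lo, hi = np.percentile(arr, [lo_pct, hi_pct], method="linear")
    return float(lo), float(hi)


@dataclass
class PSAResult:
    n_sims: int
    seed: int
    delta_cost: np.ndarray
    delta_qaly: np.ndarray
    inmb: np.ndarray
    wtp: float
    mean_delta_cost: float = 0.0
    mean_delta_qaly: float = 0.0
    mean_inmb: float = 0.0
    ui_delta_cost: tuple[float, float] = (0.0, 0.0)
    ui_delta_qaly: tuple[float, float] = (0.0, 0.0)
    ui_inmb: tuple[float, float] = (0.0, 0.0)
    quadrant_proportions: dict[str, float] = field(default_factory=dict)
    p_early_favored: float = 0.0
    p_delayed_favored: float = 0.0
    ceac: economics.CEAC | None = None
    n_clipped_draws: int = 0

    def draws_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"draw": np.arange(self.n_sims),
                             "delta_cost": self.delta_cost,
                             "delta_qaly": self.delta_qaly,
                             "inmb": self.inmb})

    def summary(self) -> dict:
        return {
            "n_sims": self.n_sims, "seed": self.seed, "wtp": self.wtp,
            "mean_delta_cost": self.mean_delta_cost,
            "mean_delta_qaly": self.mean_delta_qaly,
            "mean_inmb": self.mean_inmb,
            "ui_delta_cost": list(self.ui_delta_cost),
            "ui_delta_qaly": list(self.ui_delta_qaly),
            "ui_inmb": list(self.ui_inmb),
            "quadrant_proportions": self.quadrant_proportions,
            "p_early_favored": self.p_early_favored,
            "p_delayed_favored": self.p_delayed_favored,
            "n_clipped_draws": self.n_clipped_draws,
        }


def run_psa(ledger: ParameterLedger, strategies, settings, life_table,
            n_sims: int | None = None, seed: int | None = None,
            wtp_grid=DEFAULT_WTP_GRID) -> PSAResult:
    """Monte Carlo PSA with one shared parameter draw per simulation.

    A master :class:`numpy.random.SeedSequence` spawns one substream per
    draw, so results are reproducible and independent of evaluation order.
    """
    n = settings.n_sims if n_sims is None else int(n_sims)
    if n < 1:
        raise ValueError("n_sims must be >= 1")
    master_seed = settings.seed if seed is None else int(seed)
    streams = np.random.SeedSequence(master_seed).spawn(n)

    dc = np.empty(n)
    dq = np.empty(n)
    nmb = np.empty(n)
    n_clipped = 0
    for i, stream in enumerate(streams):
        rng = np.random.default_rng(stream)
        try:
            pset = draw_parameter_set(ledger, rng, draw_index=i)
            _, _, ce = evaluate_comparison(pset, settings, life_table, strategies)
        except Exception as exc:
            raise RuntimeError(f"PSA draw {i} failed: {exc}") from exc
        n_clipped += pset.n_clipped
        dc[i], dq[i], nmb[i] = ce.delta_cost, ce.delta_qaly, ce.inmb

    quadrants = [economics.classify_quadrant(c, q) for c, q in zip(dc, dq)]
    props = {q: quadrants.count(q) / n for q in ("NE", "SE", "SW", "NW")}
    p_early = float((nmb > 0).mean() + 0.5 * (nmb == 0).mean())
    return PSAResult(
        n_sims=n, seed=master_seed,
        delta_cost=dc, delta_qaly=dq, inmb=nmb, wtp=settings.wtp,
        mean_delta_cost=float(dc.mean()),
        mean_delta_qaly=float(dq.mean()),
        mean_inmb=float(nmb.mean()),
        ui_delta_cost=percentile_interval(dc),
        ui_delta_qaly=percentile_interval(dq),
        ui_inmb=percentile_interval(nmb),
        quadrant_proportions=props,
        p_early_favored=p_early,
        p_delayed_favored=1.0 - p_early,
        ceac=economics.ceac_from_draws(dc, dq, np.asarray(wtp_grid, dtype=float)),
        n_clipped_draws=n_clipped,
    )
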