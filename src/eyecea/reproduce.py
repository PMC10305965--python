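"""Recompute the study's headline results from its published raw cells.

Every function here runs the package's own pipeline operations on the
published inputs (category costs, screening volumes, per-100,000 treatment
rates, strategy-level totals) and returns the derived quantity the study
prints: table totals and per-person costs, the efficient frontier with its
ICERs, DALY and spectacle reconstructions, the teleophthalmology increment
and break-even counts, and the national budget extrapolation.
"""

from __future__ import annotations

from . import study_data as sd
from .cea_frontier import FrontierRow, icer_frontier
from .config import DalyParams
from .costing import (
    Basis,
    CftiCost,
    NormalizedCosts,
    tele_breakeven,
    tele_increment,
)
from .daly_model import total_dalys
from .data_model import Category, CostLine, Money, Strategy
from .reporting import budget_extrapolation


def _lines(strategy: Strategy, costs, provider: str = "pooled") -> list[CostLine]:
    return [CostLine(strategy=strategy, provider=provider,
                     raw_category=cat.value, category=cat,
                     amount=Money(value=float(v)))
            for cat, v in costs.items()]


def table1_totals() -> dict[Strategy, float]:
    """Category sums per 100,000 screened, per strategy."""
    out = {}
    for strat, costs in sd.COSTS_PER_100K.items():
        norm = NormalizedCosts(strategy=strat, basis=Basis.per_100k_screened,
                               by_category=dict(costs))
        out[strat] = norm.total
    return out


def cost_per_person(strategy: Strategy) -> float:
    """Cost per person screened, one-decimal convention."""
    return round(table1_totals()[strategy] / 100_000.0, 1)


def vision_center_facility_total() -> float:
    """Annual per-facility vision-center cost (sum of the four categories)."""
    return sum(sd.VISION_CENTER_PER_FACILITY.values())


def teleophthalmology_increment() -> float:
    """Incremental annualized teleophthalmology cost per facility."""
    lines = _lines(Strategy.teleophthalmology, sd.TELE_PER_FACILITY)
    return tele_increment(lines)


def teleophthalmology_breakeven(split: float = 0.5) -> dict[str, int]:
    """Additional treatments needed to match eye camps' per-case costs."""
    camps_ure = sd.CFTI_URE[Strategy.eye_camps][0]
    camps_cat = sd.CFTI_CATARACT[Strategy.eye_camps][0]
    target = CftiCost(strategy=Strategy.eye_camps,
                      cost_per_spectacle_initiated=camps_ure,
                      cost_per_surgery_initiated=camps_cat)
    return tele_breakeven(teleophthalmology_increment(), target, split)


def frontier() -> list[FrontierRow]:
    """Efficient frontier over the published societal costs and DALYs."""
    return icer_frontier(sd.CEA_OUTCOMES)


def frontier_summary() -> dict[str, object]:
    rows = {r.strategy: r for r in frontier()}
    camps = rows["eye_camps"]
    vc = rows["vision_centers"]
    return {
        "weakly_dominated": sorted(s for s, r in rows.items()
                                   if r.status.value == "weakly_dominated"),
        "eye_camps_icer": camps.icer,
        "vision_centers_icer": vc.icer,
        "vision_centers_incremental_cost": vc.incremental_cost,
        "vision_centers_incremental_dalys": vc.incremental_dalys,
    }


def strategy_treatment_counts(strategy: Strategy) -> tuple[float, float]:
    """(spectacles, surgeries) reconstructed from per-100k rates x volume."""
    scale = sd.N_SCREENED[strategy] / 100_000.0
    spectacles = sd.SPECTACLES_PER_100K[strategy] * scale
    surg_rate = sd.SURGERIES_PER_100K[strategy]
    surgeries = (surg_rate or 0.0) * scale
    return spectacles, surgeries


def reconstructed_dalys(strategy: Strategy,
                        params: DalyParams | None = None) -> float:
    """Strategy DALYs averted from reconstructed treatment counts."""
    spectacles, surgeries = strategy_treatment_counts(strategy)
    return total_dalys(spectacles, surgeries, params or DalyParams())


def reconstructed_total_spectacles() -> float:
    """Spectacles dispensed across the four strategies."""
    return sum(strategy_treatment_counts(s)[0] for s in sd.SPECTACLES_PER_100K)


def national_budget() -> dict[str, float]:
    """Annual budget envelope to run the national vision-center target."""
    _, lo, hi = sd.VISION_CENTER_PER_FACILITY_TOTAL
    return budget_extrapolation((lo, hi), sd.NATIONAL_FACILITY_TARGET)
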