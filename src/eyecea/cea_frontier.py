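"""Incremental cost-effectiveness analysis: societal costs, the efficient
frontier with dominance and extended (weak) dominance, ICERs, and net
monetary benefit.

Strategies are compared against a baseline of no intervention (zero cost,
zero DALYs averted). A strategy is *dominated* if another costs no more and
averts at least as many DALYs; it is *extended-dominated* if a blend of two
others does so, which manifests as an ICER inversion along the effectiveness
ordering. ICERs are computed between adjacent members of the surviving
frontier and are strictly increasing by construction.
"""

from __future__ import annotations

import enum
import warnings
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

BASELINE = "baseline"


class FrontierStatus(str, enum.Enum):
    baseline = "baseline"
    on_frontier = "on_frontier"
    dominated = "dominated"
    weakly_dominated = "weakly_dominated"


@dataclass(frozen=True)
class StrategyOutcome:
    """Total societal cost (USD) and total DALYs averted for one strategy."""

    strategy: str
    total_cost: float
    total_dalys: float

    def __post_init__(self):
        if self.total_cost < 0:
            raise ValueError("total cost must be nonnegative")


@dataclass
class FrontierRow:
    strategy: str
    total_cost: float
    total_dalys: float
    status: FrontierStatus
    incremental_cost: Optional[float] = None
    incremental_dalys: Optional[float] = None
    icer: Optional[float] = None


def societal_cost(cfti_total: float, spectacles: float, surgeries: float,
                  spectacle_cost: float, surgery_cost: float,
                  patient_cost_per_surgery: float = 0.0) -> float:
    """Societal cost of a strategy: case-finding-and-treatment-initiation
    costs, plus treatment costs (spectacles and surgeries), plus patient
    costs to access surgical treatment. Purely additive."""
    components = (cfti_total, spectacles, surgeries, spectacle_cost,
                  surgery_cost, patient_cost_per_surgery)
    if any(c < 0 for c in components):
        raise ValueError("all cost components must be nonnegative")
    return (cfti_total
            + spectacles * spectacle_cost
            + surgeries * (surgery_cost + patient_cost_per_surgery))


def nmb(cost: float, dalys: float, lam: float) -> float:
    """Net monetary benefit at willingness-to-pay ``lam`` USD per DALY."""
    if lam < 0:
        raise ValueError("lambda must be nonnegative")
    return lam * dalys - cost


def icer_frontier(outcomes: Iterable[StrategyOutcome],
                  include_baseline: bool = True) -> list[FrontierRow]:
    """Efficient frontier with dominance classification and ICERs.

    Strategies are sorted by DALYs averted; strictly dominated entries
    (another strategy has >= DALYs at lower cost, or > DALYs at equal cost)
    are flagged ``dominated``; extended-dominated entries (removal restores
    strictly increasing ICERs) are flagged ``weakly_dominated``. ICERs are
    incremental between adjacent frontier survivors starting from baseline.

    Exact cost-and-DALY ties are broken lexicographically by strategy name
    (with a warning); the later one is flagged dominated.
    """
    rows = {o.strategy: FrontierRow(o.strategy, o.total_cost, o.total_dalys,
                                    FrontierStatus.on_frontier)
            for o in outcomes}
    if not rows:
        raise ValueError("at least one strategy is required")
    if include_baseline and BASELINE not in rows:
        rows[BASELINE] = FrontierRow(BASELINE, 0.0, 0.0, FrontierStatus.baseline)
    if BASELINE in rows:
        rows[BASELINE].status = FrontierStatus.baseline

    ordered = sorted(rows.values(), key=lambda r: (r.total_dalys, r.total_cost,
                                                   r.strategy))
    for a, b in zip(ordered, ordered[1:]):
        if a.total_dalys == b.total_dalys and a.total_cost == b.total_cost:
            warnings.warn(
                f"strategies {a.strategy!r} and {b.strategy!r} tie in both "
                "cost and DALYs; lexicographic tie-break applied",
                stacklevel=2,
            )

    # strict dominance
    candidates = list(ordered)
    for r in candidates:
        if r.status is FrontierStatus.baseline:
            continue
        for other in candidates:
            if other is r or other.status in (FrontierStatus.dominated,):
                continue
            better_effect = other.total_dalys >= r.total_dalys
            if not better_effect:
                continue
            if (other.total_cost < r.total_cost
                    or (other.total_cost == r.total_cost
                        and other.total_dalys > r.total_dalys)
                    or (other.total_cost == r.total_cost
                        and other.total_dalys == r.total_dalys
                        and other.strategy < r.strategy)):
                r.status = FrontierStatus.dominated
                break

    # extended dominance: drop members until ICERs strictly increase
    def surviving() -> list[FrontierRow]:
        return [r for r in ordered
                if r.status in (FrontierStatus.baseline,
                                FrontierStatus.on_frontier)]

    while True:
        surv = surviving()
        changed = False
        for i in range(1, len(surv) - 1):
            prev, cur, nxt = surv[i - 1], surv[i], surv[i + 1]
            d_prev = cur.total_dalys - prev.total_dalys
            d_next = nxt.total_dalys - cur.total_dalys
            icer_prev = ((cur.total_cost - prev.total_cost) / d_prev
                         if d_prev > 0 else float("inf"))
            icer_next = ((nxt.total_cost - cur.total_cost) / d_next
                         if d_next > 0 else float("inf"))
            if icer_prev >= icer_next:
                cur.status = FrontierStatus.weakly_dominated
                changed = True
                break
        if not changed:
            break

    # ICERs along the surviving frontier
    surv = surviving()
    for prev, cur in zip(surv, surv[1:]):
        cur.incremental_cost = cur.total_cost - prev.total_cost
        cur.incremental_dalys = cur.total_dalys - prev.total_dalys
        cur.icer = (cur.incremental_cost / cur.incremental_dalys
                    if cur.incremental_dalys > 0 else float("inf"))
    return ordered


def frontier_icers(rows: Sequence[FrontierRow]) -> dict[str, float]:
    """Strategy -> ICER for on-frontier members (full precision)."""
    return {r.strategy: r.icer for r in rows
            if r.status is FrontierStatus.on_frontier and r.icer is not None}
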