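"""Pooling, normalization, diagnosis-share apportionment, and per-case
case-finding-and-treatment-initiation (CFTI) costs.

The costing chain is: pool providers within a strategy, normalize pooled
costs to a reporting basis (per 100,000 screened, or per facility), apportion
the total to conditions (URE / cataract / other) by diagnosis shares with
earmarked lines assigned wholly to their tag, then divide the URE share by
spectacles dispensed and the cataract share by surgeries performed. The
resulting CFTI cost per case embeds, by construction, the cost of diagnosing
people who never initiate treatment.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional

from .data_model import (
    TELE_CATEGORIES,
    Category,
    CostLine,
    Diagnoses,
    Earmark,
    Strategy,
    StrategyDataset,
    UnitError,
)


class Basis(str, enum.Enum):
    total = "total"
    per_100k_screened = "per_100k_screened"
    per_facility = "per_facility"


@dataclass(frozen=True)
class NormalizedCosts:
    """Category costs for one strategy on an explicit reporting basis."""

    strategy: Strategy
    basis: Basis
    by_category: dict[Category, float]
    #: earmarked amounts by (category, earmark tag), same basis
    earmarked: dict[tuple[Category, Earmark], float] = field(default_factory=dict)

    @property
    def total(self) -> float:
        return sum(self.by_category.values())


@dataclass(frozen=True)
class ApportionedCosts:
    """Costs split to conditions; conserves the input total exactly."""

    strategy: Strategy
    ure: float
    cataract: float
    other: float

    @property
    def total(self) -> float:
        return self.ure + self.cataract + self.other


@dataclass(frozen=True)
class CftiCost:
    """Per-case case-finding-and-treatment-initiation costs.

    ``None`` marks an undefined cost (zero corresponding treatment count),
    e.g. cataract CFTI for school screening.
    """

    strategy: Strategy
    cost_per_spectacle_initiated: Optional[float]
    cost_per_surgery_initiated: Optional[float]


def pool_strategies(
    datasets: Iterable[StrategyDataset],
) -> dict[Strategy, StrategyDataset]:
    """Pool provider datasets within each strategy.

    Cost lines are concatenated and outcome counts summed; point estimates
    downstream are computed from these pooled data. All amounts must already
    be in one currency (annualized USD).
    """
    datasets = list(datasets)
    currencies = {l.amount.currency for d in datasets for l in d.cost_lines}
    if len(currencies) > 1:
        raise UnitError(f"mixed currencies in pooled cost lines: {sorted(currencies)}")
    pooled: dict[Strategy, StrategyDataset] = {}
    for d in datasets:
        if d.strategy not in pooled:
            pooled[d.strategy] = d.model_copy(deep=True)
            continue
        p = pooled[d.strategy]
        nfac = None
        if p.n_facilities is not None or d.n_facilities is not None:
            nfac = (p.n_facilities or 0.0) + (d.n_facilities or 0.0)
        pooled[d.strategy] = StrategyDataset(
            strategy=p.strategy,
            n_screened=p.n_screened + d.n_screened,
            n_facilities=nfac,
            diagnoses=Diagnoses(
                ure=p.diagnoses.ure + d.diagnoses.ure,
                cataract=p.diagnoses.cataract + d.diagnoses.cataract,
                other=p.diagnoses.other + d.diagnoses.other,
            ),
            spectacles=p.spectacles + d.spectacles,
            surgeries=p.surgeries + d.surgeries,
            cost_lines=p.cost_lines + list(d.cost_lines),
        )
    return pooled


def _category_sums(lines: Iterable[CostLine]):
    by_cat: dict[Category, float] = {}
    earmarked: dict[tuple[Category, Earmark], float] = {}
    for l in lines:
        if l.category is None:
            raise ValueError("cost line without standardized category")
        by_cat[l.category] = by_cat.get(l.category, 0.0) + l.amount.value
        if l.earmark is not Earmark.none:
            key = (l.category, l.earmark)
            earmarked[key] = earmarked.get(key, 0.0) + l.amount.value
    return by_cat, earmarked


def normalize(pooled: StrategyDataset, basis: Basis | str) -> NormalizedCosts:
    """Scale pooled category costs to a reporting basis.

    ``per_100k_screened`` multiplies by 100,000 / n_screened;
    ``per_facility`` divides by the facility count; ``total`` is the
    identity. The category sum always equals the scaled total.
    """
    basis = Basis(basis)
    by_cat, earmarked = _category_sums(pooled.cost_lines)
    if basis is Basis.total:
        factor = 1.0
    elif basis is Basis.per_100k_screened:
        if pooled.n_screened <= 0:
            raise ValueError("per-100k normalization requires n_screened > 0")
        factor = 100_000.0 / pooled.n_screened
    else:
        if not pooled.n_facilities:
            raise ValueError("per-facility normalization requires n_facilities > 0")
        factor = 1.0 / pooled.n_facilities
    return NormalizedCosts(
        strategy=pooled.strategy,
        basis=basis,
        by_category={c: v * factor for c, v in by_cat.items()},
        earmarked={k: v * factor for k, v in earmarked.items()},
    )


def apportion(
    costs: NormalizedCosts | float,
    diagnoses: Diagnoses | Mapping[str, float],
    earmarked: Optional[Mapping[str, float]] = None,
    strategy: Strategy = Strategy.vision_centers,
) -> ApportionedCosts:
    """Split costs to URE / cataract / other.

    Earmarked amounts are assigned wholly to their tag; the residual pool is
    split in proportion to diagnosis counts. Conservation is exact:
    ``ure + cataract + other == total``.

    ``costs`` may be a :class:`NormalizedCosts` (its embedded earmark amounts
    are used) or a bare total with an explicit ``earmarked`` mapping
    ``{"ure": x, "cataract": y, "other": z}``.
    """
    if isinstance(costs, NormalizedCosts):
        total = costs.total
        strategy = costs.strategy
        tags: dict[str, float] = {}
        for (_, tag), amt in costs.earmarked.items():
            tags[tag.value] = tags.get(tag.value, 0.0) + amt
    else:
        total = float(costs)
        tags = dict(earmarked or {})
    if isinstance(diagnoses, Mapping):
        diagnoses = Diagnoses(**diagnoses)

    ear = {k: tags.get(k, 0.0) for k in ("ure", "cataract", "other")}
    ear_total = sum(ear.values())
    if ear_total > total + 1e-9 * max(1.0, total):
        raise ValueError(
            f"earmarked amounts ({ear_total}) exceed total cost ({total})"
        )
    residual = total - ear_total
    dx_total = diagnoses.total
    if dx_total <= 0:
        if residual > 0:
            raise ValueError("cannot apportion residual cost with zero diagnoses")
        shares = {"ure": 0.0, "cataract": 0.0, "other": 0.0}
    else:
        shares = {
            "ure": diagnoses.ure / dx_total,
            "cataract": diagnoses.cataract / dx_total,
            "other": diagnoses.other / dx_total,
        }
    parts = {k: ear[k] + residual * shares[k] for k in ear}
    _force_exact_conservation(parts, total)
    return ApportionedCosts(strategy=strategy, ure=parts["ure"],
                            cataract=parts["cataract"], other=parts["other"])


def _force_exact_conservation(parts: dict[str, float], total: float) -> None:
    """Nudge the split so ``(ure + cataract) + other == total`` bit-exactly.

    A single additive correction on the largest component almost always
    suffices; the fallback walks components one ulp at a time (largest
    first), falling through to the next component when round-half-even makes
    the target unreachable (the sum jumps over ``total`` by one ulp).
    """

    def current() -> float:
        return (parts["ure"] + parts["cataract"]) + parts["other"]

    order = sorted(parts, key=lambda k: parts[k], reverse=True)
    drift = total - current()
    if drift != 0.0 and parts[order[0]] + drift >= 0:
        parts[order[0]] += drift
    for key in order:
        flips = 0
        last_sign = None
        for _ in range(128):
            drift = total - current()
            if drift == 0.0:
                return
            sign = drift > 0
            if last_sign is not None and sign != last_sign:
                flips += 1
                if flips >= 2:  # oscillating around an unreachable target
                    break
            last_sign = sign
            nxt = math.nextafter(parts[key],
                                 math.inf if sign else -math.inf)
            if nxt < 0:
                break
            parts[key] = nxt


def cfti_cost(apportioned: ApportionedCosts, spectacles: float,
              surgeries: float) -> CftiCost:
    """Per-case CFTI costs: condition cost divided by treatments initiated.

    A zero treatment count yields an undefined (``None``) per-case cost
    rather than an exception — e.g. school screening performs no cataract
    surgeries.
    """
    ure = apportioned.ure / spectacles if spectacles > 0 else None
    cat = apportioned.cataract / surgeries if surgeries > 0 else None
    return CftiCost(strategy=apportioned.strategy,
                    cost_per_spectacle_initiated=ure,
                    cost_per_surgery_initiated=cat)


def strategy_cfti(pooled: StrategyDataset,
                  basis: Basis | str = Basis.total) -> CftiCost:
    """Convenience: normalize -> apportion -> CFTI for one pooled strategy.

    CFTI per-case costs are basis-invariant when costs and treatment counts
    are expressed on the same basis; here both are taken on the given basis.
    """
    basis = Basis(basis)
    norm = normalize(pooled, basis)
    app = apportion(norm, pooled.diagnoses)
    if basis is Basis.per_100k_screened:
        factor = 100_000.0 / pooled.n_screened
    elif basis is Basis.per_facility:
        factor = 1.0 / pooled.n_facilities
    else:
        factor = 1.0
    return cfti_cost(app, pooled.spectacles * factor, pooled.surgeries * factor)


# ---------------------------------------------------------------------------
# Teleophthalmology incremental costing and break-even
# ---------------------------------------------------------------------------

def tele_increment(lines: Iterable[CostLine],
                   n_facilities: float = 1.0) -> float:
    """Incremental annualized teleophthalmology cost per facility.

    Sums the planning/training, IT, remote-doctor salary and internet lines;
    any non-tele category present is a validation error.
    """
    lines = list(lines)
    bad = sorted({l.category.value for l in lines
                  if l.category not in TELE_CATEGORIES})
    if bad:
        raise ValueError(f"non-teleophthalmology categories present: {bad}")
    if n_facilities <= 0:
        raise ValueError("n_facilities must be positive")
    return sum(l.amount.value for l in lines) / n_facilities


def tele_breakeven(increment: float, target: CftiCost,
                   split: float = 0.5) -> dict[str, int]:
    """Additional annual treatments needed for teleophthalmology to match a
    target per-case CFTI cost.

    ``split`` is the fraction of the per-facility increment attributed to
    URE case finding; the remainder goes to cataract. Counts are rounded up
    (partial patients are not achievable).
    """
    if not 0.0 <= split <= 1.0:
        raise ValueError("split must lie in [0, 1]")
    if increment < 0:
        raise ValueError("increment must be nonnegative")
    out = {"spectacles": 0, "surgeries": 0}
    ure_share = split * increment
    cat_share = (1.0 - split) * increment
    if ure_share > 0:
        t = target.cost_per_spectacle_initiated
        if not t or t <= 0:
            raise ValueError("positive target URE per-case cost required")
        out["spectacles"] = math.ceil(ure_share / t)
    if cat_share > 0:
        t = target.cost_per_surgery_initiated
        if not t or t <= 0:
            raise ValueError("positive target cataract per-case cost required")
        out["surgeries"] = math.ceil(cat_share / t)
    return out
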