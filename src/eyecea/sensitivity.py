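"""One-way (tornado) sensitivity and the counterfactual self-presentation
scenario.

One-way analysis re-runs the deterministic pipeline with one parameter at a
time pushed to its low and high bound and reports the resulting ICER range
per frontier strategy. The counterfactual scenario relaxes the
no-intervention baseline: a fraction *f* of treated patients would have
self-presented anyway, so incremental DALYs shrink by (1−f) and — under the
cost-offset model — the treatment costs of that fraction are credited to the
baseline as well.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Iterable, Literal, Mapping, Optional, Sequence

import pandas as pd

from .cea_frontier import (
    BASELINE,
    FrontierRow,
    StrategyOutcome,
    frontier_icers,
    icer_frontier,
)


@dataclass(frozen=True)
class ScenarioConfig:
    """One scenario: a single parameter varied between low and high."""

    parameter: str
    low: float
    high: float
    counterfactual_model: Literal["dalys_only", "dalys_and_cost_offsets"] = "dalys_only"

    def __post_init__(self):
        if self.low > self.high:
            raise ValueError("scenario low bound exceeds high bound")


#: signature: overrides {parameter: value} -> strategy outcomes
PipelineBuilder = Callable[[Mapping[str, float]], Iterable[StrategyOutcome]]


def outcome_scaler(base: Iterable[StrategyOutcome]) -> PipelineBuilder:
    """Builder over fixed outcomes supporting ``cost_multiplier`` and
    ``daly_multiplier`` overrides (the cost-linear / DALY-linear knobs that
    are well-defined without re-costing from raw lines)."""
    base = list(base)
    known = {"cost_multiplier", "daly_multiplier"}

    def build(overrides: Mapping[str, float]) -> list[StrategyOutcome]:
        unknown = set(overrides) - known
        if unknown:
            raise KeyError(f"unknown scenario parameter(s): {sorted(unknown)}")
        cm = overrides.get("cost_multiplier", 1.0)
        dm = overrides.get("daly_multiplier", 1.0)
        return [StrategyOutcome(o.strategy, o.total_cost * cm,
                                o.total_dalys * dm)
                for o in base]

    return build


def one_way(build: PipelineBuilder,
            scenarios: Sequence[ScenarioConfig]) -> pd.DataFrame:
    """Tornado table: per scenario and strategy, the ICER at the low and
    high parameter bound.

    ``build`` re-runs the deterministic pipeline with a single-parameter
    override; strategies off the frontier in a given run carry NaN. Rows are
    sorted by descending ICER-range width, so the output is invariant to the
    scenario ordering supplied.
    """
    records = []
    for sc in scenarios:
        icers_lo = frontier_icers(icer_frontier(build({sc.parameter: sc.low})))
        icers_hi = frontier_icers(icer_frontier(build({sc.parameter: sc.high})))
        for strat in sorted(set(icers_lo) | set(icers_hi)):
            lo = icers_lo.get(strat)
            hi = icers_hi.get(strat)
            pair = sorted(x for x in (lo, hi) if x is not None)
            records.append({
                "scenario": sc.parameter,
                "strategy": strat,
                "icer_low": pair[0] if pair else float("nan"),
                "icer_high": pair[-1] if pair else float("nan"),
            })
    df = pd.DataFrame.from_records(
        records, columns=["scenario", "strategy", "icer_low", "icer_high"])
    df["range"] = df["icer_high"] - df["icer_low"]
    return (df.sort_values(["range", "scenario", "strategy"],
                           ascending=[False, True, True])
              .drop(columns="range").reset_index(drop=True))


def counterfactual_scenario(
    outcomes: Iterable[StrategyOutcome],
    f: float,
    model: Literal["dalys_only", "dalys_and_cost_offsets"] = "dalys_only",
    treatment_costs: Optional[Mapping[str, float]] = None,
) -> list[FrontierRow]:
    """Frontier under the assumption that a fraction ``f`` of treated
    patients would have self-presented without any case-finding.

    Incremental DALYs scale by (1−f). Under ``dalys_and_cost_offsets`` the
    baseline is additionally credited with the treatment costs of the
    self-presenting fraction, i.e. each strategy's incremental cost drops by
    f × its treatment-cost block (``treatment_costs`` per strategy,
    required for that model).
    """
    if not 0.0 <= f < 1.0:
        raise ValueError("self-presentation fraction must lie in [0, 1)")
    adjusted = []
    for o in outcomes:
        if o.strategy == BASELINE:
            adjusted.append(o)
            continue
        cost = o.total_cost
        if model == "dalys_and_cost_offsets":
            if treatment_costs is None:
                raise ValueError(
                    "dalys_and_cost_offsets requires per-strategy treatment costs")
            cost = cost - f * treatment_costs.get(o.strategy, 0.0)
            if cost < 0:
                raise ValueError(f"cost offset exceeds total cost for {o.strategy}")
        elif model != "dalys_only":
            raise ValueError(f"unknown counterfactual model: {model!r}")
        adjusted.append(StrategyOutcome(o.strategy, cost, o.total_dalys * (1 - f)))
    return icer_frontier(adjusted)
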