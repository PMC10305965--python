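"""Synthetic provider-level cost and patient-flow data.

Generates the same CSV shapes the ingestion layer reads, with the
statistical structure the analysis assumes: right-skewed (gamma) positive
category costs with a multiplicative provider-heterogeneity factor, and
patient flows screened -> diagnosed {URE, cataract, other} -> treatment
initiated drawn multinomially/binomially. Default marginals emulate the
pooled study scale at one tenth the volume — e.g. vision centers at about
17,574 spectacles and 5,409 surgeries per 100,000 screened, eye camps
converting about 17,752 surgeries per 100,000 — so a full synthetic run
resembles the published tables while staying fast.

The generator also exposes its *implied* (expectation-level) per-case CFTI
costs and strategy outcomes, which parameter-recovery tests compare against
pipeline estimates on generated data.
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable, Optional

import numpy as np
from pydantic import BaseModel, Field, model_validator

from .config import AnalysisConfig
from .costing import apportion, cfti_cost
from .cea_frontier import StrategyOutcome, societal_cost
from .daly_model import per_case_factors
from .data_model import (
    Category,
    CostLine,
    Diagnoses,
    Earmark,
    Money,
    Strategy,
    StrategyDataset,
    cost_lines_to_frame,
    outcomes_to_frame,
)


class StrategyParams(BaseModel):
    """Generator marginals for one strategy."""

    screening_mean: float = Field(gt=0)  # per provider per year
    prevalence: dict[str, float]  # {ure, cataract, other} per screened person
    conversion: dict[str, float]  # {spectacle | ure dx, surgery | cataract dx}
    cost_per_100k: dict[Category, float]  # expected category cost per 100k screened
    #: fraction of each category earmarked wholly to a condition
    earmark_fraction: dict[Category, dict[Earmark, float]] = Field(default_factory=dict)
    capital_categories: dict[Category, float] = Field(default_factory=dict)  # -> useful life
    facilities_per_100k: Optional[float] = None

    @model_validator(mode="after")
    def _probabilities(self) -> "StrategyParams":
        if any(not 0 <= p <= 1 for p in self.prevalence.values()):
            raise ValueError("prevalence components must lie in [0, 1]")
        if sum(self.prevalence.values()) > 1:
            raise ValueError("prevalence components must sum to at most 1")
        if any(not 0 <= p <= 1 for p in self.conversion.values()):
            raise ValueError("conversion probabilities must lie in [0, 1]")
        return self


def _default_strategies() -> dict[Strategy, StrategyParams]:
    """Marginals calibrated to the pooled study tables at 1/10 volume."""
    C = Category
    return {
        Strategy.vision_centers: StrategyParams(
            screening_mean=137_392 / 6,
            prevalence={"ure": 0.25, "cataract": 0.09, "other": 0.04},
            conversion={"spectacle": 0.70296, "surgery": 0.601},
            cost_per_100k={C.planning_preparation: 25_049,
                           C.clinical_equipment: 56_947,
                           C.human_resources: 143_190,
                           C.other_operating: 77_299},
            earmark_fraction={C.clinical_equipment: {Earmark.other: 0.10}},
            capital_categories={C.clinical_equipment: 10.0},
            facilities_per_100k=2.58,
        ),
        Strategy.eye_camps: StrategyParams(
            screening_mean=30_772 / 6,
            prevalence={"ure": 0.24, "cataract": 0.28, "other": 0.05},
            conversion={"spectacle": 0.72204, "surgery": 0.634},
            cost_per_100k={C.planning_preparation: 119_154,
                           C.clinical_equipment: 18_585,
                           C.human_resources: 100_594,
                           C.other_operating: 147_408},
            earmark_fraction={C.other_operating: {Earmark.cataract: 0.55}},
        ),
        Strategy.door_to_door: StrategyParams(
            screening_mean=28_665 / 6,
            prevalence={"ure": 0.20, "cataract": 0.10, "other": 0.04},
            conversion={"spectacle": 0.47815, "surgery": 0.4543},
            cost_per_100k={C.planning_preparation: 14_212,
                           C.clinical_equipment: 4_227,
                           C.human_resources: 32_906,
                           C.other_operating: 45_586,
                           C.vc_followup_ure: 202_816},
            earmark_fraction={C.vc_followup_ure: {Earmark.ure: 1.0},
                              C.other_operating: {Earmark.cataract: 0.35}},
        ),
        Strategy.school_screening: StrategyParams(
            screening_mean=33_224 / 6,
            prevalence={"ure": 0.06, "cataract": 0.0, "other": 0.02},
            conversion={"spectacle": 0.40983, "surgery": 0.0},
            cost_per_100k={C.planning_preparation: 3_800,
                           C.clinical_equipment: 12_599,
                           C.human_resources: 55_010,
                           C.other_operating: 14_853},
        ),
    }


class GeneratorConfig(BaseModel):
    """Full synthetic-dataset specification; identical seed, identical data."""

    n_providers: int = Field(default=6, ge=1)
    strategies: dict[Strategy, StrategyParams] = Field(
        default_factory=_default_strategies)
    cost_cv: float = Field(default=0.35, gt=0)  # within-provider category CV
    provider_heterogeneity: float = Field(default=0.30, ge=0)  # multiplier CV
    discount_rate: float = Field(default=0.03, ge=0)
    seed: int = 0


def generate_patient_flow(n_screened: int, params: StrategyParams,
                          rng: np.random.Generator) -> dict[str, float]:
    """Screened -> diagnoses (multinomial) -> treatments (binomial)."""
    p = params.prevalence
    probs = [p.get("ure", 0.0), p.get("cataract", 0.0), p.get("other", 0.0)]
    probs.append(max(0.0, 1.0 - sum(probs)))
    dx_ure, dx_cat, dx_other, _ = rng.multinomial(n_screened, probs)
    spectacles = rng.binomial(dx_ure, params.conversion.get("spectacle", 0.0))
    surgeries = rng.binomial(dx_cat, params.conversion.get("surgery", 0.0))
    return {"n_screened": float(n_screened), "dx_ure": float(dx_ure),
            "dx_cataract": float(dx_cat), "dx_other": float(dx_other),
            "spectacles": float(spectacles), "surgeries": float(surgeries)}


def _present_value_factor(life: float, rate: float) -> float:
    if rate == 0:
        return life
    return (1.0 - (1.0 + rate) ** (-life)) / rate


def generate_provider_data(
    config: GeneratorConfig,
) -> list[tuple[str, StrategyDataset]]:
    """One (provider, StrategyDataset) per provider x strategy.

    Category costs are gamma with mean proportional to screening volume,
    scaled by a per-provider gamma multiplier (mean 1, CV
    ``provider_heterogeneity``). Categories listed in
    ``capital_categories`` are emitted as capital outlays whose equivalent
    annual cost has the target mean, exercising the annualization path.
    Earmarked fractions are emitted as separate tagged lines within the same
    category, so category sums are unaffected.
    """
    rng = np.random.default_rng(config.seed)
    out: list[tuple[str, StrategyDataset]] = []
    providers = [f"P{i+1}" for i in range(config.n_providers)]
    for strat in sorted(config.strategies, key=lambda s: s.value):
        params = config.strategies[strat]
        for prov in providers:
            if config.provider_heterogeneity > 0:
                cv2 = config.provider_heterogeneity ** 2
                mult = rng.gamma(1.0 / cv2, cv2)
            else:
                mult = 1.0
            n = int(rng.poisson(params.screening_mean))
            flow = generate_patient_flow(n, params, rng)
            lines: list[CostLine] = []
            for cat, mean_100k in params.cost_per_100k.items():
                mean = mean_100k * n / 100_000.0 * mult
                if mean <= 0:
                    continue
                cv2 = config.cost_cv ** 2
                drawn = rng.gamma(1.0 / cv2, mean * cv2)
                splits = dict(params.earmark_fraction.get(cat, {}))
                splits[Earmark.none] = 1.0 - sum(splits.values())
                life = params.capital_categories.get(cat)
                for tag, frac in splits.items():
                    if frac <= 0:
                        continue
                    annual = drawn * frac
                    if life is not None:
                        amount = annual * _present_value_factor(
                            life, config.discount_rate)
                        lines.append(CostLine(
                            strategy=strat, provider=prov,
                            raw_category=cat.value, category=cat,
                            amount=Money(value=amount),
                            is_capital=True, useful_life_years=life,
                            earmark=tag))
                    else:
                        lines.append(CostLine(
                            strategy=strat, provider=prov,
                            raw_category=cat.value, category=cat,
                            amount=Money(value=annual), earmark=tag))
            nfac = None
            if params.facilities_per_100k is not None:
                nfac = max(1.0, round(params.facilities_per_100k * n / 100_000.0))
            out.append((prov, StrategyDataset(
                strategy=strat,
                n_screened=flow["n_screened"],
                n_facilities=nfac,
                diagnoses=Diagnoses(ure=flow["dx_ure"],
                                    cataract=flow["dx_cataract"],
                                    other=flow["dx_other"]),
                spectacles=flow["spectacles"],
                surgeries=flow["surgeries"],
                cost_lines=lines,
            )))
    return out


def write_csvs(data: Iterable[tuple[str, StrategyDataset]], out_dir) -> dict[str, Path]:
    """Write cost-lines and outcomes CSVs in the package's canonical layout."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    data = list(data)
    lines = [l for _, d in data for l in d.cost_lines]
    cost_path = out_dir / "cost_lines.csv"
    cost_lines_to_frame(lines).to_csv(cost_path, index=False)
    import pandas as pd

    records = pd.DataFrame(
        [outcomes_to_frame([d], provider=prov).iloc[0].to_dict()
         for prov, d in data])
    outcomes_path = out_dir / "outcomes.csv"
    records.to_csv(outcomes_path, index=False)
    return {"cost_lines": cost_path, "outcomes": outcomes_path}


# ---------------------------------------------------------------------------
# Expectation-level (implied) quantities for parameter recovery
# ---------------------------------------------------------------------------

def implied_cfti(params: StrategyParams) -> dict[str, Optional[float]]:
    """Per-case CFTI costs implied by the generator marginals (per 100k)."""
    dx = Diagnoses(ure=params.prevalence.get("ure", 0.0) * 100_000,
                   cataract=params.prevalence.get("cataract", 0.0) * 100_000,
                   other=params.prevalence.get("other", 0.0) * 100_000)
    earmarked = {"ure": 0.0, "cataract": 0.0, "other": 0.0}
    for cat, tags in params.earmark_fraction.items():
        for tag, frac in tags.items():
            earmarked[tag.value] += params.cost_per_100k.get(cat, 0.0) * frac
    total = sum(params.cost_per_100k.values())
    app = apportion(total, dx, earmarked)
    spectacles = dx.ure * params.conversion.get("spectacle", 0.0)
    surgeries = dx.cataract * params.conversion.get("surgery", 0.0)
    c = cfti_cost(app, spectacles, surgeries)
    return {"ure": c.cost_per_spectacle_initiated,
            "cataract": c.cost_per_surgery_initiated}


def implied_outcomes(config: GeneratorConfig,
                     analysis: AnalysisConfig) -> list[StrategyOutcome]:
    """Expected societal cost and DALYs per strategy at generated volume."""
    f_ure, f_cat = per_case_factors(analysis.daly)
    uc = analysis.unit_costs
    out = []
    for strat, params in config.strategies.items():
        n_total = params.screening_mean * config.n_providers
        scale = n_total / 100_000.0
        total_cfti = sum(params.cost_per_100k.values()) * scale
        spectacles = (params.prevalence.get("ure", 0.0)
                      * params.conversion.get("spectacle", 0.0) * n_total)
        surgeries = (params.prevalence.get("cataract", 0.0)
                     * params.conversion.get("surgery", 0.0) * n_total)
        cost = societal_cost(total_cfti, spectacles, surgeries,
                             uc.spectacle, uc.surgery,
                             uc.patient_access_per_surgery)
        out.append(StrategyOutcome(strat.value, cost,
                                   spectacles * f_ure + surgeries * f_cat))
    return out
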