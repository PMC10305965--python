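"""Analysis configuration: discounting, currency, DALY factors, PSA spec.

Defaults follow the reference multi-provider Indian costing study this
package reproduces: 2020 USD at 70.42 INR/USD, 3% annual discounting for both
capital annualization and DALY streams, 0.02 DALYs averted per pair of
spectacles (3-year benefit) and 0.85 per cataract surgery (19.9-year
benefit), and 10,000 Monte Carlo draws for probabilistic sensitivity.
"""

from __future__ import annotations

from typing import Literal, Optional

import yaml
from pydantic import BaseModel, Field, model_validator


class DalyParams(BaseModel):
    """Per-case DALY-aversion factors, benefit durations, and discounting.

    ``mode`` selects how the per-case factors are interpreted:

    * ``lifetime_total`` (default) — ``per_case`` values are discounted
      lifetime DALYs averted per treated case and are used as-is;
    * ``annual_weight_annuity`` — ``per_case`` values are annual disability
      weights, multiplied by the discounted annuity factor over
      ``duration_years``.
    """

    per_case_ure: float = Field(default=0.02, ge=0)
    per_case_cataract: float = Field(default=0.85, ge=0)
    duration_ure: float = Field(default=3.0, gt=0)
    duration_cataract: float = Field(default=19.9, gt=0)
    discount_rate: float = Field(default=0.03, ge=0)
    mode: Literal["lifetime_total", "annual_weight_annuity"] = "lifetime_total"


class PsaSpec(BaseModel):
    """Monte Carlo spec for probabilistic sensitivity analysis.

    ``dispersion`` is the coefficient of variation (gamma/lognormal) or the
    fractional half-width (uniform_pct) applied to each cost category.
    Per-category overrides go in ``dispersion_by_category``.
    """

    n_sims: int = Field(default=10_000, ge=1)
    distribution: Literal["gamma", "lognormal", "uniform_pct"] = "gamma"
    dispersion: float = Field(default=0.25, gt=0)
    dispersion_by_category: dict[str, float] = Field(default_factory=dict)
    vary_outcomes: bool = False
    shared_provider_shock: float = Field(default=0.0, ge=0)


class UnitCosts(BaseModel):
    """Societal treatment-cost components per case (USD).

    The reference study draws these from national sources it does not print;
    they are configurable and the frontier reproduction uses published totals
    directly, so downstream table checks do not depend on them.
    """

    spectacle: float = Field(default=3.5, ge=0)
    surgery: float = Field(default=70.0, ge=0)
    patient_access_per_surgery: float = Field(default=20.0, ge=0)


class AnalysisConfig(BaseModel):
    """Top-level knobs shared by every stage of the pipeline."""

    discount_rate: float = Field(default=0.03, ge=0)
    exchange_rate: float = Field(default=70.42, gt=0)
    price_year: int = 2020
    daly: DalyParams = Field(default_factory=DalyParams)
    psa: PsaSpec = Field(default_factory=PsaSpec)
    unit_costs: UnitCosts = Field(default_factory=UnitCosts)
    lambda_grid: list[float] = Field(
        default_factory=lambda: [float(x) for x in range(0, 2501, 25)]
    )
    gdp_per_capita_threshold: float = Field(default=1928.0, gt=0)

    @model_validator(mode="after")
    def _grid_increasing(self) -> "AnalysisConfig":
        g = self.lambda_grid
        if any(b <= a for a, b in zip(g, g[1:])):
            raise ValueError("lambda_grid must be strictly increasing")
        return self

    @classmethod
    def from_yaml(cls, path) -> "AnalysisConfig":
        with open(path) as fh:
            payload = yaml.safe_load(fh) or {}
        return cls.model_validate(payload)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.model_dump(mode="json"), fh, sort_keys=False)
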