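"""Domain types and ingestion for provider cost lines and outcome counts.

The costing pipeline starts from two flat tables:

* a **cost-lines CSV**, one row per provider cost item, with columns
  ``provider, strategy, raw_category, category, amount, currency, price_year,
  is_capital, useful_life_years, earmark`` (``category`` may be left blank and
  filled later via :func:`standardize_categories`);
* an **outcomes CSV**, one row per provider x strategy, with columns
  ``provider, strategy, n_screened, dx_ure, dx_cataract, dx_other,
  spectacles, surgeries, n_facilities``.

All monetary arithmetic is guarded by an explicit :class:`Money` carrier
(value + currency + price year); mixing currencies raises instead of silently
adding rupees to dollars.
"""

from __future__ import annotations

import enum
import math
from typing import Iterable, Mapping, Optional, Sequence

import pandas as pd
from pydantic import BaseModel, ConfigDict, Field, model_validator


class Strategy(str, enum.Enum):
    """The five case-finding strategies under comparison."""

    vision_centers = "vision_centers"
    eye_camps = "eye_camps"
    door_to_door = "door_to_door"
    school_screening = "school_screening"
    teleophthalmology = "teleophthalmology"


class Category(str, enum.Enum):
    """Closed set of standardized reporting categories.

    The first four are the per-100,000-screened reporting categories;
    ``vc_followup_ure``, ``patient_travel_cataract`` and
    ``spectacles_procurement`` are strategy-specific lines; the ``tele_*``
    categories are the incremental teleophthalmology lines.
    """

    planning_preparation = "planning_preparation"
    clinical_equipment = "clinical_equipment"
    human_resources = "human_resources"
    other_operating = "other_operating"
    vc_followup_ure = "vc_followup_ure"
    patient_travel_cataract = "patient_travel_cataract"
    spectacles_procurement = "spectacles_procurement"
    tele_planning = "tele_planning"
    tele_it = "tele_it"
    tele_doctor = "tele_doctor"
    tele_internet = "tele_internet"


#: Categories that make up the teleophthalmology increment.
TELE_CATEGORIES = frozenset(
    {Category.tele_planning, Category.tele_it, Category.tele_doctor, Category.tele_internet}
)

#: The four main-table reporting categories.
REPORTING_CATEGORIES = (
    Category.planning_preparation,
    Category.clinical_equipment,
    Category.human_resources,
    Category.other_operating,
)


class Earmark(str, enum.Enum):
    """Apportionment earmark: a line tagged ``ure``/``cataract``/``other`` is
    assigned wholly to that condition instead of being split by diagnosis
    shares (e.g. fundus-type equipment -> other; subsidized cataract travel ->
    cataract)."""

    none = "none"
    ure = "ure"
    cataract = "cataract"
    other = "other"


class UnitError(ValueError):
    """Arithmetic attempted across incompatible currencies."""


class Money(BaseModel):
    """A monetary value tagged with its currency and price year."""

    model_config = ConfigDict(frozen=True)

    value: float = Field(ge=0)
    currency: str = "USD"
    price_year: int = 2020

    def __add__(self, other: "Money") -> "Money":
        if not isinstance(other, Money):
            return NotImplemented
        if other.currency != self.currency:
            raise UnitError(f"cannot add {other.currency} to {self.currency}")
        return Money(value=self.value + other.value, currency=self.currency,
                     price_year=self.price_year)

    def scaled(self, factor: float) -> "Money":
        return Money(value=self.value * factor, currency=self.currency,
                     price_year=self.price_year)


class CostLine(BaseModel):
    """One provider cost item.

    ``useful_life_years`` must be present iff ``is_capital``: recurrent lines
    are already annual, capital lines are annualized with
    :func:`annualize_capital` before any pooling.
    """

    strategy: Strategy
    provider: str
    raw_category: str = ""
    category: Optional[Category] = None
    amount: Money
    is_capital: bool = False
    useful_life_years: Optional[float] = None
    earmark: Earmark = Earmark.none

    @model_validator(mode="after")
    def _capital_consistency(self) -> "CostLine":
        if self.is_capital:
            if self.useful_life_years is None or self.useful_life_years <= 0:
                raise ValueError(
                    "capital cost line requires positive useful_life_years"
                )
        elif self.useful_life_years is not None:
            raise ValueError(
                "useful_life_years set on a non-capital (recurrent) line"
            )
        return self


class Diagnoses(BaseModel):
    """Diagnosis counts by condition for one strategy."""

    ure: float = Field(ge=0, default=0)
    cataract: float = Field(ge=0, default=0)
    other: float = Field(ge=0, default=0)

    @property
    def total(self) -> float:
        return self.ure + self.cataract + self.other


class StrategyDataset(BaseModel):
    """Cost lines plus outcome counts for one strategy (one provider, or
    pooled across providers).

    ``n_screened`` may be smaller than total diagnoses (repeat visits are
    allowed); only nonnegativity and the treatment <= diagnosis inequalities
    are enforced.
    """

    strategy: Strategy
    n_screened: float = Field(ge=0)
    n_facilities: Optional[float] = Field(default=None, ge=0)
    diagnoses: Diagnoses = Field(default_factory=Diagnoses)
    spectacles: float = Field(ge=0, default=0)
    surgeries: float = Field(ge=0, default=0)
    cost_lines: list[CostLine] = Field(default_factory=list)

    @model_validator(mode="after")
    def _treatment_bounds(self) -> "StrategyDataset":
        if self.spectacles > self.diagnoses.ure:
            raise ValueError("spectacles dispensed exceed URE diagnoses")
        if self.surgeries > self.diagnoses.cataract:
            raise ValueError("surgeries performed exceed cataract diagnoses")
        return self


# ---------------------------------------------------------------------------
# Currency conversion and capital annualization
# ---------------------------------------------------------------------------

def convert_to_usd(amount: Money, rate: float) -> Money:
    """Convert an INR amount to USD at ``rate`` INR per USD.

    The analysis price year (2020) is preserved; only the currency tag and
    value change. Passing a non-INR amount raises :class:`UnitError`.
    """
    if rate <= 0:
        raise ValueError("exchange rate must be positive")
    if amount.currency == "USD":
        raise UnitError("amount is already in USD")
    if amount.currency != "INR":
        raise UnitError(f"expected INR, got {amount.currency}")
    return Money(value=amount.value / rate, currency="USD",
                 price_year=amount.price_year)


def annualize_capital(cost: float, useful_life_years: float,
                      discount_rate: float) -> float:
    """Equivalent annual cost of a capital outlay.

    Returns the constant payment ``cost * r / (1 - (1+r)^-L)`` whose
    discounted stream over the useful life ``L`` equals the outlay; the
    ``r -> 0`` limit is straight-line depreciation ``cost / L``.
    """
    if useful_life_years <= 0:
        raise ValueError("useful life must be positive")
    if discount_rate < 0:
        raise ValueError("discount rate must be nonnegative")
    if discount_rate == 0:
        return cost / useful_life_years
    r = discount_rate
    return cost * r / (1.0 - (1.0 + r) ** (-useful_life_years))


def annualize_line(line: CostLine, discount_rate: float) -> CostLine:
    """Annualize a capital cost line; recurrent lines pass through unchanged."""
    if not line.is_capital:
        return line
    annual = annualize_capital(line.amount.value, line.useful_life_years,
                               discount_rate)
    return line.model_copy(update={
        "amount": Money(value=annual, currency=line.amount.currency,
                        price_year=line.amount.price_year),
        "is_capital": False,
        "useful_life_years": None,
    })


# ---------------------------------------------------------------------------
# Category standardization
# ---------------------------------------------------------------------------

class MappingError(KeyError):
    """Raw categories missing from the user-supplied standardization map."""

    def __init__(self, labels: Sequence[str]):
        self.labels = list(labels)
        super().__init__(f"unmapped raw categories: {sorted(set(self.labels))}")


def standardize_categories(
    lines: Iterable[CostLine],
    mapping: Mapping[str, Category | str],
) -> list[CostLine]:
    """Map free-text provider categories onto the standard closed set.

    Every raw category must appear in ``mapping``; total cost is conserved
    exactly (lines are relabelled, never split or merged).
    """
    lines = list(lines)
    missing = [l.raw_category for l in lines if l.raw_category not in mapping]
    if missing:
        raise MappingError(missing)
    return [
        l.model_copy(update={"category": Category(mapping[l.raw_category])})
        for l in lines
    ]


# ---------------------------------------------------------------------------
# CSV ingestion / export
# ---------------------------------------------------------------------------

COST_COLUMNS = [
    "provider", "strategy", "raw_category", "category", "amount", "currency",
    "price_year", "is_capital", "useful_life_years", "earmark",
]
OUTCOME_COLUMNS = [
    "provider", "strategy", "n_screened", "dx_ure", "dx_cataract", "dx_other",
    "spectacles", "surgeries", "n_facilities",
]


class SchemaError(ValueError):
    """A required column is missing from an input table."""


def _require_columns(df: pd.DataFrame, required: Sequence[str], what: str) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{what} is missing required column(s): {missing}")


def load_cost_table(
    path,
    mapping: Optional[Mapping[str, Category | str]] = None,
) -> list[CostLine]:
    """Read a cost-lines CSV into validated :class:`CostLine` records.

    Rows with a blank ``category`` are mapped through ``mapping`` (raw ->
    standard); rows that already carry a standard category are taken as-is.
    A negative amount raises a validation error naming the row index.
    """
    df = pd.read_csv(path)
    _require_columns(df, [c for c in COST_COLUMNS if c != "category"],
                     "cost-lines CSV")
    lines: list[CostLine] = []
    for idx, row in df.iterrows():
        if row["amount"] < 0:
            raise ValueError(f"row {idx}: negative amount {row['amount']}")
        category = row.get("category")
        if pd.isna(category) or category == "":
            if mapping is None or row["raw_category"] not in mapping:
                raise MappingError([str(row["raw_category"])])
            category = mapping[row["raw_category"]]
        life = row["useful_life_years"]
        try:
            lines.append(CostLine(
                strategy=row["strategy"],
                provider=str(row["provider"]),
                raw_category=str(row["raw_category"]),
                category=Category(category),
                amount=Money(value=float(row["amount"]),
                             currency=str(row["currency"]),
                             price_year=int(row["price_year"])),
                is_capital=bool(row["is_capital"]),
                useful_life_years=None if pd.isna(life) else float(life),
                earmark=Earmark(row["earmark"]) if not pd.isna(row["earmark"])
                else Earmark.none,
            ))
        except (ValueError, TypeError) as exc:
            raise ValueError(f"row {idx}: {exc}") from exc
    return lines


def cost_lines_to_frame(lines: Iterable[CostLine]) -> pd.DataFrame:
    """Flatten cost lines to the canonical CSV layout."""
    records = []
    for l in lines:
        records.append({
            "provider": l.provider,
            "strategy": l.strategy.value,
            "raw_category": l.raw_category,
            "category": l.category.value if l.category else "",
            "amount": l.amount.value,
            "currency": l.amount.currency,
            "price_year": l.amount.price_year,
            "is_capital": l.is_capital,
            "useful_life_years": l.useful_life_years,
            "earmark": l.earmark.value,
        })
    return pd.DataFrame.from_records(records, columns=COST_COLUMNS)


def load_outcomes_table(path) -> list[StrategyDataset]:
    """Read an outcomes CSV into per-provider :class:`StrategyDataset` records
    (cost lines attached separately)."""
    df = pd.read_csv(path)
    _require_columns(df, [c for c in OUTCOME_COLUMNS if c != "n_facilities"],
                     "outcomes CSV")
    out = []
    for idx, row in df.iterrows():
        nfac = row.get("n_facilities")
        try:
            out.append(StrategyDataset(
                strategy=row["strategy"],
                n_screened=float(row["n_screened"]),
                n_facilities=None if nfac is None or pd.isna(nfac) else float(nfac),
                diagnoses=Diagnoses(ure=float(row["dx_ure"]),
                                    cataract=float(row["dx_cataract"]),
                                    other=float(row["dx_other"])),
                spectacles=float(row["spectacles"]),
                surgeries=float(row["surgeries"]),
            ))
        except ValueError as exc:
            raise ValueError(f"row {idx}: {exc}") from exc
    return out


def outcomes_to_frame(datasets: Iterable[StrategyDataset],
                      provider: str = "pooled") -> pd.DataFrame:
    records = []
    for d in datasets:
        records.append({
            "provider": provider,
            "strategy": d.strategy.value,
            "n_screened": d.n_screened,
            "dx_ure": d.diagnoses.ure,
            "dx_cataract": d.diagnoses.cataract,
            "dx_other": d.diagnoses.other,
            "spectacles": d.spectacles,
            "surgeries": d.surgeries,
            "n_facilities": d.n_facilities,
        })
    return pd.DataFrame.from_records(records, columns=OUTCOME_COLUMNS)
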