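"""Paper-shaped output tables, run manifests, and the budget extrapolation.

Machine CSVs carry full precision; a rounded display column follows the
published conventions (whole dollars for category costs, one decimal for
per-person and per-case costs, integer ICERs).
"""

from __future__ import annotations

import hashlib
import json
from datetime import datetime, timezone
from pathlib import Path
from typing import Iterable, Mapping, Optional

import pandas as pd
from pydantic import BaseModel, Field

from . import __version__
from .cea_frontier import FrontierRow
from .config import AnalysisConfig
from .costing import CftiCost, NormalizedCosts
from .data_model import REPORTING_CATEGORIES, Category, Strategy


def table1_frame(
    normalized: Mapping[Strategy, NormalizedCosts],
    cfti: Mapping[Strategy, CftiCost],
    rates: Optional[Mapping[Strategy, Mapping[str, float]]] = None,
) -> pd.DataFrame:
    """Costing table: categories x strategies per 100,000 screened, with
    total, per-person and per-case rows."""
    cols = {}
    for strat, norm in normalized.items():
        col = {}
        for cat in REPORTING_CATEGORIES:
            col[cat.value] = norm.by_category.get(cat, 0.0)
        for cat, v in norm.by_category.items():
            if cat not in REPORTING_CATEGORIES:
                col[cat.value] = v
        col["total"] = norm.total
        col["cost_per_person_screened"] = norm.total / 100_000.0
        c = cfti.get(strat)
        col["cfti_ure"] = (c.cost_per_spectacle_initiated
                           if c and c.cost_per_spectacle_initiated is not None
                           else float("nan"))
        col["cfti_cataract"] = (c.cost_per_surgery_initiated
                                if c and c.cost_per_surgery_initiated is not None
                                else float("nan"))
        if rates and strat in rates:
            for k, v in rates[strat].items():
                col[k] = v
        cols[strat.value] = col
    return pd.DataFrame(cols)


def table2_frame(vc_per_facility: Mapping[Category, float],
                 tele_per_facility: Mapping[Category, float]) -> pd.DataFrame:
    """Per-facility vision-center costs (panel A) and incremental
    teleophthalmology costs (panel B), with panel totals."""
    rows = []
    for cat, v in vc_per_facility.items():
        rows.append({"panel": "vision_center", "category": cat.value, "cost": v})
    rows.append({"panel": "vision_center", "category": "total",
                 "cost": sum(vc_per_facility.values())})
    for cat, v in tele_per_facility.items():
        rows.append({"panel": "teleophthalmology", "category": cat.value, "cost": v})
    rows.append({"panel": "teleophthalmology", "category": "total",
                 "cost": sum(tele_per_facility.values())})
    return pd.DataFrame(rows)


def table3_frame(rows: Iterable[FrontierRow]) -> pd.DataFrame:
    """Frontier table with dominance status and integer-rounded ICERs."""
    records = []
    for r in rows:
        records.append({
            "strategy": r.strategy,
            "total_cost": r.total_cost,
            "total_dalys": r.total_dalys,
            "incremental_cost": r.incremental_cost,
            "incremental_dalys": r.incremental_dalys,
            "icer": r.icer,
            "icer_rounded": (round(r.icer) if r.icer is not None else None),
            "status": r.status.value,
        })
    return pd.DataFrame.from_records(records)


def budget_extrapolation(per_facility_ci: tuple[float, float],
                         n_facilities: float) -> dict[str, float]:
    """National budget envelope: facility count x per-facility annual cost
    bounds, in USD millions (raw and rounded to the nearest $10M)."""
    lo, hi = per_facility_ci
    if lo > hi:
        raise ValueError("CI lower bound exceeds upper bound")
    low_m = n_facilities * lo / 1e6
    high_m = n_facilities * hi / 1e6
    return {
        "low_musd": low_m,
        "high_musd": high_m,
        "low_musd_rounded": round(low_m / 10.0) * 10.0,
        "high_musd_rounded": round(high_m / 10.0) * 10.0,
    }


class RunManifest(BaseModel):
    """Provenance record written once per output directory."""

    config_hash: str
    input_digests: dict[str, str] = Field(default_factory=dict)
    seed: Optional[int] = None
    package_version: str = __version__
    timestamp: str = ""


def _sha256_file(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def write_manifest(out_dir, config: AnalysisConfig,
                   inputs: Mapping[str, Path] | None = None,
                   seed: Optional[int] = None) -> Path:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    cfg_json = json.dumps(config.model_dump(mode="json"), sort_keys=True)
    manifest = RunManifest(
        config_hash=hashlib.sha256(cfg_json.encode()).hexdigest(),
        input_digests={k: _sha256_file(Path(p)) for k, p in (inputs or {}).items()},
        seed=seed,
        timestamp=datetime.now(timezone.utc).isoformat(),
    )
    path = out_dir / "manifest.json"
    path.write_text(manifest.model_dump_json(indent=2))
    return path
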