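"""Probabilistic sensitivity analysis and cost-effectiveness acceptability
curves.

Cost uncertainty is propagated by drawing each cost category independently
from a distribution centred on its pooled point estimate (gamma by default —
strictly positive and right-skewed, the standard choice for costs) and
re-running the full deterministic chain (apportion -> per-case CFTI -> DALYs
-> societal cost) for every draw. Percentile intervals of the resulting
draws give the confidence intervals; the CEAC reports, at each
willingness-to-pay λ, the fraction of draws in which each strategy attains
the maximal net monetary benefit.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .cea_frontier import StrategyOutcome, societal_cost
from .config import AnalysisConfig, PsaSpec
from .costing import Basis, apportion, cfti_cost, normalize
from .daly_model import per_case_factors, total_dalys
from .data_model import Diagnoses, Strategy, StrategyDataset


@dataclass
class PsaResult:
    """Per-draw pipeline outputs for all strategies.

    ``draws`` maps strategy -> DataFrame with one row per simulation and
    columns ``total_cost``, ``total_dalys``, ``cfti_ure``, ``cfti_cataract``
    (per-case costs NaN where undefined). ``n_undefined`` counts draws whose
    CFTI was undefined (zero treatment count under outcome variation).
    """

    draws: dict[str, pd.DataFrame]
    spec: PsaSpec
    seed: int
    n_undefined: dict[str, int] = field(default_factory=dict)


def sample_costs(point: Mapping, spec: PsaSpec,
                 rng: np.random.Generator) -> pd.DataFrame:
    """Draw ``spec.n_sims`` independent samples per cost category.

    Gamma and lognormal draws are parameterized so each category's mean is
    its point estimate with the configured coefficient of variation;
    ``uniform_pct`` draws uniformly within ±dispersion of the point. A zero
    point estimate yields a degenerate constant-zero column (warned).
    """
    cols = {}
    for cat, mean in point.items():
        name = getattr(cat, "value", str(cat))
        cv = spec.dispersion_by_category.get(name, spec.dispersion)
        if mean == 0:
            warnings.warn(f"zero point estimate for {name}: degenerate draws",
                          stacklevel=2)
            cols[name] = np.zeros(spec.n_sims)
            continue
        if mean < 0:
            raise ValueError(f"negative point estimate for {name}")
        if spec.distribution == "gamma":
            shape = 1.0 / cv**2
            cols[name] = rng.gamma(shape, mean * cv**2, size=spec.n_sims)
        elif spec.distribution == "lognormal":
            sigma2 = np.log1p(cv**2)
            mu = np.log(mean) - sigma2 / 2.0
            cols[name] = rng.lognormal(mu, np.sqrt(sigma2), size=spec.n_sims)
        else:  # uniform_pct
            half = mean * cv
            cols[name] = rng.uniform(mean - half, mean + half, size=spec.n_sims)
    return pd.DataFrame(cols)


def run_psa(pooled: Mapping[Strategy, StrategyDataset],
            config: AnalysisConfig, seed: int) -> PsaResult:
    """Monte Carlo propagation of cost uncertainty through the pipeline.

    For each draw the category costs (and their earmarked components, which
    scale with their category) are resampled, apportioned by diagnosis
    shares, divided by treatment counts for per-case CFTI costs, and
    assembled into a societal cost; DALYs come from treatment counts (fixed
    unless ``spec.vary_outcomes`` resamples them binomially from diagnoses).
    Identical seeds give identical draws.
    """
    spec = config.psa
    rng = np.random.default_rng(seed)
    draws: dict[str, pd.DataFrame] = {}
    n_undef: dict[str, int] = {}
    f_ure, f_cat = per_case_factors(config.daly)
    uc = config.unit_costs

    for strat in sorted(pooled, key=lambda s: s.value):
        ds = pooled[strat]
        norm = normalize(ds, Basis.total)
        cat_draws = sample_costs(norm.by_category, spec, rng)
        if spec.shared_provider_shock > 0:
            shock = rng.gamma(1.0 / spec.shared_provider_shock**2,
                              spec.shared_provider_shock**2,
                              size=spec.n_sims)
            cat_draws = cat_draws.mul(shock, axis=0)
        # earmark fractions of each category scale with the category draw
        ear_frac: dict[str, dict[str, float]] = {}
        for (cat, tag), amt in norm.earmarked.items():
            base = norm.by_category[cat]
            if base > 0:
                ear_frac.setdefault(cat.value, {})
                ear_frac[cat.value][tag.value] = (
                    ear_frac[cat.value].get(tag.value, 0.0) + amt / base)

        if spec.vary_outcomes and ds.diagnoses.ure > 0:
            p_spec = ds.spectacles / ds.diagnoses.ure
            spectacles = rng.binomial(int(round(ds.diagnoses.ure)), p_spec,
                                      size=spec.n_sims).astype(float)
        else:
            spectacles = np.full(spec.n_sims, float(ds.spectacles))
        if spec.vary_outcomes and ds.diagnoses.cataract > 0:
            p_surg = ds.surgeries / ds.diagnoses.cataract
            surgeries = rng.binomial(int(round(ds.diagnoses.cataract)), p_surg,
                                     size=spec.n_sims).astype(float)
        else:
            surgeries = np.full(spec.n_sims, float(ds.surgeries))

        total = cat_draws.sum(axis=1).to_numpy()
        ear = {"ure": np.zeros(spec.n_sims), "cataract": np.zeros(spec.n_sims),
               "other": np.zeros(spec.n_sims)}
        for cat_name, tags in ear_frac.items():
            for tag, frac in tags.items():
                ear[tag] += cat_draws[cat_name].to_numpy() * frac
        residual = total - ear["ure"] - ear["cataract"] - ear["other"]
        dx = ds.diagnoses
        dx_total = dx.total
        if dx_total > 0:
            cost_ure = ear["ure"] + residual * (dx.ure / dx_total)
            cost_cat = ear["cataract"] + residual * (dx.cataract / dx_total)
        else:
            cost_ure = ear["ure"]
            cost_cat = ear["cataract"]

        with np.errstate(divide="ignore", invalid="ignore"):
            cfti_ure = np.where(spectacles > 0, cost_ure / spectacles, np.nan)
            cfti_cat = np.where(surgeries > 0, cost_cat / surgeries, np.nan)
        undef = int(np.sum((spectacles == 0) & (ds.spectacles > 0))
                    + np.sum((surgeries == 0) & (ds.surgeries > 0)))
        n_undef[strat.value] = undef

        dalys = spectacles * f_ure + surgeries * f_cat
        soc = (total + spectacles * uc.spectacle
               + surgeries * (uc.surgery + uc.patient_access_per_surgery))
        draws[strat.value] = pd.DataFrame({
            "total_cost": soc,
            "total_dalys": dalys,
            "cfti_ure": cfti_ure,
            "cfti_cataract": cfti_cat,
        })
    return PsaResult(draws=draws, spec=spec, seed=seed, n_undefined=n_undef)


def percentile_ci(samples: Sequence[float] | np.ndarray,
                  level: float = 0.95) -> tuple[float, float]:
    """Empirical percentile interval (linear interpolation rule).

    For ``level=0.95`` this is the 2.5th and 97.5th percentiles; NaN entries
    (undefined draws) are excluded, with at least two finite samples
    required.
    """
    arr = np.asarray(samples, dtype=float)
    arr = arr[~np.isnan(arr)]
    if arr.size < 2:
        raise ValueError("need at least two finite samples for a CI")
    alpha = (1.0 - level) / 2.0
    lo, hi = np.percentile(arr, [100 * alpha, 100 * (1 - alpha)])
    return float(lo), float(hi)


@dataclass(frozen=True)
class CeacCurve:
    """Probability each strategy has the maximal net monetary benefit, on a
    grid of DALY valuations λ. Probabilities sum to 1 at every λ (ties split
    equally)."""

    lambda_grid: np.ndarray
    prob_best: pd.DataFrame  # index aligned with lambda_grid, one col/strategy

    def to_frame(self) -> pd.DataFrame:
        out = self.prob_best.copy()
        out.insert(0, "lambda", self.lambda_grid)
        return out


def ceac(result: PsaResult | Mapping[str, pd.DataFrame],
         lambda_grid: Sequence[float],
         include_baseline: bool = True) -> CeacCurve:
    """Cost-effectiveness acceptability curves from PSA draws.

    At each λ, each draw's winner is the strategy with maximal net monetary
    benefit λ·DALYs − cost (baseline contributes NMB 0); exact ties within a
    draw split the probability mass equally, so columns sum to 1.
    """
    draws = result.draws if isinstance(result, PsaResult) else dict(result)
    names = sorted(draws)
    n_sims = len(next(iter(draws.values())))
    costs = np.column_stack([draws[s]["total_cost"].to_numpy() for s in names])
    dalys = np.column_stack([draws[s]["total_dalys"].to_numpy() for s in names])
    if include_baseline and "baseline" not in names:
        names = ["baseline"] + names
        costs = np.column_stack([np.zeros(n_sims), costs])
        dalys = np.column_stack([np.zeros(n_sims), dalys])
    lam = np.asarray(lambda_grid, dtype=float)
    probs = np.zeros((lam.size, len(names)))
    for i, l in enumerate(lam):
        nmb = l * dalys - costs
        best = nmb.max(axis=1, keepdims=True)
        winners = np.isclose(nmb, best, rtol=0.0, atol=1e-9 * (1 + np.abs(best)))
        probs[i] = (winners / winners.sum(axis=1, keepdims=True)).mean(axis=0)
    return CeacCurve(lambda_grid=lam,
                     prob_best=pd.DataFrame(probs, columns=names))


def psa_outcomes_from_table(outcomes: Iterable[StrategyOutcome],
                            spec: PsaSpec, seed: int) -> PsaResult:
    """PSA over published strategy-level totals (costs varied, DALYs fixed).

    Used when only strategy totals are available (no category breakdown):
    each strategy's total societal cost is drawn around its point estimate.
    """
    rng = np.random.default_rng(seed)
    draws = {}
    for o in sorted(outcomes, key=lambda o: o.strategy):
        if o.strategy == "baseline":
            continue
        cost = sample_costs({"total": o.total_cost}, spec, rng)["total"]
        draws[o.strategy] = pd.DataFrame({
            "total_cost": cost.to_numpy(),
            "total_dalys": np.full(spec.n_sims, o.total_dalys),
            "cfti_ure": np.nan,
            "cfti_cataract": np.nan,
        })
    return PsaResult(draws=draws, spec=spec, seed=seed)
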