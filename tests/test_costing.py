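"""Pooling, normalization, apportionment, per-case CFTI costs, and
teleophthalmology incremental costing."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from eyecea import study_data as sd
from eyecea.costing import (
    Basis,
    CftiCost,
    apportion,
    cfti_cost,
    normalize,
    pool_strategies,
    strategy_cfti,
    tele_breakeven,
    tele_increment,
)
from eyecea.data_model import (
    Category,
    CostLine,
    Diagnoses,
    Earmark,
    Money,
    Strategy,
    StrategyDataset,
    UnitError,
)


def _ds(strategy=Strategy.eye_camps, n_screened=10_000, costs=None,
        earmarks=None, **kwargs):
    lines = []
    for cat, amount in (costs or {}).items():
        lines.append(CostLine(strategy=strategy, provider=kwargs.get("provider", "P1"),
                              raw_category=cat.value, category=cat,
                              amount=Money(value=amount),
                              earmark=(earmarks or {}).get(cat, Earmark.none)))
    kwargs.pop("provider", None)
    return StrategyDataset(strategy=strategy, n_screened=n_screened,
                           cost_lines=lines, **kwargs)


class TestPooling:
    def test_two_provider_additivity(self):
        a = _ds(costs={Category.human_resources: 100.0}, n_screened=10_000)
        b = _ds(costs={Category.human_resources: 200.0}, n_screened=20_000,
                provider="P2")
        pooled = pool_strategies([a, b])[Strategy.eye_camps]
        assert pooled.n_screened == 30_000
        assert sum(l.amount.value for l in pooled.cost_lines) == 300.0

    def test_single_provider_identity(self):
        a = _ds(costs={Category.human_resources: 100.0},
                diagnoses={"ure": 5, "cataract": 2, "other": 1}, spectacles=3)
        pooled = pool_strategies([a])[Strategy.eye_camps]
        assert pooled.model_dump() == a.model_dump()

    def test_six_providers_match_brute_force_sums(self, rng):
        datasets, screened, amounts = [], 0.0, 0.0
        for i in range(6):
            n = float(rng.integers(1_000, 50_000))
            c = float(rng.uniform(100, 10_000))
            screened += n
            amounts += c
            datasets.append(_ds(costs={Category.human_resources: c},
                                n_screened=n, provider=f"P{i}"))
        pooled = pool_strategies(datasets)[Strategy.eye_camps]
        assert pooled.n_screened == screened
        assert sum(l.amount.value for l in pooled.cost_lines) == pytest.approx(
            amounts, rel=1e-12)

    def test_mixed_currencies_rejected(self):
        a = _ds(costs={Category.human_resources: 100.0})
        b = _ds(costs={Category.human_resources: 100.0})
        b.cost_lines[0] = b.cost_lines[0].model_copy(update={
            "amount": Money(value=100.0, currency="INR")})
        with pytest.raises(UnitError):
            pool_strategies([a, b])


class TestNormalize:
    def test_published_vision_center_totals(self):
        """The four published per-100k category values sum to the printed
        total and imply the printed per-person cost."""
        ds = _ds(strategy=Strategy.vision_centers, n_screened=100_000,
                 costs={c: float(v) for c, v in
                        sd.COSTS_PER_100K[Strategy.vision_centers].items()})
        norm = normalize(ds, Basis.per_100k_screened)
        assert norm.total == 302_485
        assert round(norm.total / 100_000, 1) == 3.0

    def test_identity_at_100k_screened(self):
        ds = _ds(n_screened=100_000, costs={Category.human_resources: 123.0})
        norm = normalize(ds, Basis.per_100k_screened)
        assert norm.by_category[Category.human_resources] == 123.0

    def test_scaling(self):
        ds = _ds(n_screened=50_000, costs={Category.human_resources: 100.0})
        assert normalize(ds, Basis.per_100k_screened).total == 200.0

    def test_zero_denominator_rejected(self):
        ds = _ds(n_screened=0, costs={Category.human_resources: 1.0})
        with pytest.raises(ValueError):
            normalize(ds, Basis.per_100k_screened)
        with pytest.raises(ValueError):
            normalize(ds, Basis.per_facility)

    def test_per_facility(self):
        ds = _ds(strategy=Strategy.vision_centers, n_facilities=4,
                 costs={Category.human_resources: 400.0})
        assert normalize(ds, Basis.per_facility).total == 100.0

    def test_pool_then_normalize_is_weighted_average(self, rng):
        """Pooling then normalizing equals the screening-weighted average of
        per-provider normalized totals."""
        datasets = []
        for i in range(5):
            datasets.append(_ds(
                n_screened=float(rng.integers(5_000, 60_000)),
                costs={Category.human_resources: float(rng.uniform(1e3, 1e5)),
                       Category.other_operating: float(rng.uniform(1e3, 1e5))},
                provider=f"P{i}"))
        pooled = pool_strategies(datasets)[Strategy.eye_camps]
        got = normalize(pooled, Basis.per_100k_screened).total
        weights = np.array([d.n_screened for d in datasets])
        per = np.array([normalize(d, Basis.per_100k_screened).total
                        for d in datasets])
        assert got == pytest.approx(np.average(per, weights=weights), rel=1e-9)


class TestApportion:
    def test_symmetric_split(self):
        app = apportion(100.0, {"ure": 50, "cataract": 50, "other": 0})
        assert (app.ure, app.cataract, app.other) == (50.0, 50.0, 0.0)

    def test_earmark_plus_proportional_residual(self):
        app = apportion(100.0, {"ure": 35, "cataract": 35, "other": 0},
                        earmarked={"cataract": 30.0})
        assert app.ure == pytest.approx(35.0)
        assert app.cataract == pytest.approx(65.0)
        assert app.other == pytest.approx(0.0)

    def test_degenerate_share_all_to_other(self):
        app = apportion(100.0, {"ure": 0, "cataract": 0, "other": 10})
        assert app.other == 100.0

    def test_earmarks_exceeding_total_rejected(self):
        with pytest.raises(ValueError, match="exceed"):
            apportion(100.0, {"ure": 1, "cataract": 1, "other": 1},
                      earmarked={"ure": 200.0})

    @given(
        total=st.floats(0.0, 1e7),
        dx=st.tuples(*[st.floats(0, 1e5)] * 3),
        fracs=st.tuples(*[st.floats(0, 0.3)] * 3),
    )
    @settings(max_examples=200, deadline=None)
    def test_conservation_is_exact(self, total, dx, fracs):
        diagnoses = {"ure": dx[0], "cataract": dx[1], "other": dx[2]}
        if sum(dx) == 0:
            return
        earmarked = {"ure": total * fracs[0], "cataract": total * fracs[1],
                     "other": total * fracs[2]}
        app = apportion(total, diagnoses, earmarked)
        assert app.ure + app.cataract + app.other == total
        assert min(app.ure, app.cataract, app.other) >= -1e-9 * max(total, 1)


class TestCfti:
    def test_simple_division(self):
        app = apportion(2000.0, {"ure": 100, "cataract": 100, "other": 0})
        c = cfti_cost(app, spectacles=100, surgeries=0)
        assert c.cost_per_spectacle_initiated == pytest.approx(10.0)
        assert c.cost_per_surgery_initiated is None  # undefined, not an error

    def test_matches_brute_force_earmark_share_divide_oracle(self):
        """Pipeline CFTI equals an independent earmark+share+divide
        recomputation on a camps-like fixture."""
        ds = _ds(strategy=Strategy.eye_camps, n_screened=100_000,
                 costs={Category.planning_preparation: 119_154.0,
                        Category.other_operating: 147_408.0},
                 earmarks={Category.other_operating: Earmark.cataract},
                 diagnoses={"ure": 24_000, "cataract": 28_000, "other": 5_000},
                 spectacles=17_329, surgeries=17_752)
        got = strategy_cfti(ds)
        # oracle: earmarked line wholly to cataract, residual by dx shares
        residual = 119_154.0
        share_cat = 28_000 / 57_000
        share_ure = 24_000 / 57_000
        oracle_cat = (147_408.0 + residual * share_cat) / 17_752
        oracle_ure = (residual * share_ure) / 17_329
        assert got.cost_per_surgery_initiated == pytest.approx(oracle_cat, rel=1e-12)
        assert got.cost_per_spectacle_initiated == pytest.approx(oracle_ure, rel=1e-12)

    @given(scale_cost=st.floats(0.1, 10), scale_n=st.floats(0.1, 10))
    @settings(max_examples=50, deadline=None)
    def test_homogeneity(self, scale_cost, scale_n):
        """CFTI is degree-1 homogeneous in costs, degree -1 in counts."""
        app = apportion(1000.0, {"ure": 10, "cataract": 10, "other": 0})
        base = cfti_cost(app, 40, 25)
        app2 = apportion(1000.0 * scale_cost, {"ure": 10, "cataract": 10, "other": 0})
        scaled = cfti_cost(app2, 40 * scale_n, 25 * scale_n)
        factor = scale_cost / scale_n
        assert scaled.cost_per_spectacle_initiated == pytest.approx(
            base.cost_per_spectacle_initiated * factor, rel=1e-9)
        assert scaled.cost_per_surgery_initiated == pytest.approx(
            base.cost_per_surgery_initiated * factor, rel=1e-9)


class TestTeleophthalmology:
    def _tele_lines(self, scale=1.0):
        vals = {Category.tele_planning: 57.0, Category.tele_it: 164.0,
                Category.tele_doctor: 766.0, Category.tele_internet: 284.0}
        return [CostLine(strategy=Strategy.teleophthalmology, provider="P1",
                         raw_category=c.value, category=c,
                         amount=Money(value=v * scale))
                for c, v in vals.items()]

    def test_published_increment(self):
        assert tele_increment(self._tele_lines()) == 1_271.0

    def test_empty_is_zero(self):
        assert tele_increment([]) == 0.0

    def test_linearity(self):
        assert tele_increment(self._tele_lines(2.0)) == 2 * 1_271.0

    def test_non_tele_category_rejected(self):
        bad = self._tele_lines() + [CostLine(
            strategy=Strategy.teleophthalmology, provider="P1",
            raw_category="rent", category=Category.other_operating,
            amount=Money(value=1.0))]
        with pytest.raises(ValueError, match="other_operating"):
            tele_increment(bad)

    def test_breakeven_hand_division_with_ceiling(self):
        target = CftiCost(strategy=Strategy.eye_camps,
                          cost_per_spectacle_initiated=8.0,
                          cost_per_surgery_initiated=13.7)
        assert tele_breakeven(1_271.0, target, split=0.5) == {
            "spectacles": 80, "surgeries": 47}

    def test_breakeven_boundaries(self):
        target = CftiCost(strategy=Strategy.eye_camps,
                          cost_per_spectacle_initiated=8.0,
                          cost_per_surgery_initiated=13.7)
        assert tele_breakeven(0.0, target) == {"spectacles": 0, "surgeries": 0}
        assert tele_breakeven(1_271.0, target, split=1.0)["surgeries"] == 0

    def test_breakeven_zero_target_rejected(self):
        target = CftiCost(strategy=Strategy.eye_camps,
                          cost_per_spectacle_initiated=0.0,
                          cost_per_surgery_initiated=None)
        with pytest.raises(ValueError):
            tele_breakeven(100.0, target, split=1.0)
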