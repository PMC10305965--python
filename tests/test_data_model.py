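"""Ingestion, money handling, annualization and category standardization."""

import math

import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from eyecea.data_model import (
    Category,
    CostLine,
    Earmark,
    MappingError,
    Money,
    SchemaError,
    Strategy,
    StrategyDataset,
    UnitError,
    annualize_capital,
    annualize_line,
    convert_to_usd,
    cost_lines_to_frame,
    load_cost_table,
    load_outcomes_table,
    standardize_categories,
)


def _write_cost_csv(path, rows):
    pd.DataFrame(rows).to_csv(path, index=False)


BASE_ROW = dict(provider="P1", strategy="eye_camps",
                raw_category="planning", category="planning_preparation",
                amount=100.0, currency="USD", price_year=2020,
                is_capital=False, useful_life_years=None, earmark="none")


class TestLoadCostTable:
    def test_single_row_identity_parse(self, tmp_path):
        p = tmp_path / "c.csv"
        _write_cost_csv(p, [BASE_ROW])
        (line,) = load_cost_table(p)
        assert line.strategy is Strategy.eye_camps
        assert line.category is Category.planning_preparation
        assert line.amount == Money(value=100.0, currency="USD", price_year=2020)
        assert not line.is_capital

    def test_useful_life_without_capital_flag_rejected(self, tmp_path):
        p = tmp_path / "c.csv"
        _write_cost_csv(p, [{**BASE_ROW, "useful_life_years": 5.0}])
        with pytest.raises(ValueError, match="row 0"):
            load_cost_table(p)

    def test_negative_amount_names_row(self, tmp_path):
        p = tmp_path / "c.csv"
        _write_cost_csv(p, [BASE_ROW, {**BASE_ROW, "amount": -1.0}])
        with pytest.raises(ValueError, match="row 1"):
            load_cost_table(p)

    def test_missing_column_names_it(self, tmp_path):
        p = tmp_path / "c.csv"
        row = {k: v for k, v in BASE_ROW.items() if k != "currency"}
        _write_cost_csv(p, [row])
        with pytest.raises(SchemaError, match="currency"):
            load_cost_table(p)

    def test_reporting_categories_round_trip(self, tmp_path):
        """All four reporting categories survive a write-then-read cycle."""
        cats = ["planning_preparation", "clinical_equipment",
                "human_resources", "other_operating"]
        lines = [CostLine(strategy=Strategy.vision_centers, provider="P1",
                          raw_category=c, category=Category(c),
                          amount=Money(value=10.0 * (i + 1)))
                 for i, c in enumerate(cats)]
        p = tmp_path / "c.csv"
        cost_lines_to_frame(lines).to_csv(p, index=False)
        reloaded = load_cost_table(p)
        assert [l.category.value for l in reloaded] == cats
        assert [l.amount.value for l in reloaded] == [10.0, 20.0, 30.0, 40.0]

    def test_blank_category_mapped_or_rejected(self, tmp_path):
        p = tmp_path / "c.csv"
        _write_cost_csv(p, [{**BASE_ROW, "category": "", "raw_category": "rent"}])
        (line,) = load_cost_table(p, mapping={"rent": Category.other_operating})
        assert line.category is Category.other_operating
        with pytest.raises(MappingError):
            load_cost_table(p)


class TestOutcomes:
    def test_load_and_validate(self, tmp_path):
        p = tmp_path / "o.csv"
        pd.DataFrame([{
            "provider": "P1", "strategy": "eye_camps", "n_screened": 1000,
            "dx_ure": 200, "dx_cataract": 100, "dx_other": 30,
            "spectacles": 150, "surgeries": 60, "n_facilities": None,
        }]).to_csv(p, index=False)
        (ds,) = load_outcomes_table(p)
        assert ds.diagnoses.total == 330

    def test_treatments_cannot_exceed_diagnoses(self):
        with pytest.raises(ValueError, match="spectacles"):
            StrategyDataset(strategy=Strategy.eye_camps, n_screened=10,
                            diagnoses={"ure": 5, "cataract": 0, "other": 0},
                            spectacles=6)


class TestConvertToUsd:
    @pytest.mark.parametrize("inr,rate,usd", [
        (70.42, 70.42, 1.0),       # unit conversion at the market rate
        (0.0, 70.42, 0.0),
        (140_840.0, 70.42, 2_000.0),
    ])
    def test_values(self, inr, rate, usd):
        out = convert_to_usd(Money(value=inr, currency="INR"), rate)
        assert out.currency == "USD" and out.price_year == 2020
        assert out.value == pytest.approx(usd)

    def test_non_inr_rejected(self):
        with pytest.raises(UnitError):
            convert_to_usd(Money(value=1.0, currency="USD"), 70.42)

    @given(st.floats(0.01, 1e7), st.floats(1.0, 500.0))
    @settings(max_examples=100, deadline=None)
    def test_inverse_conversion_round_trip(self, value, rate):
        usd = convert_to_usd(Money(value=value, currency="INR"), rate)
        assert usd.value * rate == pytest.approx(value, rel=1e-12)


class TestAnnualizeCapital:
    def _payment_oracle(self, cost, life, rate):
        """Independent oracle: bisect for the constant payment whose
        discounted stream over the (integer) life repays the outlay."""
        from scipy.optimize import brentq

        def npv_gap(p):
            return sum(p / (1 + rate) ** t for t in range(1, int(life) + 1)) - cost

        return brentq(npv_gap, 1e-9, cost * 10)

    @pytest.mark.parametrize("cost,life,rate,expected", [
        (1000.0, 1, 0.0, 1000.0),
        (500.0, 5, 0.0, 100.0),     # straight-line limit
    ])
    def test_zero_rate_limits(self, cost, life, rate, expected):
        assert annualize_capital(cost, life, rate) == pytest.approx(expected)

    def test_matches_repayment_oracle(self):
        got = annualize_capital(1000.0, 10, 0.03)
        assert got == pytest.approx(117.23, abs=0.005)
        assert got == pytest.approx(self._payment_oracle(1000.0, 10, 0.03),
                                    rel=1e-10)

    @given(st.floats(1.0, 1e6), st.integers(1, 40), st.floats(0.001, 0.15))
    @settings(max_examples=100, deadline=None)
    def test_discounted_payments_repay_the_outlay(self, cost, life, rate):
        p = annualize_capital(cost, life, rate)
        npv = sum(p / (1 + rate) ** t for t in range(1, life + 1))
        assert npv == pytest.approx(cost, rel=1e-9)

    def test_nonpositive_life_rejected(self):
        with pytest.raises(ValueError):
            annualize_capital(100.0, 0, 0.03)

    def test_annualize_line_passthrough_for_recurrent(self):
        line = CostLine(strategy=Strategy.eye_camps, provider="P1",
                        raw_category="x", category=Category.other_operating,
                        amount=Money(value=50.0))
        assert annualize_line(line, 0.03) is line


class TestStandardizeCategories:
    def _line(self, raw, amount, strategy=Strategy.eye_camps):
        return CostLine(strategy=strategy, provider="P1", raw_category=raw,
                        amount=Money(value=amount))

    def test_empty_input(self):
        assert standardize_categories([], {}) == []

    def test_conservation_small(self):
        lines = [self._line("a", 400), self._line("b", 300), self._line("c", 200)]
        mapping = {"a": Category.human_resources, "b": Category.human_resources,
                   "c": Category.other_operating}
        out = standardize_categories(lines, mapping)
        assert sum(l.amount.value for l in out) == 900

    def test_sixteen_raw_collapse_to_four_matches_groupby(self, rng):
        """Per-category sums equal an independent pandas group-by oracle."""
        raw = [f"raw{i}" for i in range(16)]
        targets = [Category.planning_preparation, Category.clinical_equipment,
                   Category.human_resources, Category.other_operating]
        mapping = {r: targets[i % 4] for i, r in enumerate(raw)}
        lines = [self._line(r, float(a))
                 for r, a in zip(raw, rng.integers(1, 1000, size=16))]
        out = standardize_categories(lines, mapping)
        df = pd.DataFrame({"cat": [mapping[l.raw_category].value for l in lines],
                           "amt": [l.amount.value for l in lines]})
        oracle = df.groupby("cat")["amt"].sum()
        for cat in targets:
            got = sum(l.amount.value for l in out if l.category is cat)
            assert got == oracle[cat.value]

    def test_unmapped_labels_reported(self):
        with pytest.raises(MappingError, match="mystery"):
            standardize_categories([self._line("mystery", 1.0)], {"known": "other_operating"})

    @given(st.lists(st.tuples(st.sampled_from("abcdef"),
                              st.floats(0, 1e6)), min_size=1, max_size=30))
    @settings(max_examples=100, deadline=None)
    def test_total_cost_conserved(self, spec):
        mapping = {c: Category.other_operating for c in "abc"}
        mapping.update({c: Category.human_resources for c in "def"})
        lines = [self._line(r, a) for r, a in spec]
        out = standardize_categories(lines, mapping)
        assert sum(l.amount.value for l in out) == sum(a for _, a in spec)
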