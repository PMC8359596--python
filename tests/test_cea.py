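import math

import pytest

from headache_cea import (
    WHOThresholds,
    break_even_cost_factor,
    classify_who,
    compute_icer,
    generate_country,
    hlys_gained,
    per_1000_cohort,
    provider_cost_delta,
    sensitivity_sweep,
)
from headache_cea.model import CostDelta, EffectivenessResult
from headache_cea.tables import load_table_fixture


class TestComputeIcer:
    @pytest.mark.parametrize(
        "cost,hlys,expected_rounded",
        [
            (2_468_610, 1126, 2192),     # Luxembourg migraine, 1 year
            (216_491_177, 97_311, 2225), # Spain migraine, 1 year
        ],
    )
    def test_printed_migraine_cells(self, cost, hlys, expected_rounded):
        outcome = compute_icer(cost, hlys)
        assert outcome.dominance == "icer_defined"
        assert outcome.rounded == expected_rounded

    def test_cost_saving_cell_has_no_icer(self):
        outcome = compute_icer(-304_638, 776)  # MOH cell printed "(cost saved)"
        assert outcome.dominance == "cost_saving"
        assert outcome.icer is None and outcome.rounded is None

    def test_zero_cost_with_gain_is_cost_saving_boundary(self):
        assert compute_icer(0.0, 100.0).dominance == "cost_saving"

    def test_no_gain(self):
        assert compute_icer(500.0, 0.0).dominance == "no_gain"
        assert compute_icer(-500.0, -1.0).dominance == "no_gain"

    def test_non_finite_inputs_rejected(self):
        with pytest.raises(ValueError, match="non-finite"):
            compute_icer(math.nan, 10)
        with pytest.raises(ValueError, match="non-finite"):
            compute_icer(10, math.inf)

    def test_full_precision_retained(self):
        outcome = compute_icer(10.0, 3.0)
        assert outcome.icer == pytest.approx(10 / 3)
        assert outcome.rounded == 3

    def test_rounding_half_away_from_zero(self):
        assert compute_icer(5.0, 2.0).rounded == 3  # 2.5 -> 3


class TestClassifyWho:
    thresholds = WHOThresholds(gdp_per_capita=10_000)

    def test_highly_cost_effective(self):
        assert classify_who(2192, self.thresholds) == "highly_cost_effective"

    def test_between_one_and_three_gdp(self):
        assert classify_who(15_000, self.thresholds) == "cost_effective"

    def test_boundaries_are_strict(self):
        assert classify_who(10_000, self.thresholds) == "cost_effective"
        assert classify_who(30_000, self.thresholds) == "not_cost_effective"

    def test_dominance_overrides(self):
        assert classify_who(compute_icer(-1.0, 5.0), self.thresholds) == "dominant"

    def test_no_gain_is_never_cost_effective(self):
        assert classify_who(compute_icer(1.0, 0.0), self.thresholds) == "not_cost_effective"

    def test_monotone_in_icer(self):
        order = {"highly_cost_effective": 0, "cost_effective": 1, "not_cost_effective": 2}
        cats = [
            order[classify_who(icer, self.thresholds)]
            for icer in (1, 5_000, 9_999.99, 10_000, 29_999.99, 30_000, 1e6)
        ]
        assert cats == sorted(cats)


class TestSensitivity:
    def test_break_even_factor_ratio_identity(self):
        # base ICER 1315; threshold 131,500 euros/HLY -> factor exactly 100
        thresholds = WHOThresholds(gdp_per_capita=131_500 / 3)
        outcome = compute_icer(1315.0, 1.0)
        assert break_even_cost_factor(outcome, thresholds) == pytest.approx(100.0)

    def test_identity_factor_reproduces_base_classification(self):
        thresholds = WHOThresholds(gdp_per_capita=10_000)
        result = sensitivity_sweep(2_468_610, 1126, [1.0], [1.0], thresholds)
        assert set(result.table["who_category"]) == {"highly_cost_effective"}

    @pytest.mark.parametrize("factor", [0.5, 1, 2, 10, 100])
    def test_cost_inflation_equals_hly_deflation(self, factor):
        thresholds = WHOThresholds(gdp_per_capita=10_000)
        result = sensitivity_sweep(2_468_610, 1126, [factor], [factor], thresholds)
        cost_row = result.table[result.table["kind"] == "cost"].iloc[0]
        hly_row = result.table[result.table["kind"] == "hly"].iloc[0]
        assert cost_row["icer"] == pytest.approx(hly_row["icer"], rel=1e-12)
        assert cost_row["who_category"] == hly_row["who_category"]

    def test_dominant_cells_break_even_at_infinity(self):
        thresholds = WHOThresholds(gdp_per_capita=10_000)
        result = sensitivity_sweep(-100.0, 10.0, [1.0], [1.0], thresholds)
        assert math.isinf(result.break_even_cost_factor)

    def test_non_positive_factor_rejected(self):
        thresholds = WHOThresholds(gdp_per_capita=10_000)
        with pytest.raises(ValueError, match="positive"):
            sensitivity_sweep(1.0, 1.0, [0.0], [], thresholds)

    def test_break_even_marks_the_category_boundary(self):
        thresholds = WHOThresholds(gdp_per_capita=10_000)
        base = compute_icer(2_468_610, 1126)
        factor = break_even_cost_factor(base, thresholds)
        just_below = classify_who(base.icer * factor * (1 - 1e-9), thresholds)
        just_above = classify_who(base.icer * factor * (1 + 1e-9), thresholds)
        assert just_below == "cost_effective"
        assert just_above == "not_cost_effective"


def _fixture_pair(row):
    cost = CostDelta(
        country_id=row.country_id,
        headache_type=row.headache_type,
        horizon_years=row.horizon_years,
        perspective="provider",
        additional_cost=row.additional_cost_provider,
    )
    eff = EffectivenessResult(
        country_id=row.country_id,
        headache_type=row.headache_type,
        horizon_years=row.horizon_years,
        hlys_gained=row.hlys_gained,
        effective_fraction_current=0.1,
        effective_fraction_achieved=0.4,
    )
    return cost, eff


class TestPer1000Cohort:
    def test_identity_at_exactly_1000_patients(self):
        row = load_table_fixture().cell("Luxembourg", "migraine", 1)
        cost, eff = _fixture_pair(row)
        scaled_cost, scaled_eff = per_1000_cohort((cost, eff), 1000)
        assert scaled_cost.additional_cost == pytest.approx(cost.additional_cost)
        assert scaled_eff.hlys_gained == pytest.approx(eff.hlys_gained)

    def test_luxembourg_scaling_preserves_icer(self):
        row = load_table_fixture().cell("Luxembourg", "migraine", 1)
        cost, eff = _fixture_pair(row)
        scaled_cost, scaled_eff = per_1000_cohort((cost, eff), row.n_patients)
        # extensive quantities shrink by 124.713; the ICER is untouched
        assert scaled_cost.additional_cost == pytest.approx(2_468_610 / 124.713)
        assert compute_icer(
            scaled_cost.additional_cost, scaled_eff.hlys_gained
        ).rounded == 2192

    def test_icer_invariant_for_all_fixture_cells(self):
        for row in load_table_fixture().rows:
            cost, eff = _fixture_pair(row)
            scaled_cost, scaled_eff = per_1000_cohort((cost, eff), row.n_patients)
            before = compute_icer(cost.additional_cost, eff.hlys_gained)
            after = compute_icer(scaled_cost.additional_cost, scaled_eff.hlys_gained)
            assert before.dominance == after.dominance
            if before.icer is not None:
                assert after.icer == pytest.approx(before.icer, rel=1e-12)

    def test_rejects_non_positive_cohort(self):
        row = load_table_fixture().rows[0]
        with pytest.raises(ValueError, match="n_patients"):
            per_1000_cohort(_fixture_pair(row), 0)

    def test_generated_cell_scaling_includes_components(self):
        country = generate_country("small-high-wage", 2)
        eff = hlys_gained(country, "moh", horizon_years=5)
        cost = provider_cost_delta(country, "moh", horizon_years=5)
        n = country.n_patients("moh")
        scaled_cost, _ = per_1000_cohort((cost, eff), n)
        for key, value in cost.components.items():
            assert scaled_cost.components[key] == pytest.approx(
                value * 1000 / n, rel=1e-12
            )
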