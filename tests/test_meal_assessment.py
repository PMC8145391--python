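"""Portion aggregation and deviation scoring."""

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mealscope.food_model import CatalogError, Ingredient, Recipe
from mealscope.guideline_engine import ThresholdSpec
from mealscope.meal_assessment import (
    PortionProfile,
    aggregate_portion,
    cohort_mean,
    evaluate,
    percent_deviation,
)

from conftest import build_catalog, make_item


def recipe_of(*ingredients, servings=1, anchor=None):
    ings = tuple(Ingredient(item_id=i, amount_g=a) for i, a in ingredients)
    return Recipe(
        recipe_id="r",
        name="r",
        servings=servings,
        ingredients=ings,
        anchor_protein=anchor or ingredients[0][0],
    )


class TestAggregation:
    def test_single_ingredient_identity_scale(self):
        cat = build_catalog(make_item("fish", {"protein_fish_low_co2e"}, protein=10.0))
        profile = aggregate_portion(recipe_of(("fish", 100)), cat)
        assert profile.protein == pytest.approx(10.0)

    def test_two_ingredients_two_servings(self):
        cat = build_catalog(
            make_item("meat", {"protein_red_meat"}, protein=20.0),
            make_item("beans", {"protein_plant"}, protein=4.0),
        )
        profile = aggregate_portion(
            recipe_of(("meat", 100), ("beans", 50), servings=2), cat
        )
        assert profile.protein == pytest.approx((20 + 2) / 2)

    def test_co2e_per_portion(self):
        cat = build_catalog(make_item("beef", {"protein_red_meat"}, co2e=26.0))
        profile = aggregate_portion(recipe_of(("beef", 250)), cat)
        assert profile.co2e == pytest.approx(6.5)

    def test_wholegrain_uses_mass_fraction(self):
        cat = build_catalog(make_item("bread", {"grain_whole"}, wg=0.6))
        profile = aggregate_portion(recipe_of(("bread", 200), servings=2), cat)
        assert profile.wholegrain == pytest.approx(60.0)

    def test_missing_profile_names_ingredient(self, swedish_catalog):
        with pytest.raises(CatalogError, match="durian"):
            aggregate_portion(recipe_of(("durian", 100)), swedish_catalog)

    def test_merged_recipe_profile_is_sum_of_parts(self, swedish_catalog):
        a = recipe_of(("minced_beef", 300), ("spaghetti", 200), servings=2)
        b = recipe_of(("onion", 100), ("rapeseed_oil", 30), servings=2, anchor="onion")
        merged = recipe_of(
            ("minced_beef", 300), ("spaghetti", 200), ("onion", 100),
            ("rapeseed_oil", 30), servings=2,
        )
        pa = aggregate_portion(a, swedish_catalog)
        pb = aggregate_portion(b, swedish_catalog)
        pm = aggregate_portion(merged, swedish_catalog)
        for comp in ("energy", "protein", "fat", "fiber", "co2e", "fruit_veg"):
            assert pm.component(comp) == pytest.approx(
                pa.component(comp) + pb.component(comp)
            )

    @settings(max_examples=50, derandomize=True)
    @given(factor=st.integers(2, 10))
    def test_scaling_amounts_and_servings_leaves_portion_unchanged(self, factor):
        cat = build_catalog(
            make_item("beef", {"protein_red_meat"}, co2e=26.0, fat=18.0, sat=8.0),
            make_item("rice", {"grain_refined"}, energy=350.0),
        )
        base = recipe_of(("beef", 400), ("rice", 300), servings=4)
        scaled = recipe_of(
            ("beef", 400 * factor), ("rice", 300 * factor), servings=4 * factor
        )
        p1, p2 = aggregate_portion(base, cat), aggregate_portion(scaled, cat)
        for comp in ("energy", "protein", "fat", "saturated_fat", "co2e"):
            assert p1.component(comp) == pytest.approx(p2.component(comp))


class TestPercentDeviation:
    @pytest.mark.parametrize(
        "value,spec,expected",
        [
            # climate impact of the original dish cohort vs the meal budget
            (1.68, ThresholdSpec(kind="max_only", high=0.5, reference=0.5), 236),
            # fat vs the 20-33 g range midpoint
            (44.1, ThresholdSpec(kind="range", low=20, high=33, reference=26.5), 66),
            # below-minimum fiber and fruit+veg in the original dishes
            (4.2, ThresholdSpec(kind="min_only", low=7.5, reference=7.5), -44),
            (60.9, ThresholdSpec(kind="min_only", low=150, reference=150), -59),
            # altered dishes exceed the minima
            (17.4, ThresholdSpec(kind="min_only", low=7.5, reference=7.5), 132),
            (196.7, ThresholdSpec(kind="min_only", low=150, reference=150), 31),
            (45.1, ThresholdSpec(kind="min_only", low=21, reference=21), 115),
            # altered saturated fat below the printed 9 g cap
            (5.1, ThresholdSpec(kind="max_only", high=9, reference=9), -43),
        ],
    )
    def test_published_deviation_percentages(self, value, spec, expected):
        assert percent_deviation(value, spec) == expected

    def test_value_at_reference_is_zero(self):
        spec = ThresholdSpec(kind="range", low=10, high=20, reference=15)
        assert percent_deviation(15, spec) == 0

    def test_zero_reference_rejected(self):
        with pytest.raises(ValueError):
            percent_deviation(1.0, ThresholdSpec(kind="min_only", low=0, reference=0))

    @settings(max_examples=100, derandomize=True)
    @given(
        value=st.floats(0.01, 1000),
        reference=st.floats(0.01, 1000),
    )
    def test_sign_convention(self, value, reference):
        spec = ThresholdSpec(kind="min_only", low=reference, reference=reference)
        pct = percent_deviation(value, spec)
        if value > reference * 1.01:
            assert pct >= 0
        elif value < reference * 0.99:
            assert pct <= 0


class TestEvaluate:
    def test_profile_at_every_reference_is_compliant(self, paper_guideline):
        g = paper_guideline
        profile = PortionProfile(
            energy=g.energy.reference,
            protein=g.protein.reference,
            fat=g.fat.reference,
            saturated_fat=g.saturated_fat.reference,
            fiber=g.fiber.reference,
            wholegrain=g.wholegrain.reference,
            fruit_veg=g.fruit_veg.reference,
            co2e=g.co2e.reference,
        )
        report = evaluate(profile, g)
        assert report.overall_compliant
        assert all(d.signed_pct == 0 for d in report.components.values())

    def test_cohort_mean_style_profile_flags_co2e(self, paper_guideline):
        profile = PortionProfile(
            energy=735, protein=27, fat=44.1, saturated_fat=17.7,
            fiber=4.2, wholegrain=0, fruit_veg=60.9, co2e=1.68,
        )
        report = evaluate(profile, paper_guideline)
        assert not report.overall_compliant
        assert "co2e" in report.violations()
        assert report.components["co2e"].signed_pct == 236

    def test_fiber_far_above_minimum_is_within_bounds(self, paper_guideline):
        profile = PortionProfile(
            energy=735, protein=27, fat=26.5, saturated_fat=5,
            fiber=17.4, wholegrain=45, fruit_veg=196.7, co2e=0.4,
        )
        report = evaluate(profile, paper_guideline)
        fiber = report.components["fiber"]
        assert fiber.signed_pct == 132
        assert fiber.within_bounds
        assert report.overall_compliant


class TestCohortMean:
    def test_single_profile_is_identity(self):
        p = PortionProfile(energy=1, protein=2, fat=3, saturated_fat=1,
                           fiber=4, wholegrain=5, fruit_veg=6, co2e=0.7)
        assert cohort_mean([p]) == p

    def test_componentwise_mean(self):
        a = PortionProfile(energy=0, protein=0, fat=0, saturated_fat=0,
                           fiber=0, wholegrain=0, fruit_veg=0, co2e=1.0)
        b = PortionProfile(energy=0, protein=0, fat=0, saturated_fat=0,
                           fiber=0, wholegrain=0, fruit_veg=0, co2e=2.0)
        assert cohort_mean([a, b]).co2e == pytest.approx(1.5)

    def test_empty_cohort_rejected(self):
        with pytest.raises(ValueError):
            cohort_mean([])

    def test_fixture_mean_matches_brute_force(self, fixture_set):
        profiles = [
            aggregate_portion(r, fixture_set.catalog) for r in fixture_set.recipes
        ]
        mean = cohort_mean(profiles)
        for comp in ("energy", "protein", "fat", "co2e", "fiber"):
            expected = sum(p.component(comp) for p in profiles) / len(profiles)
            assert mean.component(comp) == pytest.approx(expected)
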