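"""Substitution rules and the greedy repair loop."""

import pytest

from mealscope.alteration_engine import (
    AddIngredient,
    AlterationRule,
    ReplaceByRole,
    apply_rule,
    default_ruleset,
    repair,
    replay,
)
from mealscope.food_model import Ingredient, Recipe
from mealscope.meal_assessment import aggregate_portion

from conftest import build_catalog, make_item


@pytest.fixture(scope="module")
def plantable_catalog():
    return build_catalog(
        make_item("beef", {"protein_red_meat"}, protein=20.0, co2e=26.0,
                  substitutes=(("soy", "plant_protein"),)),
        make_item("soy", {"protein_plant"}, protein=16.0, fiber=5.0, co2e=1.1),
        make_item("rice", {"grain_refined"}, energy=350.0),
    )


def beef_recipe(amount=400.0, servings=1):
    return Recipe(
        recipe_id="stew",
        name="Stew",
        servings=servings,
        ingredients=(
            Ingredient(item_id="beef", amount_g=amount),
            Ingredient(item_id="rice", amount_g=200.0),
        ),
        anchor_protein="beef",
    )


class TestRuleset:
    def test_six_rules_first_triggered_by_climate(self):
        rules = default_ruleset()
        assert len(rules) == 6
        assert rules[0].triggers == ("co2e:above",)

    def test_meat_replacement_is_full_not_partial(self, plantable_catalog):
        rule = default_ruleset()[0]
        recipe = beef_recipe(400.0)
        altered, entries = apply_rule(recipe, rule, plantable_catalog)
        assert altered.amount_of("beef") == 0.0
        (entry,) = entries
        assert entry.old_amount_g == 400.0

    def test_wholegrain_swap_preserves_total_grain_grams(self, swedish_catalog):
        rule = next(
            r for r in default_ruleset() if r.rule_id == "wholegrain_swap_or_add"
        )
        recipe = Recipe(
            recipe_id="pasta",
            name="Pasta",
            servings=2,
            ingredients=(
                Ingredient(item_id="minced_beef", amount_g=300),
                Ingredient(item_id="spaghetti", amount_g=250),
            ),
            anchor_protein="minced_beef",
        )
        altered, _ = apply_rule(recipe, rule, swedish_catalog)
        assert altered.amount_of("wholegrain_spaghetti") == 250
        assert altered.amount_of("spaghetti") == 0


class TestApplyRule:
    def test_protein_equalized_amount(self, plantable_catalog):
        # 400 g at 20 g/100 g protein -> substitute at 16 g/100 g needs 500 g
        rule = default_ruleset()[0]
        altered, entries = apply_rule(beef_recipe(400.0), rule, plantable_catalog)
        assert altered.amount_of("soy") == pytest.approx(500.0)
        assert entries[0].new_amount_g == pytest.approx(500.0)

    def test_protein_per_portion_preserved(self, plantable_catalog):
        rule = default_ruleset()[0]
        recipe = beef_recipe(400.0, servings=4)
        before = aggregate_portion(recipe, plantable_catalog).protein
        altered, _ = apply_rule(recipe, rule, plantable_catalog)
        after = aggregate_portion(altered, plantable_catalog).protein
        assert after == pytest.approx(before, rel=0.05)

    def test_co2e_strictly_decreases_when_substitute_is_cleaner(self, plantable_catalog):
        rule = default_ruleset()[0]
        recipe = beef_recipe(400.0, servings=4)
        before = aggregate_portion(recipe, plantable_catalog).co2e
        altered, _ = apply_rule(recipe, rule, plantable_catalog)
        assert aggregate_portion(altered, plantable_catalog).co2e < before

    def test_rule_without_matching_category_skips(self, plantable_catalog):
        dairy_rule = next(
            r for r in default_ruleset() if r.rule_id == "swap_full_fat_dairy"
        )
        assert apply_rule(beef_recipe(), dairy_rule, plantable_catalog) is None

    def test_input_recipe_never_mutated(self, plantable_catalog):
        rule = default_ruleset()[0]
        recipe = beef_recipe(400.0)
        apply_rule(recipe, rule, plantable_catalog)
        assert recipe.amount_of("beef") == 400.0
        assert recipe.provenance == "original"
        assert recipe.trace == ()

    def test_double_addition_raises_fruit_veg_by_step_over_servings(self, swedish_catalog):
        rule = AlterationRule(
            rule_id="add",
            triggers=("fruit_veg:below",),
            action=AddIngredient(category="vegetable", step_g=50.0),
            max_applications=5,
        )
        recipe = Recipe(
            recipe_id="plain",
            name="Plain",
            servings=4,
            ingredients=(Ingredient(item_id="minced_beef", amount_g=400),),
            anchor_protein="minced_beef",
        )
        before = aggregate_portion(recipe, swedish_catalog).fruit_veg
        once, _ = apply_rule(recipe, rule, swedish_catalog)
        twice, _ = apply_rule(once, rule, swedish_catalog)
        after = aggregate_portion(twice, swedish_catalog).fruit_veg
        assert after - before == pytest.approx(100.0 / 4)


class TestRepair:
    def test_compliant_recipe_untouched(self, swedish_catalog, paper_guideline):
        # a dish engineered to sit inside every bound
        recipe = Recipe(
            recipe_id="ok",
            name="Ok",
            servings=1,
            ingredients=(
                Ingredient(item_id="soy_mince", amount_g=130),
                Ingredient(item_id="wholegrain_couscous", amount_g=90),
                Ingredient(item_id="carrot", amount_g=160),
                Ingredient(item_id="rapeseed_oil", amount_g=15),
            ),
            anchor_protein="soy_mince",
        )
        result = repair(recipe, paper_guideline, swedish_catalog)
        assert result.status == "compliant"
        assert result.trace == ()
        assert result.iterations == 1
        assert result.recipe == recipe

    def test_unsatisfiable_without_substitutes(self, paper_guideline):
        catalog = build_catalog(
            make_item("beef", {"protein_red_meat"}, protein=20.0, co2e=26.0)
        )
        recipe = Recipe(
            recipe_id="stew",
            name="Stew",
            servings=1,
            ingredients=(Ingredient(item_id="beef", amount_g=500),),
            anchor_protein="beef",
        )
        result = repair(recipe, paper_guideline, catalog)
        assert result.status == "infeasible"

    def test_bolognese_trace_contains_documented_edit_types(
        self, fixture_set, paper_guideline
    ):
        bolognese = {r.recipe_id: r for r in fixture_set.recipes}["bolognese"]
        result = repair(bolognese, paper_guideline, fixture_set.catalog)
        assert result.status == "compliant"
        rules_used = {t.rule_id for t in result.trace}
        assert "replace_meat_with_plant" in rules_used
        assert "wholegrain_swap_or_add" in rules_used
        assert "add_fruit_veg" in rules_used
        assert result.recipe.provenance == "altered"

    def test_all_ten_fixture_dishes_become_compliant(
        self, fixture_set, paper_guideline
    ):
        results = [
            repair(r, paper_guideline, fixture_set.catalog) for r in fixture_set.recipes
        ]
        assert all(res.status == "compliant" for res in results)
        assert all(res.report.overall_compliant for res in results)

    def test_trace_replays_to_final_recipe(self, fixture_set, paper_guideline):
        taco = {r.recipe_id: r for r in fixture_set.recipes}["taco"]
        result = repair(taco, paper_guideline, fixture_set.catalog)
        replayed = replay(taco, result.recipe.trace, fixture_set.catalog)
        assert replayed == result.recipe

    def test_meat_replacement_steps_strictly_reduce_co2e(
        self, fixture_set, paper_guideline
    ):
        catalog = fixture_set.catalog
        for recipe in fixture_set.recipes:
            result = repair(recipe, paper_guideline, catalog)
            replacement_rules = {
                "replace_meat_with_plant",
                "swap_high_impact_seafood",
            }
            current = recipe
            for rule_id in result.recipe.trace:
                rule = next(r for r in default_ruleset() if r.rule_id == rule_id)
                before = aggregate_portion(current, catalog).co2e
                current, _ = apply_rule(current, rule, catalog)
                after = aggregate_portion(current, catalog).co2e
                if rule_id in replacement_rules:
                    assert after < before, (recipe.recipe_id, rule_id)
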