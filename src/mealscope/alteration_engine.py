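"""Rule-based repair of non-compliant dishes.

The published alteration of the ten dishes was a manual exercise; here it
is encoded as a deterministic greedy loop over priority-ordered
substitution rules, so every edit is reproducible and auditable:

1. a climate-budget violation fully replaces red/processed-meat and
   poultry ingredients with a plant-based protein (reducing the meat is
   not enough to reach the meal budget while keeping protein adequate —
   the replacement is protein-equalized, so the substitute amount is
   ``old_amount × old_protein / new_protein``);
2. a remaining climate violation swaps high-impact seafood (salmon,
   shrimp) for low-impact seafood (mussels, clams), again
   protein-equalized;
3. fat/saturated-fat/climate violations swap full-fat dairy for
   plant-based (or, failing that, low-fat) dairy gram-for-gram;
4. a wholegrain shortfall swaps refined grains for their wholegrain
   counterparts gram-for-gram — or, when the dish has no grain at all
   (potato dishes), adds a wholegrain item in fixed steps;
5. fiber or fruit+vegetable shortfalls add fiber-dense, low-energy
   vegetables in fixed gram steps;
6. residual fat or energy excess scales down added fats/oils.

Rules trigger on a violated component *in a direction* (e.g. fat above
its range); a below-range fat or protein content has no repair rule and
the dish is reported infeasible rather than silently bent. The loop stops
as soon as the dish evaluates compliant, or when no rule applies or the
iteration cap is reached (status ``infeasible`` — never an exception).
"""

from __future__ import annotations

from typing import Literal, Sequence, Union

from pydantic import BaseModel, ConfigDict, Field

from .food_model import Catalog, Ingredient, Recipe
from .guideline_engine import MealGuideline
from .meal_assessment import DeviationReport, aggregate_portion, evaluate

__all__ = [
    "AddIngredient",
    "AlterationRule",
    "PRIORITY_ORDER",
    "ReduceIngredient",
    "RepairResult",
    "ReplaceByRole",
    "SwapWholegrain",
    "TraceEntry",
    "apply_rule",
    "default_ruleset",
    "repair",
    "replay",
]

#: Components in repair priority order; direction-qualified triggers
#: ("co2e:above", "fiber:below", ...) are matched against this order.
PRIORITY_ORDER: tuple[str, ...] = (
    "co2e",
    "saturated_fat",
    "fat",
    "wholegrain",
    "fiber",
    "fruit_veg",
    "energy",
    "protein",
)


class ReplaceByRole(BaseModel):
    """Replace every ingredient in the given categories with its catalog
    substitute for ``role`` (falling back to ``fallback_role``)."""

    model_config = ConfigDict(frozen=True)

    kind: Literal["replace"] = "replace"
    categories: tuple[str, ...]
    role: str
    fallback_role: str | None = None
    equalize_protein: bool = False


class SwapWholegrain(BaseModel):
    """Swap refined grains for their wholegrain substitutes gram-for-gram;
    when the recipe has no swappable refined grain, add ``step_g`` of the
    most fiber-dense wholegrain catalog item instead."""

    model_config = ConfigDict(frozen=True)

    kind: Literal["swap_wholegrain"] = "swap_wholegrain"
    step_g: float = Field(default=50.0, gt=0)


class AddIngredient(BaseModel):
    """Add ``step_g`` grams (whole batch, not per portion) of the most
    fiber-dense item of ``category`` (ties: lower energy, then item id)."""

    model_config = ConfigDict(frozen=True)

    kind: Literal["add"] = "add"
    category: str
    step_g: float = Field(gt=0)


class ReduceIngredient(BaseModel):
    """Scale every ingredient of ``category`` down by ``step_fraction``."""

    model_config = ConfigDict(frozen=True)

    kind: Literal["reduce"] = "reduce"
    category: str
    step_fraction: float = Field(gt=0, le=1)


Action = Union[ReplaceByRole, SwapWholegrain, AddIngredient, ReduceIngredient]


class AlterationRule(BaseModel):
    model_config = ConfigDict(frozen=True)

    rule_id: str
    triggers: tuple[str, ...]
    action: Action = Field(discriminator="kind")
    max_applications: int = Field(default=3, ge=1)


class TraceEntry(BaseModel):
    model_config = ConfigDict(frozen=True)

    rule_id: str
    item_id: str
    new_item_id: str
    old_amount_g: float
    new_amount_g: float


class RepairResult(BaseModel):
    model_config = ConfigDict(frozen=True)

    status: Literal["compliant", "infeasible"]
    recipe: Recipe
    report: DeviationReport
    trace: tuple[TraceEntry, ...]
    iterations: int


def default_ruleset() -> tuple[AlterationRule, ...]:
    """The six default repair rules, in priority order (see module docs)."""
    return (
        AlterationRule(
            rule_id="replace_meat_with_plant",
            triggers=("co2e:above",),
            action=ReplaceByRole(
                categories=(
                    "protein_red_meat",
                    "protein_processed_meat",
                    "protein_poultry",
                ),
                role="plant_protein",
                equalize_protein=True,
            ),
            max_applications=3,
        ),
        AlterationRule(
            rule_id="swap_high_impact_seafood",
            triggers=("co2e:above",),
            action=ReplaceByRole(
                categories=("protein_fish_high_co2e",),
                role="low_co2e_seafood",
                equalize_protein=True,
            ),
            max_applications=3,
        ),
        AlterationRule(
            rule_id="swap_full_fat_dairy",
            triggers=("co2e:above", "saturated_fat:above", "fat:above"),
            action=ReplaceByRole(
                categories=("dairy_full_fat",),
                role="plant_dairy",
                fallback_role="low_fat_dairy",
            ),
            max_applications=3,
        ),
        AlterationRule(
            rule_id="wholegrain_swap_or_add",
            triggers=("wholegrain:below",),
            action=SwapWholegrain(step_g=50.0),
            max_applications=10,
        ),
        AlterationRule(
            rule_id="add_fruit_veg",
            triggers=("fiber:below", "fruit_veg:below"),
            action=AddIngredient(category="vegetable", step_g=50.0),
            max_applications=30,
        ),
        AlterationRule(
            rule_id="reduce_added_fat",
            triggers=("fat:above", "energy:above"),
            action=ReduceIngredient(category="fat_oil", step_fraction=0.25),
            max_applications=6,
        ),
    )


# ---------------------------------------------------------------------------
# Rule application
# ---------------------------------------------------------------------------


def _with_edit(
    recipe: Recipe, rule_id: str, ingredients: Sequence[Ingredient]
) -> Recipe:
    return recipe.model_copy(
        update={
            "ingredients": tuple(ingredients),
            "provenance": "altered",
            "trace": recipe.trace + (rule_id,),
        }
    )


def _merge(ingredients: list[Ingredient]) -> list[Ingredient]:
    merged: dict[str, float] = {}
    order: list[str] = []
    for ing in ingredients:
        if ing.item_id not in merged:
            order.append(ing.item_id)
            merged[ing.item_id] = 0.0
        merged[ing.item_id] += ing.amount_g
    return [Ingredient(item_id=i, amount_g=merged[i]) for i in order]


def _apply_replace(
    recipe: Recipe, rule: AlterationRule, action: ReplaceByRole, catalog: Catalog
) -> tuple[Recipe, list[TraceEntry]] | None:
    cats = set(action.categories)
    new_ingredients: list[Ingredient] = []
    entries: list[TraceEntry] = []
    for ing in recipe.ingredients:
        item = catalog.item(ing.item_id)
        if not (item.categories & cats):
            new_ingredients.append(ing)
            continue
        sub_id = item.substitute_for_role(action.role)
        if sub_id is None and action.fallback_role:
            sub_id = item.substitute_for_role(action.fallback_role)
        if sub_id is None:
            new_ingredients.append(ing)
            continue
        if action.equalize_protein:
            old_p = catalog.nutrient(ing.item_id).protein_g
            new_p = catalog.nutrient(sub_id).protein_g
            if new_p <= 0:
                new_ingredients.append(ing)
                continue
            new_amount = ing.amount_g * old_p / new_p
        else:
            new_amount = ing.amount_g
        new_ingredients.append(Ingredient(item_id=sub_id, amount_g=new_amount))
        entries.append(
            TraceEntry(
                rule_id=rule.rule_id,
                item_id=ing.item_id,
                new_item_id=sub_id,
                old_amount_g=ing.amount_g,
                new_amount_g=new_amount,
            )
        )
    if not entries:
        return None
    return _with_edit(recipe, rule.rule_id, _merge(new_ingredients)), entries


def _pick_fiber_dense(catalog: Catalog, category: str) -> str | None:
    candidates = [
        it for it in catalog.items_in_category(category) if it.excluded_as == "none"
    ]
    if not candidates:
        return None
    return min(
        candidates,
        key=lambda it: (
            -catalog.nutrient(it.item_id).fiber_g,
            catalog.nutrient(it.item_id).energy_kcal,
            it.item_id,
        ),
    ).item_id


def _apply_swap_wholegrain(
    recipe: Recipe, rule: AlterationRule, action: SwapWholegrain, catalog: Catalog
) -> tuple[Recipe, list[TraceEntry]] | None:
    new_ingredients: list[Ingredient] = []
    entries: list[TraceEntry] = []
    for ing in recipe.ingredients:
        item = catalog.item(ing.item_id)
        sub_id = (
            item.substitute_for_role("wholegrain")
            if "grain_refined" in item.categories
            else None
        )
        if sub_id is None:
            new_ingredients.append(ing)
            continue
        new_ingredients.append(Ingredient(item_id=sub_id, amount_g=ing.amount_g))
        entries.append(
            TraceEntry(
                rule_id=rule.rule_id,
                item_id=ing.item_id,
                new_item_id=sub_id,
                old_amount_g=ing.amount_g,
                new_amount_g=ing.amount_g,
            )
        )
    if entries:
        return _with_edit(recipe, rule.rule_id, _merge(new_ingredients)), entries
    # No refined grain to swap: add a wholegrain item instead.
    add_id = _pick_fiber_dense(catalog, "grain_whole")
    if add_id is None:
        return None
    return _apply_addition(recipe, rule, add_id, action.step_g)


def _apply_addition(
    recipe: Recipe, rule: AlterationRule, item_id: str, step_g: float
) -> tuple[Recipe, list[TraceEntry]]:
    old_amount = recipe.amount_of(item_id)
    ingredients = list(recipe.ingredients)
    if old_amount > 0:
        ingredients = [
            Ingredient(item_id=i.item_id, amount_g=i.amount_g + step_g)
            if i.item_id == item_id
            else i
            for i in ingredients
        ]
    else:
        ingredients.append(Ingredient(item_id=item_id, amount_g=step_g))
    entry = TraceEntry(
        rule_id=rule.rule_id,
        item_id=item_id,
        new_item_id=item_id,
        old_amount_g=old_amount,
        new_amount_g=old_amount + step_g,
    )
    return _with_edit(recipe, rule.rule_id, ingredients), [entry]


def _apply_add(
    recipe: Recipe, rule: AlterationRule, action: AddIngredient, catalog: Catalog
) -> tuple[Recipe, list[TraceEntry]] | None:
    item_id = _pick_fiber_dense(catalog, action.category)
    if item_id is None:
        return None
    return _apply_addition(recipe, rule, item_id, action.step_g)


def _apply_reduce(
    recipe: Recipe, rule: AlterationRule, action: ReduceIngredient, catalog: Catalog
) -> tuple[Recipe, list[TraceEntry]] | None:
    new_ingredients: list[Ingredient] = []
    entries: list[TraceEntry] = []
    for ing in recipe.ingredients:
        item = catalog.item(ing.item_id)
        if action.category not in item.categories:
            new_ingredients.append(ing)
            continue
        new_amount = ing.amount_g * (1.0 - action.step_fraction)
        if new_amount <= 0:
            new_ingredients.append(ing)
            continue
        new_ingredients.append(Ingredient(item_id=ing.item_id, amount_g=new_amount))
        entries.append(
            TraceEntry(
                rule_id=rule.rule_id,
                item_id=ing.item_id,
                new_item_id=ing.item_id,
                old_amount_g=ing.amount_g,
                new_amount_g=new_amount,
            )
        )
    if not entries:
        return None
    return _with_edit(recipe, rule.rule_id, new_ingredients), entries


def apply_rule(
    recipe: Recipe, rule: AlterationRule, catalog: Catalog
) -> tuple[Recipe, list[TraceEntry]] | None:
    """Apply one rule to a recipe; returns the edited copy and its trace
    entries, or ``None`` (skip signal) when the rule finds nothing to edit.
    The input recipe is never modified."""
    action = rule.action
    if isinstance(action, ReplaceByRole):
        return _apply_replace(recipe, rule, action, catalog)
    if isinstance(action, SwapWholegrain):
        return _apply_swap_wholegrain(recipe, rule, action, catalog)
    if isinstance(action, AddIngredient):
        return _apply_add(recipe, rule, action, catalog)
    return _apply_reduce(recipe, rule, action, catalog)


# ---------------------------------------------------------------------------
# Repair loop
# ---------------------------------------------------------------------------


def _ordered_violations(report: DeviationReport, guideline: MealGuideline) -> list[str]:
    keys: list[str] = []
    for component in PRIORITY_ORDER:
        dev = report.components[component]
        if dev.within_bounds:
            continue
        spec = guideline.spec(component)
        if spec.kind == "min_only":
            direction = "below"
        elif spec.kind == "max_only":
            direction = "above"
        else:
            direction = "above" if dev.value > spec.high else "below"  # type: ignore[operator]
        keys.append(f"{component}:{direction}")
    return keys


def repair(
    recipe: Recipe,
    guideline: MealGuideline,
    catalog: Catalog,
    ruleset: Sequence[AlterationRule] | None = None,
    max_iter: int = 50,
) -> RepairResult:
    """Greedy repair: evaluate, and while non-compliant apply the first
    rule whose trigger matches the highest-priority violation. Guaranteed
    to terminate; infeasibility is a status, not an exception."""
    if max_iter < 1:
        raise ValueError("max_iter must be >= 1")
    ruleset = tuple(ruleset) if ruleset is not None else default_ruleset()
    current = recipe
    trace: list[TraceEntry] = []
    applications: dict[str, int] = {}
    iterations = 0
    for _ in range(max_iter):
        iterations += 1
        report = evaluate(aggregate_portion(current, catalog), guideline)
        if report.overall_compliant:
            return RepairResult(
                status="compliant",
                recipe=current,
                report=report,
                trace=tuple(trace),
                iterations=iterations,
            )
        applied = False
        for violation in _ordered_violations(report, guideline):
            for rule in ruleset:
                if violation not in rule.triggers:
                    continue
                if applications.get(rule.rule_id, 0) >= rule.max_applications:
                    continue
                outcome = apply_rule(current, rule, catalog)
                if outcome is None:
                    continue
                current, entries = outcome
                trace.extend(entries)
                applications[rule.rule_id] = applications.get(rule.rule_id, 0) + 1
                applied = True
                break
            if applied:
                break
        if not applied:
            break
    report = evaluate(aggregate_portion(current, catalog), guideline)
    status = "compliant" if report.overall_compliant else "infeasible"
    return RepairResult(
        status=status,
        recipe=current,
        report=report,
        trace=tuple(trace),
        iterations=iterations,
    )


def replay(
    recipe: Recipe,
    rule_ids: Sequence[str],
    catalog: Catalog,
    ruleset: Sequence[AlterationRule] | None = None,
) -> Recipe:
    """Re-apply a recorded rule sequence to the original recipe; because
    every rule is deterministic this reproduces the repaired dish."""
    rules = {r.rule_id: r for r in (ruleset if ruleset is not None else default_ruleset())}
    current = recipe
    for rule_id in rule_ids:
        outcome = apply_rule(current, rules[rule_id], catalog)
        if outcome is None:
            raise ValueError(f"rule {rule_id!r} no longer applies during replay")
        current = outcome[0]
    return current
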