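"""Per-portion nutrient/CO2e aggregation and guideline deviation scoring.

A dish's portion profile is a linear aggregate: for each nutrient, sum
``amount_g / 100 × per-100 g value`` over the ingredients and divide by the
serving count; wholegrain and fruit+vegetable grams use the corresponding
mass fractions; the climate footprint is ``amount_kg × kg CO2e per kg``
per serving.

Deviations are reported the way single-meal assessments print them: a
signed percent relative to a *reference* — the midpoint for two-sided
ranges, the bound itself for one-sided limits — with a positive sign
meaning above the reference. Compliance, by contrast, uses the actual
low/high bounds, so a fiber content far above its minimum is a large
positive deviation and still compliant (minima have no ceiling).
"""

from __future__ import annotations

from typing import Iterable, Mapping

from pydantic import BaseModel, ConfigDict, Field, model_validator

from .food_model import Catalog, CatalogError, Recipe
from .guideline_engine import MealGuideline, ThresholdSpec, round_half_away

__all__ = [
    "ComponentDeviation",
    "DeviationReport",
    "PortionProfile",
    "aggregate_portion",
    "cohort_mean",
    "evaluate",
    "percent_deviation",
]


class PortionProfile(BaseModel):
    """Nutrients and climate footprint of one served portion."""

    model_config = ConfigDict(frozen=True)

    energy: float = Field(ge=0)
    protein: float = Field(ge=0)
    fat: float = Field(ge=0)
    saturated_fat: float = Field(ge=0)
    fiber: float = Field(ge=0)
    wholegrain: float = Field(ge=0)
    fruit_veg: float = Field(ge=0)
    co2e: float = Field(ge=0)

    @model_validator(mode="after")
    def _saturated_le_total(self) -> "PortionProfile":
        if self.saturated_fat > self.fat + 1e-9:
            raise ValueError(
                f"saturated_fat ({self.saturated_fat}) exceeds fat ({self.fat})"
            )
        return self

    def component(self, name: str) -> float:
        return getattr(self, name)


class ComponentDeviation(BaseModel):
    model_config = ConfigDict(frozen=True)

    component: str
    value: float
    reference: float
    signed_pct: int
    raw_pct: float
    within_bounds: bool


class DeviationReport(BaseModel):
    model_config = ConfigDict(frozen=True)

    components: Mapping[str, ComponentDeviation]
    overall_compliant: bool

    def violations(self) -> list[str]:
        return [name for name, dev in self.components.items() if not dev.within_bounds]


def aggregate_portion(recipe: Recipe, catalog: Catalog) -> PortionProfile:
    """Aggregate a recipe's ingredients into a per-portion profile.

    Raises :class:`CatalogError` naming the first ingredient that lacks a
    nutrient profile or climate factor.
    """
    totals = {
        "energy": 0.0,
        "protein": 0.0,
        "fat": 0.0,
        "saturated_fat": 0.0,
        "fiber": 0.0,
        "wholegrain": 0.0,
        "fruit_veg": 0.0,
        "co2e": 0.0,
    }
    for ing in recipe.ingredients:
        if ing.item_id not in catalog.items:
            raise CatalogError(
                f"recipe {recipe.recipe_id!r}: unknown ingredient {ing.item_id!r}"
            )
        nutrient = catalog.nutrient(ing.item_id)
        co2e_per_kg = catalog.co2e_per_kg(ing.item_id)
        per100 = ing.amount_g / 100.0
        totals["energy"] += per100 * nutrient.energy_kcal
        totals["protein"] += per100 * nutrient.protein_g
        totals["fat"] += per100 * nutrient.fat_g
        totals["saturated_fat"] += per100 * nutrient.saturated_fat_g
        totals["fiber"] += per100 * nutrient.fiber_g
        totals["wholegrain"] += ing.amount_g * nutrient.wholegrain_fraction
        totals["fruit_veg"] += ing.amount_g * nutrient.fruit_veg_fraction
        totals["co2e"] += ing.amount_g / 1000.0 * co2e_per_kg
    servings = float(recipe.servings)
    return PortionProfile(**{k: v / servings for k, v in totals.items()})


def percent_deviation(value: float, spec: ThresholdSpec) -> int:
    """Signed percent deviation of ``value`` from the spec's reference,
    rounded to the nearest integer percent (half away from zero)."""
    return int(round_half_away(_raw_percent_deviation(value, spec)))


def _raw_percent_deviation(value: float, spec: ThresholdSpec) -> float:
    if spec.reference <= 0:
        raise ValueError(f"deviation reference must be positive, got {spec.reference}")
    return 100.0 * (value - spec.reference) / spec.reference


def evaluate(profile: PortionProfile, guideline: MealGuideline) -> DeviationReport:
    """Score a portion profile against a meal guideline, component by
    component; the overall verdict requires every bounded component to sit
    within its bounds."""
    components: dict[str, ComponentDeviation] = {}
    for name in MealGuideline.COMPONENTS:
        spec = guideline.spec(name)
        value = profile.component(name)
        raw = _raw_percent_deviation(value, spec)
        components[name] = ComponentDeviation(
            component=name,
            value=value,
            reference=spec.reference,
            signed_pct=int(round_half_away(raw)),
            raw_pct=raw,
            within_bounds=spec.within(value),
        )
    return DeviationReport(
        components=components,
        overall_compliant=all(dev.within_bounds for dev in components.values()),
    )


def cohort_mean(profiles: Iterable[PortionProfile]) -> PortionProfile:
    """Component-wise arithmetic mean over a set of portion profiles."""
    profiles = list(profiles)
    if not profiles:
        raise ValueError("cohort_mean needs at least one profile")
    n = float(len(profiles))
    return PortionProfile(
        **{
            name: sum(p.component(name) for p in profiles) / n
            for name in MealGuideline.COMPONENTS
        }
    )
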