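"""Per-meal nutritional thresholds and the meal climate budget.

Daily recommendations (Nordic Nutrition Recommendations plus the Swedish
Food Agency's wholegrain advice) are scaled to a single main meal using a
meal fraction, 0.30 by default following the school-lunch convention of
one main meal supplying ~30% of the daily intake. Macronutrient energy
percentages (E%) are converted to grams with Atwater factors (4 kcal/g
protein, 9 kcal/g fat) at the meal-energy midpoint.

The climate side divides an annual per-capita food carbon allowance
(590 kg CO2e by default, the WWF-derived food budget compatible with the
1.5 °C target) into week, day and meal budgets.

Rounding conventions are fixed so that the derived numbers are unique:
grams from E% round to the nearest integer (half away from zero), the
weekly CO2e budget to the nearest integer, daily and meal CO2e to one
decimal. One known wrinkle: 10 E% saturated fat at the 735 kcal midpoint
computes to 8.2 g while the published per-meal bound is 9 g; the guideline
carries the published bound as operative and keeps the computed value
alongside (see docs/methods.md).
"""

from __future__ import annotations

import math
from typing import ClassVar, Literal

import yaml
from pydantic import BaseModel, ConfigDict, Field, model_validator

__all__ = [
    "ATWATER",
    "ClimateBudget",
    "DailyGuideline",
    "EnergyConversion",
    "MealGuideline",
    "ThresholdSpec",
    "build_meal_guideline",
    "derive_climate_budget",
    "derive_meal_energy",
    "e_percent_to_grams",
    "load_guideline",
    "nnr_daily_defaults",
    "nnr_meal_defaults",
    "round_half_away",
    "scale_daily_amount",
    "write_guideline",
]


def round_half_away(x: float, ndigits: int = 0) -> float:
    """Round with ties going away from zero (the convention used for all
    reported guideline and deviation figures; Python's builtin rounds to
    even)."""
    factor = 10.0**ndigits
    scaled = x * factor
    rounded = math.floor(abs(scaled) + 0.5) * (1 if scaled >= 0 else -1)
    return rounded / factor if ndigits else float(rounded)


class EnergyConversion(BaseModel):
    """Atwater energy densities."""

    model_config = ConfigDict(frozen=True)

    kcal_per_g_protein: float = Field(default=4.0, gt=0)
    kcal_per_g_fat: float = Field(default=9.0, gt=0)


ATWATER = EnergyConversion()


class DailyGuideline(BaseModel):
    """Recommended daily intakes for an average healthy adult."""

    model_config = ConfigDict(frozen=True)

    energy_kcal: tuple[float, float] = (1700.0, 3200.0)
    protein_epct: tuple[float, float] = (10.0, 20.0)
    fat_epct: tuple[float, float] = (25.0, 40.0)
    saturated_epct_max: float = 10.0
    wholegrain_g: tuple[float, float] = (70.0, 90.0)
    fiber_g: tuple[float, float] = (25.0, 35.0)
    fruit_veg_g: float = 500.0

    @model_validator(mode="after")
    def _ranges_ordered(self) -> "DailyGuideline":
        for name in ("energy_kcal", "protein_epct", "fat_epct", "wholegrain_g", "fiber_g"):
            low, high = getattr(self, name)
            if not 0 <= low <= high:
                raise ValueError(f"{name} range ({low}, {high}) not ordered")
        for name in ("protein_epct", "fat_epct"):
            low, high = getattr(self, name)
            if high > 100:
                raise ValueError(f"{name} exceeds 100 E%")
        if not 0 <= self.saturated_epct_max <= 100:
            raise ValueError("saturated_epct_max outside [0, 100]")
        return self


def nnr_daily_defaults() -> DailyGuideline:
    return DailyGuideline()


class ThresholdSpec(BaseModel):
    """One per-meal component bound.

    ``reference`` is the value percent deviations are computed against:
    the midpoint for two-sided ranges, the bound itself for one-sided
    specs. ``within(value)`` checks the actual low/high bounds, never the
    reference.
    """

    model_config = ConfigDict(frozen=True)

    kind: Literal["range", "min_only", "max_only"]
    low: float | None = None
    high: float | None = None
    reference: float

    @model_validator(mode="after")
    def _consistent(self) -> "ThresholdSpec":
        if self.kind == "range":
            if self.low is None or self.high is None or self.low > self.high:
                raise ValueError("range spec needs ordered low/high")
        elif self.kind == "min_only" and self.low is None:
            raise ValueError("min_only spec needs low")
        elif self.kind == "max_only" and self.high is None:
            raise ValueError("max_only spec needs high")
        return self

    def within(self, value: float) -> bool:
        if self.kind == "range":
            return self.low <= value <= self.high  # type: ignore[operator]
        if self.kind == "min_only":
            return value >= self.low  # type: ignore[operator]
        return value <= self.high  # type: ignore[operator]


class ClimateBudget(BaseModel):
    model_config = ConfigDict(frozen=True)

    year_kg: float
    week_kg: float
    day_kg: float
    meal_kg: float


class MealGuideline(BaseModel):
    """Per-meal thresholds for every assessed component, plus the climate
    budget chain they were derived from."""

    model_config = ConfigDict(frozen=True)

    meal_fraction: float = Field(gt=0, le=1)
    energy: ThresholdSpec
    protein: ThresholdSpec
    fat: ThresholdSpec
    saturated_fat: ThresholdSpec
    wholegrain: ThresholdSpec
    fiber: ThresholdSpec
    fruit_veg: ThresholdSpec
    co2e: ThresholdSpec
    climate_budget: ClimateBudget
    saturated_fat_computed_g: float

    COMPONENTS: ClassVar[tuple[str, ...]] = (
        "energy",
        "protein",
        "fat",
        "saturated_fat",
        "fiber",
        "wholegrain",
        "fruit_veg",
        "co2e",
    )

    def spec(self, component: str) -> ThresholdSpec:
        return getattr(self, component)


def derive_meal_energy(
    daily_low: float, daily_high: float, meal_fraction: float = 0.30
) -> tuple[float, float, float]:
    """Scale the daily energy range to one meal; returns (low, high,
    midpoint) in kcal, unrounded."""
    if daily_low <= 0 or daily_high <= 0 or daily_low > daily_high:
        raise ValueError(f"invalid daily energy range ({daily_low}, {daily_high})")
    if not 0 < meal_fraction <= 1:
        raise ValueError(f"meal_fraction {meal_fraction} outside (0, 1]")
    low = daily_low * meal_fraction
    high = daily_high * meal_fraction
    midpoint = meal_fraction * (daily_low + daily_high) / 2.0
    return low, high, midpoint


def e_percent_to_grams(e_pct: float, meal_kcal: float, kcal_per_g: float) -> float:
    """Convert an energy-percent bound to grams at a given meal energy,
    rounded to the nearest integer gram (half away from zero)."""
    if not 0 <= e_pct <= 100:
        raise ValueError(f"e_pct {e_pct} outside [0, 100]")
    if meal_kcal <= 0:
        raise ValueError("meal_kcal must be positive")
    if kcal_per_g <= 0:
        raise ValueError("kcal_per_g must be positive")
    return round_half_away(e_pct / 100.0 * meal_kcal / kcal_per_g)


def scale_daily_amount(daily_g: float, meal_fraction: float = 0.30) -> float:
    """Scale a daily gram amount to one meal (reported unrounded; the
    published per-meal values carry one decimal where needed)."""
    if daily_g < 0:
        raise ValueError("daily_g must be non-negative")
    return daily_g * meal_fraction


def derive_climate_budget(
    annual_food_kg: float, meal_fraction: float = 0.30
) -> ClimateBudget:
    """Divide the annual per-capita food carbon allowance into week, day and
    meal budgets (week to integer kg, day and meal to one decimal)."""
    if annual_food_kg <= 0:
        raise ValueError("annual_food_kg must be positive")
    day_raw = annual_food_kg / 365.0
    return ClimateBudget(
        year_kg=annual_food_kg,
        week_kg=round_half_away(annual_food_kg / 52.0),
        day_kg=round_half_away(day_raw, 1),
        meal_kg=round_half_away(meal_fraction * day_raw, 1),
    )


def build_meal_guideline(
    daily: DailyGuideline | None = None,
    conversion: EnergyConversion = ATWATER,
    meal_fraction: float = 0.30,
    annual_food_kg: float = 590.0,
    saturated_fat_printed_g: float | None = 9.0,
) -> MealGuideline:
    """Compose the per-meal guideline.

    Energy, protein and fat become two-sided ranges (reference = midpoint);
    saturated fat and CO2e are upper bounds; wholegrain, fiber and
    fruit+vegetables are lower bounds with no per-meal ceiling.
    ``saturated_fat_printed_g`` overrides the E%-derived saturated-fat bound
    with the published per-meal figure; pass ``None`` to use the computed
    value instead.
    """
    daily = daily or nnr_daily_defaults()
    e_low, e_high, e_mid = derive_meal_energy(*daily.energy_kcal, meal_fraction)

    protein_low = e_percent_to_grams(daily.protein_epct[0], e_mid, conversion.kcal_per_g_protein)
    protein_high = e_percent_to_grams(daily.protein_epct[1], e_mid, conversion.kcal_per_g_protein)
    fat_low = e_percent_to_grams(daily.fat_epct[0], e_mid, conversion.kcal_per_g_fat)
    fat_high = e_percent_to_grams(daily.fat_epct[1], e_mid, conversion.kcal_per_g_fat)
    sat_computed = (
        daily.saturated_epct_max / 100.0 * e_mid / conversion.kcal_per_g_fat
    )
    sat_bound = (
        float(saturated_fat_printed_g)
        if saturated_fat_printed_g is not None
        else round_half_away(sat_computed, 1)
    )
    budget = derive_climate_budget(annual_food_kg, meal_fraction)

    def _range(low: float, high: float) -> ThresholdSpec:
        return ThresholdSpec(kind="range", low=low, high=high, reference=(low + high) / 2.0)

    def _min(low: float) -> ThresholdSpec:
        return ThresholdSpec(kind="min_only", low=low, reference=low)

    def _max(high: float) -> ThresholdSpec:
        return ThresholdSpec(kind="max_only", high=high, reference=high)

    return MealGuideline(
        meal_fraction=meal_fraction,
        energy=_range(e_low, e_high),
        protein=_range(protein_low, protein_high),
        fat=_range(fat_low, fat_high),
        saturated_fat=_max(sat_bound),
        wholegrain=_min(scale_daily_amount(daily.wholegrain_g[0], meal_fraction)),
        fiber=_min(scale_daily_amount(daily.fiber_g[0], meal_fraction)),
        fruit_veg=_min(scale_daily_amount(daily.fruit_veg_g, meal_fraction)),
        co2e=_max(budget.meal_kg),
        climate_budget=budget,
        saturated_fat_computed_g=sat_computed,
    )


def nnr_meal_defaults() -> MealGuideline:
    """The per-meal guideline with all published defaults: 30% meal fraction,
    NNR daily values, 590 kg CO2e/year food budget, 9 g saturated-fat bound."""
    return build_meal_guideline()


# ---------------------------------------------------------------------------
# Structured-text round trip (YAML)
# ---------------------------------------------------------------------------


def write_guideline(guideline: MealGuideline, path: str) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(guideline.model_dump(), fh, sort_keys=False)


def load_guideline(path: str) -> MealGuideline:
    with open(path, encoding="utf-8") as fh:
        return MealGuideline.model_validate(yaml.safe_load(fh))
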