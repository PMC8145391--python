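"""Seeded synthetic data: catalogs, receipts and recipes.

Real receipt-level sales data from a retailer are confidential, so this
module generates data with the same *structure*: baskets anchored on a
protein source with planted popularity shares, dish-mate items that
co-occur with their anchor far above independence, and filler items that
appear independently of everything. That planted structure is what the
sales pipeline is expected to recover (rank order, lift separation), which
makes every downstream stage testable without external data.

Two kinds of data are provided:

* randomized generators (:func:`generate_catalog`, :func:`generate_receipts`,
  :func:`generate_recipes`) driven by a single seeded NumPy generator, for
  property tests and simulations;
* a curated *standard fixture* (:func:`standard_fixture`): a hand-authored
  Swedish-style catalog of ~45 items with realistic per-100 g composition
  and kg CO2e/kg factors, the ten commonly prepared dishes built around the
  most-sold protein sources (tikka masala, tacos, Bolognese, lasagna,
  sausage stroganoff, ...), and a receipt configuration whose planted
  popularity and dish-mate map mirror those dishes. The fixture dishes are
  deliberately meat-anchored, wholegrain-free and vegetable-sparse, so the
  cohort violates the per-meal climate budget roughly threefold — the
  situation the alteration engine is designed to repair.

Category CO2e defaults in the random generator are ordered
red meat > processed meat > high-impact fish > poultry > low-impact
seafood > dairy > plant protein. These are generator defaults preserving
the qualitative ordering of published footprints, not measurements.
"""

from __future__ import annotations

from typing import Mapping, Sequence

import numpy as np
from pydantic import BaseModel, ConfigDict, Field, model_validator

from .food_model import (
    CATEGORIES,
    Catalog,
    ClimateFactor,
    FoodItem,
    Ingredient,
    NutrientProfile,
    Recipe,
    ReceiptLine,
    SubstituteLink,
    write_catalog,
    write_receipts,
    write_recipes,
)

__all__ = [
    "DEFAULT_CO2E_RANGES",
    "GeneratorConfig",
    "RecipeTemplate",
    "SlotSpec",
    "StandardFixture",
    "generate_catalog",
    "generate_receipts",
    "generate_recipes",
    "standard_catalog",
    "standard_fixture",
    "standard_recipes",
    "standard_templates",
    "write_fixtures",
]


#: Per-category kg CO2e/kg sampling ranges; midpoints keep the qualitative
#: ordering red > processed > fish(high) > poultry > fish(low) > dairy > plant.
DEFAULT_CO2E_RANGES: dict[str, tuple[float, float]] = {
    "protein_red_meat": (22.0, 30.0),
    "protein_processed_meat": (7.0, 13.0),
    "protein_fish_high_co2e": (5.0, 11.0),
    "protein_poultry": (2.2, 3.8),
    "protein_fish_low_co2e": (0.8, 1.6),
    "dairy_full_fat": (0.6, 1.4),
    "dairy_low_fat": (0.5, 1.3),
    "dairy_plant": (0.3, 0.9),
    "protein_plant": (0.4, 1.0),
    "grain_refined": (0.8, 2.0),
    "grain_whole": (0.8, 2.0),
    "vegetable": (0.2, 1.0),
    "fruit": (0.3, 1.0),
    "fat_oil": (1.0, 3.0),
    "other": (0.3, 2.0),
}

# (protein_g, fat_g, fiber_g, carb_g) sampling ranges per category.
_DEFAULT_NUTRIENT_RANGES: dict[str, tuple[tuple[float, float], ...]] = {
    "protein_red_meat": ((17.0, 22.0), (5.0, 20.0), (0.0, 0.0), (0.0, 1.0)),
    "protein_processed_meat": ((10.0, 15.0), (18.0, 30.0), (0.0, 0.5), (1.0, 5.0)),
    "protein_poultry": ((17.0, 23.0), (2.0, 8.0), (0.0, 0.0), (0.0, 1.0)),
    "protein_fish_high_co2e": ((17.0, 21.0), (1.0, 14.0), (0.0, 0.0), (0.0, 1.0)),
    "protein_fish_low_co2e": ((10.0, 14.0), (1.0, 3.0), (0.0, 0.0), (1.0, 4.0)),
    "protein_plant": ((8.0, 18.0), (1.0, 8.0), (4.0, 9.0), (5.0, 15.0)),
    "dairy_full_fat": ((2.0, 4.0), (15.0, 40.0), (0.0, 0.0), (3.0, 5.0)),
    "dairy_low_fat": ((3.0, 5.0), (0.5, 7.0), (0.0, 0.0), (4.0, 6.0)),
    "dairy_plant": ((1.0, 3.0), (1.0, 14.0), (0.3, 1.0), (4.0, 8.0)),
    "grain_refined": ((7.0, 12.0), (0.5, 5.0), (1.0, 3.0), (60.0, 75.0)),
    "grain_whole": ((8.0, 13.0), (1.5, 5.0), (5.0, 10.0), (55.0, 70.0)),
    "vegetable": ((0.8, 3.5), (0.1, 0.5), (1.0, 3.0), (3.0, 8.0)),
    "fruit": ((0.3, 1.0), (0.1, 0.5), (1.5, 3.0), (8.0, 14.0)),
    "fat_oil": ((0.0, 0.5), (80.0, 100.0), (0.0, 0.0), (0.0, 0.5)),
    "other": ((1.0, 3.0), (0.1, 2.0), (1.0, 2.5), (10.0, 20.0)),
}


class GeneratorConfig(BaseModel):
    """Parameters for the random catalog/receipt generators.

    ``protein_popularity`` are planted sales-weight shares over anchor
    proteins (they must sum to 1); ``dishmates`` maps each anchor to the
    items that co-occur with it with probability ``dishmate_prob``;
    ``filler_items`` appear in any receipt with probability ``filler_prob``
    independently of the anchor.
    """

    model_config = ConfigDict(frozen=True)

    seed: int = 0
    n_receipts: int = Field(default=5000, ge=0)
    n_items: int = Field(default=30, ge=1)
    protein_popularity: Mapping[str, float] = Field(default_factory=dict)
    dishmate_prob: float = Field(default=0.9, ge=0, le=1)
    filler_prob: float = Field(default=0.2, ge=0, le=1)
    dishmates: Mapping[str, tuple[str, ...]] = Field(default_factory=dict)
    filler_items: tuple[str, ...] = ()
    weight_range: tuple[float, float] = (0.2, 1.0)
    category_nutrient_ranges: Mapping[str, tuple[tuple[float, float], ...]] = Field(
        default_factory=lambda: dict(_DEFAULT_NUTRIENT_RANGES)
    )
    category_co2e_ranges: Mapping[str, tuple[float, float]] = Field(
        default_factory=lambda: dict(DEFAULT_CO2E_RANGES)
    )

    @model_validator(mode="after")
    def _valid(self) -> "GeneratorConfig":
        if self.protein_popularity:
            total = sum(self.protein_popularity.values())
            if abs(total - 1.0) > 1e-9:
                raise ValueError(f"protein_popularity shares sum to {total}, not 1")
            if any(p < 0 for p in self.protein_popularity.values()):
                raise ValueError("protein_popularity shares must be non-negative")
        low, high = self.weight_range
        if not 0 < low <= high:
            raise ValueError(f"weight_range ({low}, {high}) not ordered/positive")
        for cat, (lo, hi) in self.category_co2e_ranges.items():
            if not 0 <= lo <= hi:
                raise ValueError(f"co2e range for {cat} ({lo}, {hi}) invalid")
        return self


def generate_catalog(config: GeneratorConfig) -> Catalog:
    """Random catalog: ``n_items`` items assigned round-robin over all
    categories, composition sampled from per-category ranges, energy set
    consistently from the sampled macronutrients (4/9/4 kcal per g protein/
    fat/carbohydrate). Deterministic per seed."""
    if config.n_items < 1:
        raise ValueError("n_items must be >= 1")
    rng = np.random.default_rng(config.seed)
    items: dict[str, FoodItem] = {}
    nutrients: dict[str, NutrientProfile] = {}
    climate: dict[str, ClimateFactor] = {}
    for i in range(config.n_items):
        category = CATEGORIES[i % len(CATEGORIES)]
        item_id = f"syn_{category}_{i:03d}"
        pr, fr, br, cr = config.category_nutrient_ranges[category]
        protein = float(rng.uniform(*pr))
        fat = float(rng.uniform(*fr))
        sat = fat * float(rng.uniform(0.2, 0.5))
        fiber = float(rng.uniform(*br))
        carb = float(rng.uniform(*cr))
        lo, hi = config.category_co2e_ranges[category]
        items[item_id] = FoodItem(
            item_id=item_id, name=item_id.replace("_", " "), categories=frozenset({category})
        )
        nutrients[item_id] = NutrientProfile(
            energy_kcal=4.0 * protein + 9.0 * fat + 4.0 * carb,
            protein_g=protein,
            fat_g=fat,
            saturated_fat_g=sat,
            fiber_g=fiber,
            wholegrain_fraction=1.0 if category == "grain_whole" else 0.0,
            fruit_veg_fraction=1.0 if category in ("vegetable", "fruit") else 0.0,
        )
        climate[item_id] = ClimateFactor(item_id=item_id, co2e_per_kg=float(rng.uniform(lo, hi)))
    return Catalog(items=items, nutrients=nutrients, climate=climate)


def generate_receipts(catalog: Catalog, config: GeneratorConfig) -> list[ReceiptLine]:
    """Protein-anchored baskets: each receipt draws one anchor by planted
    popularity, each of the anchor's dish-mates with ``dishmate_prob``, and
    each filler with ``filler_prob``; line weights are uniform within
    ``weight_range``. Deterministic per seed."""
    if not config.protein_popularity:
        raise ValueError("config.protein_popularity is empty")
    unknown = sorted(set(config.protein_popularity) - set(catalog.items))
    if unknown:
        raise ValueError(f"protein_popularity references unknown items: {unknown}")
    for anchor, mates in config.dishmates.items():
        missing = sorted(set(mates) - set(catalog.items))
        if missing:
            raise ValueError(f"dishmates of {anchor!r} reference unknown items: {missing}")

    rng = np.random.default_rng(config.seed)
    n = config.n_receipts
    if n == 0:
        return []
    anchors = sorted(config.protein_popularity)
    shares = np.array([config.protein_popularity[a] for a in anchors])
    anchor_idx = rng.choice(len(anchors), size=n, p=shares)

    receipt_items: list[list[str]] = [[anchors[i]] for i in anchor_idx]
    # Dish-mates: one Bernoulli draw per (receipt, mate of its anchor).
    for ai, anchor in enumerate(anchors):
        rows = np.flatnonzero(anchor_idx == ai)
        for mate in config.dishmates.get(anchor, ()):
            hits = rows[rng.random(rows.size) < config.dishmate_prob]
            for r in hits:
                receipt_items[r].append(mate)
    for filler in config.filler_items:
        hits = np.flatnonzero(rng.random(n) < config.filler_prob)
        for r in hits:
            receipt_items[r].append(filler)

    lo, hi = config.weight_range
    lines: list[ReceiptLine] = []
    for r, item_list in enumerate(receipt_items):
        weights = rng.uniform(lo, hi, size=len(item_list))
        receipt_id = f"r{r:06d}"
        for item_id, w in zip(item_list, weights):
            lines.append(ReceiptLine(receipt_id=receipt_id, item_id=item_id, weight_kg=float(w)))
    return lines


class SlotSpec(BaseModel):
    """One ingredient slot of a recipe template: either a pinned item or a
    category to fill from the catalog (first eligible item in id order)."""

    model_config = ConfigDict(frozen=True)

    amount_g: float = Field(gt=0)
    item_id: str | None = None
    category: str | None = None
    role: str = "other"

    @model_validator(mode="after")
    def _one_of(self) -> "SlotSpec":
        if (self.item_id is None) == (self.category is None):
            raise ValueError("slot needs exactly one of item_id / category")
        return self


class RecipeTemplate(BaseModel):
    model_config = ConfigDict(frozen=True)

    recipe_id: str
    name: str
    servings: int = Field(ge=1)
    slots: tuple[SlotSpec, ...]

    @model_validator(mode="after")
    def _has_protein(self) -> "RecipeTemplate":
        if not any(s.role == "protein" for s in self.slots):
            raise ValueError(f"template {self.recipe_id!r} has no protein slot")
        return self


def generate_recipes(catalog: Catalog, templates: Sequence[RecipeTemplate]) -> list[Recipe]:
    """Instantiate templates against a catalog. Category slots take the
    first non-excluded catalog item of that category (id order), so the
    result is deterministic; an unfillable slot raises an error naming the
    category."""
    recipes: list[Recipe] = []
    for tpl in templates:
        ingredients: list[Ingredient] = []
        anchor: str | None = None
        for slot in tpl.slots:
            if slot.item_id is not None:
                if slot.item_id not in catalog.items:
                    raise ValueError(
                        f"template {tpl.recipe_id!r}: unknown item {slot.item_id!r}"
                    )
                chosen = slot.item_id
            else:
                candidates = [
                    it for it in catalog.items_in_category(slot.category)  # type: ignore[arg-type]
                    if it.excluded_as == "none"
                ]
                if not candidates:
                    raise ValueError(
                        f"template {tpl.recipe_id!r}: no catalog item fills "
                        f"category {slot.category!r}"
                    )
                chosen = candidates[0].item_id
            ingredients.append(Ingredient(item_id=chosen, amount_g=slot.amount_g))
            if slot.role == "protein" and anchor is None:
                anchor = chosen
        assert anchor is not None  # guaranteed by template validator
        recipes.append(
            Recipe(
                recipe_id=tpl.recipe_id,
                name=tpl.name,
                servings=tpl.servings,
                ingredients=tuple(ingredients),
                anchor_protein=anchor,
                provenance="original",
            )
        )
    return recipes


# ---------------------------------------------------------------------------
# Standard fixture: curated catalog, ten dishes, receipt configuration
# ---------------------------------------------------------------------------

# item_id, name, categories, excluded_as, substitutes ("id:role;..."),
# (energy kcal, protein g, fat g, sat fat g, fiber g, wg frac, f+v frac), co2e/kg
_STANDARD_ITEMS: tuple[tuple, ...] = (
    # protein sources
    ("chicken_breast", "Chicken breast fillet", "protein_poultry", "none",
     "soy_mince:plant_protein", (110, 22, 2, 0.6, 0, 0, 0), 3.6),
    ("chicken_leg", "Chicken leg", "protein_poultry", "none",
     "soy_mince:plant_protein", (125, 18, 6, 1.6, 0, 0, 0), 3.6),
    ("whole_chicken", "Whole chicken", "protein_poultry", "none",
     "soy_mince:plant_protein", (120, 19, 5, 1.4, 0, 0, 0), 3.6),
    ("minced_beef", "Minced meat (beef)", "protein_red_meat", "none",
     "soy_mince:plant_protein", (240, 19, 18, 8, 0, 0, 0), 26.0),
    ("mixed_mince", "Minced meat (pork/beef 50/50)", "protein_red_meat", "none",
     "soy_mince:plant_protein", (230, 18, 17, 7, 0, 0, 0), 16.0),
    ("pork_fillet", "Pork fillet", "protein_red_meat", "none",
     "soy_mince:plant_protein", (110, 21, 3, 1.1, 0, 0, 0), 6.0),
    ("falu_sausage", "Falu sausage", "protein_processed_meat", "none",
     "soy_mince:plant_protein", (250, 11, 21, 8, 0, 0, 0), 7.0),
    ("grilled_sausage", "Grilled/spicy sausage", "protein_processed_meat", "none",
     "soy_mince:plant_protein", (280, 12, 25, 9.5, 0, 0, 0), 7.0),
    ("bacon", "Bacon", "protein_processed_meat", "none",
     "soy_mince:plant_protein", (320, 14, 29, 11, 0, 0, 0), 11.0),
    ("sliced_ham", "Sliced ham", "protein_processed_meat", "snack_spread",
     "", (110, 18, 4, 1.4, 0, 0, 0), 7.0),
    ("caviar_spread", "Caviar spread", "protein_fish_high_co2e", "snack_spread",
     "", (280, 9, 24, 3, 0, 0, 0), 8.0),
    ("eggs", "Eggs", "other", "egg", "", (140, 13, 10, 2.6, 0, 0, 0), 2.0),
    ("salmon_fillet", "Salmon fillet", "protein_fish_high_co2e", "none",
     "mussels:low_co2e_seafood", (200, 20, 13, 3, 0, 0, 0), 6.0),
    ("shrimp", "Shrimp", "protein_fish_high_co2e", "snack_spread",
     "clams:low_co2e_seafood", (80, 18, 1, 0.2, 0, 0, 0), 12.0),
    ("mussels", "Mussels", "protein_fish_low_co2e", "none", "",
     (85, 12, 2, 0.4, 0, 0, 0), 0.9),
    ("clams", "Clams", "protein_fish_low_co2e", "none", "",
     (80, 11, 1, 0.3, 0, 0, 0), 1.0),
    ("soy_mince", "Soy mince (hydrated)", "protein_plant", "none", "",
     (105, 16, 6, 0.8, 5, 0, 0), 1.1),
    ("cooked_lentils", "Cooked lentils", "protein_plant", "none", "",
     (115, 9, 0.4, 0.1, 8, 0, 0), 0.7),
    ("tofu", "Tofu", "protein_plant", "none", "", (120, 12, 7, 1, 1, 0, 0), 1.0),
    # dairy
    ("cooking_cream", "Cooking cream", "dairy_full_fat", "none",
     "oat_cream:plant_dairy", (190, 2.5, 19, 12, 0, 0, 0), 4.0),
    ("creme_fraiche", "Crème fraîche", "dairy_full_fat", "none",
     "oat_cream:plant_dairy", (200, 2.4, 20, 13, 0, 0, 0), 4.0),
    ("cheese_grated", "Grated cheese", "dairy_full_fat", "none",
     "plant_cheese:plant_dairy;low_fat_cheese:low_fat_dairy",
     (360, 26, 28, 18, 0, 0, 0), 8.0),
    ("low_fat_cheese", "Low-fat cheese", "dairy_low_fat", "none", "",
     (270, 31, 17, 11, 0, 0, 0), 8.0),
    ("butter", "Butter", "dairy_full_fat", "none",
     "plant_margarine:plant_dairy", (730, 0.6, 81, 52, 0, 0, 0), 13.0),
    ("milk", "Milk", "dairy_full_fat", "none",
     "oat_milk:plant_dairy", (60, 3.4, 3, 1.9, 0, 0, 0), 1.2),
    ("oat_cream", "Oat cream", "dairy_plant", "none", "",
     (150, 1, 13, 1.3, 0.5, 0, 0), 0.6),
    ("oat_milk", "Oat milk", "dairy_plant", "none", "",
     (45, 1, 1.5, 0.2, 0.8, 0, 0), 0.4),
    ("plant_cheese", "Plant-based cheese", "dairy_plant", "none", "",
     (280, 1, 23, 8, 0, 0, 0), 2.0),
    ("plant_margarine", "Plant margarine", "dairy_plant", "none", "",
     (540, 0.2, 60, 18, 0, 0, 0), 1.5),
    # grains
    ("white_rice", "White rice (dry)", "grain_refined", "none",
     "wholegrain_rice:wholegrain", (350, 7, 0.6, 0.2, 1.4, 0, 0), 2.0),
    ("spaghetti", "Spaghetti (dry)", "grain_refined", "none",
     "wholegrain_spaghetti:wholegrain", (360, 12, 1.5, 0.3, 3, 0, 0), 0.8),
    ("egg_noodles", "Egg noodles (dry)", "grain_refined", "none",
     "wholegrain_noodles:wholegrain", (380, 12, 5, 1, 2, 0, 0), 1.0),
    ("lasagna_sheets", "Lasagna sheets (dry)", "grain_refined", "none",
     "wholegrain_lasagna_sheets:wholegrain", (360, 12, 1.5, 0.3, 3, 0, 0), 0.8),
    ("tortilla_bread", "Tortilla bread", "grain_refined", "none",
     "wholegrain_tortilla:wholegrain", (310, 8, 7, 3, 2.4, 0, 0), 1.3),
    ("couscous", "Couscous (dry)", "grain_refined", "none",
     "wholegrain_couscous:wholegrain", (360, 12, 1, 0.2, 2, 0, 0), 0.9),
    ("wholegrain_rice", "Wholegrain rice (dry)", "grain_whole", "none", "",
     (350, 7.5, 2.5, 0.5, 3.5, 1, 0), 2.0),
    ("wholegrain_spaghetti", "Wholegrain spaghetti (dry)", "grain_whole", "none", "",
     (350, 13, 2.5, 0.4, 7, 1, 0), 0.8),
    ("wholegrain_noodles", "Wholegrain noodles (dry)", "grain_whole", "none", "",
     (360, 12, 4, 0.8, 6, 1, 0), 1.0),
    ("wholegrain_lasagna_sheets", "Wholegrain lasagna sheets (dry)", "grain_whole",
     "none", "", (350, 13, 2, 0.4, 7, 1, 0), 0.8),
    ("wholegrain_tortilla", "Wholegrain tortilla", "grain_whole", "none", "",
     (300, 9, 6, 2.5, 6, 1, 0), 1.3),
    ("wholegrain_couscous", "Wholegrain couscous (dry)", "grain_whole", "none", "",
     (350, 13, 2, 0.3, 8, 1, 0), 0.9),
    # vegetables & fruit
    ("onion", "Onion", "vegetable", "none", "", (40, 1.3, 0.1, 0, 1.7, 0, 1), 0.3),
    ("crushed_tomatoes", "Crushed tomatoes", "vegetable", "none", "",
     (30, 1.2, 0.2, 0, 1.3, 0, 1), 0.6),
    ("tomato", "Tomato", "vegetable", "none", "", (20, 0.8, 0.2, 0, 1.2, 0, 1), 0.8),
    ("lettuce", "Lettuce", "vegetable", "none", "", (15, 1.2, 0.2, 0, 1.3, 0, 1), 0.5),
    ("bell_pepper", "Bell pepper", "vegetable", "none", "",
     (30, 1, 0.3, 0, 1.8, 0, 1), 1.0),
    ("broccoli", "Broccoli", "vegetable", "none", "",
     (35, 3.5, 0.4, 0.1, 2.6, 0, 1), 0.4),
    ("carrot", "Carrot", "vegetable", "none", "", (35, 0.9, 0.2, 0, 2.8, 0, 1), 0.2),
    ("lemon", "Lemon", "fruit", "none", "", (30, 0.7, 0.3, 0, 1.5, 0, 1), 0.8),
    ("apple", "Apple", "fruit", "none", "", (50, 0.3, 0.2, 0, 2.0, 0, 1), 0.3),
    # fats & other
    ("rapeseed_oil", "Rapeseed oil", "fat_oil", "none", "",
     (900, 0, 100, 7, 0, 0, 0), 1.5),
    ("potatoes", "Potatoes", "other", "none", "", (80, 1.7, 0.1, 0, 1.8, 0, 0), 0.1),
)


def standard_catalog() -> Catalog:
    """The curated Swedish-style fixture catalog (deterministic)."""
    items: dict[str, FoodItem] = {}
    nutrients: dict[str, NutrientProfile] = {}
    climate: dict[str, ClimateFactor] = {}
    for item_id, name, cats, excluded, subs, nutr, co2e in _STANDARD_ITEMS:
        links = tuple(
            SubstituteLink(item_id=tok.split(":")[0], role=tok.split(":")[1])
            for tok in subs.split(";")
            if tok
        )
        items[item_id] = FoodItem(
            item_id=item_id,
            name=name,
            categories=frozenset(cats.split(";")),
            excluded_as=excluded,
            substitutes=links,
        )
        e, p, f, s, b, wg, fv = nutr
        nutrients[item_id] = NutrientProfile(
            energy_kcal=e, protein_g=p, fat_g=f, saturated_fat_g=s,
            fiber_g=b, wholegrain_fraction=wg, fruit_veg_fraction=fv,
        )
        climate[item_id] = ClimateFactor(item_id=item_id, co2e_per_kg=co2e)
    return Catalog(items=items, nutrients=nutrients, climate=climate)


def _tpl(recipe_id: str, name: str, *slots: tuple) -> RecipeTemplate:
    return RecipeTemplate(
        recipe_id=recipe_id,
        name=name,
        servings=4,
        slots=tuple(
            SlotSpec(item_id=item, amount_g=amount, role=role)
            for item, amount, role in slots
        ),
    )


def standard_templates() -> tuple[RecipeTemplate, ...]:
    """Templates for the ten commonly prepared dishes, each anchored on one
    of the most-sold protein sources (amounts are as-purchased grams for a
    four-serving batch)."""
    return (
        _tpl("tikka_masala", "Tikka masala with rice",
             ("chicken_breast", 500, "protein"), ("white_rice", 250, "carb"),
             ("cooking_cream", 200, "sauce"), ("crushed_tomatoes", 200, "veg"),
             ("onion", 100, "veg"), ("rapeseed_oil", 30, "fat")),
        _tpl("chicken_wok", "Chicken wok with noodles",
             ("chicken_breast", 450, "protein"), ("egg_noodles", 250, "carb"),
             ("bell_pepper", 150, "veg"), ("carrot", 100, "veg"),
             ("onion", 100, "veg"), ("rapeseed_oil", 40, "fat")),
        _tpl("taco", "Tacos",
             ("minced_beef", 550, "protein"), ("tortilla_bread", 300, "carb"),
             ("cheese_grated", 100, "sauce"), ("creme_fraiche", 100, "sauce"),
             ("tomato", 150, "veg"), ("lettuce", 100, "veg"), ("onion", 50, "veg")),
        _tpl("bolognese", "Spaghetti Bolognese",
             ("minced_beef", 500, "protein"), ("spaghetti", 250, "carb"),
             ("crushed_tomatoes", 300, "veg"), ("cheese_grated", 30, "sauce"),
             ("onion", 100, "veg"), ("rapeseed_oil", 50, "fat")),
        _tpl("chicken_leg_curry", "Chicken leg with curry sauce and rice",
             ("chicken_leg", 600, "protein"), ("white_rice", 250, "carb"),
             ("cooking_cream", 200, "sauce"), ("onion", 100, "veg"),
             ("rapeseed_oil", 20, "fat")),
        _tpl("lasagna", "Lasagna",
             ("mixed_mince", 450, "protein"), ("lasagna_sheets", 200, "carb"),
             ("crushed_tomatoes", 300, "veg"), ("milk", 300, "sauce"),
             ("cheese_grated", 100, "sauce"), ("onion", 100, "veg"),
             ("rapeseed_oil", 40, "fat")),
        _tpl("sausage_stroganoff", "Sausage stroganoff",
             ("falu_sausage", 500, "protein"), ("white_rice", 250, "carb"),
             ("cooking_cream", 250, "sauce"), ("crushed_tomatoes", 100, "veg"),
             ("onion", 100, "veg"), ("rapeseed_oil", 30, "fat")),
        _tpl("pork_fillet_bearnaise",
             "Marinated pork fillet with potato wedges and Béarnaise",
             ("pork_fillet", 500, "protein"), ("potatoes", 600, "carb"),
             ("butter", 100, "sauce"), ("creme_fraiche", 100, "sauce"),
             ("lettuce", 100, "veg"), ("rapeseed_oil", 20, "fat")),
        _tpl("salmon_shrimp", "Salmon and shrimp with dill sauce and potatoes",
             ("salmon_fillet", 400, "protein"), ("shrimp", 150, "protein_extra"),
             ("potatoes", 600, "carb"), ("cooking_cream", 300, "sauce"),
             ("lemon", 50, "veg"), ("rapeseed_oil", 40, "fat")),
        _tpl("sausage_mash", "Grilled sausage with mashed potatoes",
             ("grilled_sausage", 500, "protein"), ("potatoes", 600, "carb"),
             ("milk", 200, "sauce"), ("butter", 50, "sauce"),
             ("onion", 100, "veg"), ("rapeseed_oil", 30, "fat")),
    )


def standard_recipes(catalog: Catalog | None = None) -> list[Recipe]:
    return generate_recipes(catalog or standard_catalog(), standard_templates())


#: Planted sales-weight shares for the fixture anchors (structural, not the
#: retailer's confidential shares; the *order* mirrors the published ranking).
_STANDARD_POPULARITY: dict[str, float] = {
    "chicken_breast": 0.20,
    "minced_beef": 0.17,
    "chicken_leg": 0.13,
    "grilled_sausage": 0.11,
    "mixed_mince": 0.10,
    "falu_sausage": 0.08,
    "pork_fillet": 0.07,
    "salmon_fillet": 0.06,
    "bacon": 0.05,
    "whole_chicken": 0.03,
}

#: Distinctive co-purchase partners per anchor. Pantry staples (onion, oil,
#: plain tomato, ...) are modelled as independent fillers instead, so lift
#: cleanly separates planted dish-mates from background items. The two
#: weak-association anchors (bacon, whole chicken) have no dish-mates.
_STANDARD_DISHMATES: dict[str, tuple[str, ...]] = {
    "chicken_breast": ("white_rice", "cooking_cream", "crushed_tomatoes",
                       "egg_noodles", "bell_pepper"),
    "minced_beef": ("spaghetti", "crushed_tomatoes", "tortilla_bread",
                    "cheese_grated", "creme_fraiche"),
    "chicken_leg": ("white_rice", "cooking_cream"),
    "grilled_sausage": ("potatoes", "milk", "butter"),
    "mixed_mince": ("lasagna_sheets", "cheese_grated", "milk", "crushed_tomatoes"),
    "falu_sausage": ("white_rice", "cooking_cream", "crushed_tomatoes"),
    "pork_fillet": ("potatoes", "butter", "creme_fraiche", "lettuce"),
    "salmon_fillet": ("shrimp", "potatoes", "cooking_cream", "lemon"),
    "bacon": (),
    "whole_chicken": (),
}

_STANDARD_FILLERS: tuple[str, ...] = (
    "onion", "rapeseed_oil", "tomato", "carrot", "broccoli", "apple",
)


def standard_receipt_config(seed: int = 0, n_receipts: int = 5000) -> GeneratorConfig:
    return GeneratorConfig(
        seed=seed,
        n_receipts=n_receipts,
        protein_popularity=dict(_STANDARD_POPULARITY),
        dishmates=dict(_STANDARD_DISHMATES),
        filler_items=_STANDARD_FILLERS,
        dishmate_prob=0.9,
        filler_prob=0.2,
    )


class StandardFixture(BaseModel):
    model_config = ConfigDict(frozen=True, arbitrary_types_allowed=True)

    catalog: Catalog
    recipes: tuple[Recipe, ...]
    receipts: tuple[ReceiptLine, ...]
    config: GeneratorConfig


def standard_fixture(seed: int = 0, n_receipts: int = 5000) -> StandardFixture:
    """Catalog + ten dishes + seeded receipts, ready for the full pipeline."""
    catalog = standard_catalog()
    config = standard_receipt_config(seed=seed, n_receipts=n_receipts)
    return StandardFixture(
        catalog=catalog,
        recipes=tuple(standard_recipes(catalog)),
        receipts=tuple(generate_receipts(catalog, config)),
        config=config,
    )


def write_fixtures(directory, seed: int = 0, n_receipts: int = 5000) -> None:
    """Materialize the standard fixture set as the CSV/YAML files the
    loaders read (catalog directory, recipes.yaml, receipts.csv)."""
    from pathlib import Path

    root = Path(directory)
    root.mkdir(parents=True, exist_ok=True)
    fixture = standard_fixture(seed=seed, n_receipts=n_receipts)
    write_catalog(fixture.catalog, root / "catalog")
    write_recipes(fixture.recipes, root / "recipes.yaml")
    write_receipts(fixture.receipts, root / "receipts.csv")
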