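"""Core domain types and file I/O for catalogs, recipes and receipts.

The domain model mirrors how a retail-basket sustainability analysis sees
food: a *catalog* of items carrying category tags (protein sources, dairy,
grains, vegetables, ...), a nutrient composition table per 100 g edible food
(as in the Swedish food composition database), a climate-factor table in
kg CO2e per kg purchased food (as in the Mat.se database), *recipes* that
combine catalog items into dishes with a serving count, and *receipt lines*
(receipt id, item id, weight) from point-of-sale statistics.

All amounts are "as purchased" grams; cooked-yield conversion is out of
scope because the climate factors themselves exclude post-processing steps
such as cooking. Wholegrain and fruit/vegetable content are modelled as
mass fractions of an ingredient so that composite products aggregate
linearly.

File formats are deliberately plain: comma-separated UTF-8 with a header
row for the tabular inputs (items, nutrients, climate factors, receipts)
and YAML for recipes. See ``docs/`` and ``examples/`` for the schemas.
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable, Literal, Mapping

import pandas as pd
import yaml
from pydantic import BaseModel, ConfigDict, Field, model_validator

__all__ = [
    "CATEGORIES",
    "PROTEIN_CATEGORIES",
    "Category",
    "CatalogError",
    "Catalog",
    "ClimateFactor",
    "FoodItem",
    "Ingredient",
    "NutrientProfile",
    "Recipe",
    "ReceiptLine",
    "SubstituteLink",
    "load_catalog",
    "load_receipts",
    "load_recipes",
    "write_catalog",
    "write_receipts",
    "write_recipes",
]

Category = Literal[
    "protein_red_meat",
    "protein_processed_meat",
    "protein_poultry",
    "protein_fish_high_co2e",
    "protein_fish_low_co2e",
    "protein_plant",
    "dairy_full_fat",
    "dairy_low_fat",
    "dairy_plant",
    "grain_refined",
    "grain_whole",
    "vegetable",
    "fruit",
    "fat_oil",
    "other",
]

CATEGORIES: tuple[str, ...] = Category.__args__  # type: ignore[attr-defined]

#: Tags that make an item count as a protein source for the sales ranking.
PROTEIN_CATEGORIES: frozenset[str] = frozenset(
    c for c in CATEGORIES if c.startswith("protein_")
)

ExclusionTag = Literal["snack_spread", "egg", "none"]


class CatalogError(ValueError):
    """Raised when a catalog, recipe or receipt file violates an invariant."""


class SubstituteLink(BaseModel):
    """A directed substitution edge: this item may be replaced by ``item_id``
    when an alteration rule asks for ``role`` (e.g. ``plant_protein``,
    ``low_co2e_seafood``, ``plant_dairy``, ``low_fat_dairy``, ``wholegrain``)."""

    model_config = ConfigDict(frozen=True)

    item_id: str
    role: str


class NutrientProfile(BaseModel):
    """Composition per 100 g edible food.

    ``wholegrain_fraction`` and ``fruit_veg_fraction`` are the shares of the
    item's mass counting toward the wholegrain and fruit+vegetable meal
    minima, which keeps aggregation linear for mixed products.
    """

    model_config = ConfigDict(frozen=True)

    energy_kcal: float = Field(ge=0)
    protein_g: float = Field(ge=0)
    fat_g: float = Field(ge=0)
    saturated_fat_g: float = Field(ge=0)
    fiber_g: float = Field(ge=0)
    wholegrain_fraction: float = Field(ge=0, le=1)
    fruit_veg_fraction: float = Field(ge=0, le=1)

    @model_validator(mode="after")
    def _saturated_le_total(self) -> "NutrientProfile":
        if self.saturated_fat_g > self.fat_g + 1e-9:
            raise ValueError(
                f"saturated_fat_g ({self.saturated_fat_g}) exceeds fat_g ({self.fat_g})"
            )
        return self


class FoodItem(BaseModel):
    model_config = ConfigDict(frozen=True)

    item_id: str
    name: str
    categories: frozenset[Category]
    excluded_as: ExclusionTag = "none"
    substitutes: tuple[SubstituteLink, ...] = ()

    def substitute_for_role(self, role: str) -> str | None:
        for link in self.substitutes:
            if link.role == role:
                return link.item_id
        return None


class ClimateFactor(BaseModel):
    model_config = ConfigDict(frozen=True)

    item_id: str
    co2e_per_kg: float = Field(ge=0)


class Ingredient(BaseModel):
    model_config = ConfigDict(frozen=True)

    item_id: str
    amount_g: float = Field(gt=0)


class Recipe(BaseModel):
    """A dish: ingredient amounts (as-purchased grams for the whole batch),
    a serving count, and the protein source the dish is built around."""

    model_config = ConfigDict(frozen=True)

    recipe_id: str
    name: str
    servings: int = Field(ge=1)
    ingredients: tuple[Ingredient, ...]
    anchor_protein: str
    provenance: Literal["original", "altered"] = "original"
    trace: tuple[str, ...] = ()

    @model_validator(mode="after")
    def _anchor_present(self) -> "Recipe":
        if self.provenance == "original":
            ids = {i.item_id for i in self.ingredients}
            if self.anchor_protein not in ids:
                raise ValueError(
                    f"anchor_protein {self.anchor_protein!r} not among ingredients "
                    f"of original recipe {self.recipe_id!r}"
                )
        return self

    def ingredient_ids(self) -> frozenset[str]:
        return frozenset(i.item_id for i in self.ingredients)

    def amount_of(self, item_id: str) -> float:
        return sum(i.amount_g for i in self.ingredients if i.item_id == item_id)


class ReceiptLine(BaseModel):
    model_config = ConfigDict(frozen=True)

    receipt_id: str
    item_id: str
    weight_kg: float = Field(gt=0)


class Catalog(BaseModel):
    """Validated bundle of items, nutrient profiles and climate factors.

    Invariants enforced on construction:

    * item ids unique (guaranteed by the mapping keys);
    * every item has both a nutrient profile and a climate factor;
    * substitute links resolve to existing items;
    * items tagged ``grain_whole`` have ``wholegrain_fraction > 0``.
    """

    model_config = ConfigDict(frozen=True)

    items: Mapping[str, FoodItem]
    nutrients: Mapping[str, NutrientProfile]
    climate: Mapping[str, ClimateFactor]

    @model_validator(mode="after")
    def _cross_validate(self) -> "Catalog":
        for item_id, item in self.items.items():
            if item.item_id != item_id:
                raise ValueError(f"item keyed {item_id!r} has item_id {item.item_id!r}")
            if item_id not in self.nutrients:
                raise ValueError(f"item {item_id!r} has no nutrient profile")
            if item_id not in self.climate:
                raise ValueError(f"item {item_id!r} has no climate factor")
            dangling = [s.item_id for s in item.substitutes if s.item_id not in self.items]
            if dangling:
                raise ValueError(
                    f"item {item_id!r} has substitute links to unknown items: {dangling}"
                )
            if "grain_whole" in item.categories:
                if self.nutrients[item_id].wholegrain_fraction <= 0:
                    raise ValueError(
                        f"item {item_id!r} is tagged grain_whole but has "
                        "wholegrain_fraction 0"
                    )
        return self

    def item(self, item_id: str) -> FoodItem:
        try:
            return self.items[item_id]
        except KeyError:
            raise CatalogError(f"unknown item {item_id!r}") from None

    def nutrient(self, item_id: str) -> NutrientProfile:
        try:
            return self.nutrients[item_id]
        except KeyError:
            raise CatalogError(f"no nutrient profile for item {item_id!r}") from None

    def co2e_per_kg(self, item_id: str) -> float:
        try:
            return self.climate[item_id].co2e_per_kg
        except KeyError:
            raise CatalogError(f"no climate factor for item {item_id!r}") from None

    def items_in_category(self, category: str) -> list[FoodItem]:
        return sorted(
            (it for it in self.items.values() if category in it.categories),
            key=lambda it: it.item_id,
        )


# ---------------------------------------------------------------------------
# CSV / YAML readers and writers
# ---------------------------------------------------------------------------

_ITEM_COLUMNS = ["item_id", "name", "categories", "excluded_as", "substitutes"]
_NUTRIENT_COLUMNS = [
    "item_id",
    "energy_kcal",
    "protein_g",
    "fat_g",
    "saturated_fat_g",
    "fiber_g",
    "wholegrain_fraction",
    "fruit_veg_fraction",
]
_CLIMATE_COLUMNS = ["item_id", "co2e_per_kg"]
_RECEIPT_COLUMNS = ["receipt_id", "item_id", "weight_kg"]


def _require_columns(df: pd.DataFrame, required: Iterable[str], path: Path) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise CatalogError(f"{path}: missing column(s) {missing}")


def _parse_substitutes(cell: object) -> tuple[SubstituteLink, ...]:
    if cell is None or (isinstance(cell, float) and pd.isna(cell)) or cell == "":
        return ()
    links = []
    for token in str(cell).split(";"):
        token = token.strip()
        if not token:
            continue
        try:
            item_id, role = token.split(":")
        except ValueError:
            raise CatalogError(f"malformed substitute link {token!r}") from None
        links.append(SubstituteLink(item_id=item_id.strip(), role=role.strip()))
    return tuple(links)


def _format_substitutes(links: tuple[SubstituteLink, ...]) -> str:
    return ";".join(f"{l.item_id}:{l.role}" for l in links)


def load_catalog(path: str | Path) -> Catalog:
    """Load a catalog from a directory holding ``items.csv``, ``nutrients.csv``
    and ``climate.csv``.

    Raises :class:`CatalogError` naming the offending row or column when a
    file is malformed or an invariant is violated.
    """
    root = Path(path)
    items_path, nutrients_path, climate_path = (
        root / "items.csv",
        root / "nutrients.csv",
        root / "climate.csv",
    )
    for p in (items_path, nutrients_path, climate_path):
        if not p.exists():
            raise CatalogError(f"catalog file not found: {p}")

    items_df = pd.read_csv(items_path, dtype=str).fillna("")
    _require_columns(items_df, _ITEM_COLUMNS, items_path)
    nutrients_df = pd.read_csv(nutrients_path)
    _require_columns(nutrients_df, _NUTRIENT_COLUMNS, nutrients_path)
    climate_df = pd.read_csv(climate_path)
    _require_columns(climate_df, _CLIMATE_COLUMNS, climate_path)

    items: dict[str, FoodItem] = {}
    for row in items_df.itertuples(index=False):
        try:
            item = FoodItem(
                item_id=row.item_id,
                name=row.name,
                categories=frozenset(
                    c.strip() for c in str(row.categories).split(";") if c.strip()
                ),
                excluded_as=(row.excluded_as or "none"),
                substitutes=_parse_substitutes(row.substitutes),
            )
        except (ValueError, CatalogError) as exc:
            raise CatalogError(f"{items_path}: item {row.item_id!r}: {exc}") from None
        if item.item_id in items:
            raise CatalogError(f"{items_path}: duplicate item_id {item.item_id!r}")
        items[item.item_id] = item

    nutrients: dict[str, NutrientProfile] = {}
    for row in nutrients_df.itertuples(index=False):
        try:
            nutrients[str(row.item_id)] = NutrientProfile(
                energy_kcal=row.energy_kcal,
                protein_g=row.protein_g,
                fat_g=row.fat_g,
                saturated_fat_g=row.saturated_fat_g,
                fiber_g=row.fiber_g,
                wholegrain_fraction=row.wholegrain_fraction,
                fruit_veg_fraction=row.fruit_veg_fraction,
            )
        except ValueError as exc:
            raise CatalogError(f"{nutrients_path}: item {row.item_id!r}: {exc}") from None

    climate: dict[str, ClimateFactor] = {}
    for row in climate_df.itertuples(index=False):
        try:
            climate[str(row.item_id)] = ClimateFactor(
                item_id=str(row.item_id), co2e_per_kg=row.co2e_per_kg
            )
        except ValueError as exc:
            raise CatalogError(f"{climate_path}: item {row.item_id!r}: {exc}") from None

    try:
        return Catalog(items=items, nutrients=nutrients, climate=climate)
    except ValueError as exc:
        raise CatalogError(str(exc)) from None


def write_catalog(catalog: Catalog, path: str | Path) -> None:
    """Write a catalog as the three CSV files :func:`load_catalog` reads."""
    root = Path(path)
    root.mkdir(parents=True, exist_ok=True)
    items_rows = [
        {
            "item_id": it.item_id,
            "name": it.name,
            "categories": ";".join(sorted(it.categories)),
            "excluded_as": it.excluded_as,
            "substitutes": _format_substitutes(it.substitutes),
        }
        for it in sorted(catalog.items.values(), key=lambda i: i.item_id)
    ]
    pd.DataFrame(items_rows, columns=_ITEM_COLUMNS).to_csv(root / "items.csv", index=False)
    nutrient_rows = [
        {"item_id": item_id, **catalog.nutrients[item_id].model_dump()}
        for item_id in sorted(catalog.nutrients)
    ]
    pd.DataFrame(nutrient_rows, columns=_NUTRIENT_COLUMNS).to_csv(
        root / "nutrients.csv", index=False
    )
    climate_rows = [
        {"item_id": item_id, "co2e_per_kg": catalog.climate[item_id].co2e_per_kg}
        for item_id in sorted(catalog.climate)
    ]
    pd.DataFrame(climate_rows, columns=_CLIMATE_COLUMNS).to_csv(
        root / "climate.csv", index=False
    )


def load_recipes(path: str | Path, catalog: Catalog | None = None) -> list[Recipe]:
    """Load recipes from a YAML file; validate item references against
    ``catalog`` when one is given."""
    path = Path(path)
    with open(path, encoding="utf-8") as fh:
        doc = yaml.safe_load(fh)
    if not isinstance(doc, dict) or "recipes" not in doc:
        raise CatalogError(f"{path}: expected a top-level 'recipes' list")
    recipes: list[Recipe] = []
    for raw in doc["recipes"]:
        try:
            recipe = Recipe(
                recipe_id=raw["recipe_id"],
                name=raw.get("name", raw["recipe_id"]),
                servings=raw["servings"],
                ingredients=tuple(
                    Ingredient(item_id=i["item"], amount_g=i["amount_g"])
                    for i in raw["ingredients"]
                ),
                anchor_protein=raw["anchor_protein"],
                provenance=raw.get("provenance", "original"),
                trace=tuple(raw.get("trace", ())),
            )
        except (KeyError, ValueError) as exc:
            raise CatalogError(f"{path}: recipe {raw.get('recipe_id')!r}: {exc}") from None
        if catalog is not None:
            unknown = sorted(recipe.ingredient_ids() - set(catalog.items))
            if unknown:
                raise CatalogError(
                    f"{path}: recipe {recipe.recipe_id!r} references unknown items: "
                    f"{unknown}"
                )
        recipes.append(recipe)
    return recipes


def write_recipes(recipes: Iterable[Recipe], path: str | Path) -> None:
    doc = {
        "recipes": [
            {
                "recipe_id": r.recipe_id,
                "name": r.name,
                "servings": r.servings,
                "anchor_protein": r.anchor_protein,
                "provenance": r.provenance,
                "trace": list(r.trace),
                "ingredients": [
                    {"item": i.item_id, "amount_g": i.amount_g} for i in r.ingredients
                ],
            }
            for r in recipes
        ]
    }
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)


def load_receipts(path: str | Path, catalog: Catalog | None = None) -> list[ReceiptLine]:
    path = Path(path)
    if not path.exists():
        raise CatalogError(f"receipts file not found: {path}")
    df = pd.read_csv(path)
    _require_columns(df, _RECEIPT_COLUMNS, path)
    lines: list[ReceiptLine] = []
    for idx, row in enumerate(df.itertuples(index=False)):
        try:
            line = ReceiptLine(
                receipt_id=str(row.receipt_id),
                item_id=str(row.item_id),
                weight_kg=row.weight_kg,
            )
        except ValueError as exc:
            raise CatalogError(f"{path}: row {idx}: {exc}") from None
        if catalog is not None and line.item_id not in catalog.items:
            raise CatalogError(f"{path}: row {idx}: unknown item {line.item_id!r}")
        lines.append(line)
    return lines


def write_receipts(lines: Iterable[ReceiptLine], path: str | Path) -> None:
    df = pd.DataFrame(
        [(l.receipt_id, l.item_id, l.weight_kg) for l in lines],
        columns=_RECEIPT_COLUMNS,
    )
    df.to_csv(path, index=False)
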