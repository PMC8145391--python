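import pytest

from mealscope.food_model import (
    Catalog,
    ClimateFactor,
    FoodItem,
    NutrientProfile,
    SubstituteLink,
)
from mealscope.guideline_engine import nnr_meal_defaults
from mealscope.synthetic_data import standard_catalog, standard_fixture


def make_item(
    item_id: str,
    categories: set[str],
    *,
    energy: float = 100.0,
    protein: float = 10.0,
    fat: float = 5.0,
    sat: float = 1.0,
    fiber: float = 0.0,
    wg: float = 0.0,
    fv: float = 0.0,
    co2e: float = 1.0,
    excluded_as: str = "none",
    substitutes: tuple[tuple[str, str], ...] = (),
):
    """Build one (FoodItem, NutrientProfile, ClimateFactor) triple."""
    return (
        FoodItem(
            item_id=item_id,
            name=item_id,
            categories=frozenset(categories),
            excluded_as=excluded_as,
            substitutes=tuple(
                SubstituteLink(item_id=i, role=r) for i, r in substitutes
            ),
        ),
        NutrientProfile(
            energy_kcal=energy,
            protein_g=protein,
            fat_g=fat,
            saturated_fat_g=sat,
            fiber_g=fiber,
            wholegrain_fraction=wg,
            fruit_veg_fraction=fv,
        ),
        ClimateFactor(item_id=item_id, co2e_per_kg=co2e),
    )


def build_catalog(*triples) -> Catalog:
    return Catalog(
        items={t[0].item_id: t[0] for t in triples},
        nutrients={t[0].item_id: t[1] for t in triples},
        climate={t[0].item_id: t[2] for t in triples},
    )


@pytest.fixture(scope="session")
def swedish_catalog():
    return standard_catalog()


@pytest.fixture(scope="session")
def fixture_set():
    """Standard fixture: curated catalog, 10 dishes, 5000 seeded receipts."""
    return standard_fixture(seed=0, n_receipts=5000)


@pytest.fixture(scope="session")
def paper_guideline():
    """Per-meal guideline with all published defaults."""
    return nnr_meal_defaults()
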