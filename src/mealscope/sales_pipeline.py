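"""Protein ranking and co-purchase association from receipt lines.

Step one of the analysis ranks protein sources by total sold weight,
after dropping items sold as snacks, starters or spreads and eggs (eggs
occur in every kind of basket, so their associations carry no dish
signal). Shares are normalized over the reported top *k* so they read as
"relative percentage of 100%".

Step two scores, for one anchor protein, which other items consumers buy
together with it, using receipt-level co-occurrence and the standard
basket-mining statistics:

* support — fraction of all receipts containing both anchor and item;
* confidence — P(item | anchor);
* lift — confidence / P(item), >1 meaning above-independence co-purchase.

The underlying retailer tool's association measure is unpublished; the
support/confidence/lift triple is this package's auditable stand-in.
A dish library is then matched against the top associated items by simple
ingredient overlap, and anchors whose best associate has a lift below a
configurable floor are flagged as weak (the published analysis reassigned
such anchors' dishes to other proteins).
"""

from __future__ import annotations

from typing import Iterable, Sequence

import pandas as pd
from pydantic import BaseModel, ConfigDict, Field, model_validator

from .food_model import PROTEIN_CATEGORIES, Catalog, Recipe, ReceiptLine

__all__ = [
    "AssociationRow",
    "AssociationTable",
    "ProteinRanking",
    "RankedProtein",
    "assemble_dishes",
    "association_scores",
    "is_weak_anchor",
    "rank_protein_sources",
]


class RankedProtein(BaseModel):
    model_config = ConfigDict(frozen=True)

    item_id: str
    total_weight_kg: float
    share_of_top_k: float


class ProteinRanking(BaseModel):
    model_config = ConfigDict(frozen=True)

    entries: tuple[RankedProtein, ...]
    k: int

    @model_validator(mode="after")
    def _invariants(self) -> "ProteinRanking":
        shares = sum(e.share_of_top_k for e in self.entries)
        if self.entries and abs(shares - 1.0) > 1e-9:
            raise ValueError(f"shares sum to {shares}, not 1")
        weights = [e.total_weight_kg for e in self.entries]
        if any(a < b for a, b in zip(weights, weights[1:])):
            raise ValueError("entries not in descending weight order")
        return self

    def item_ids(self) -> list[str]:
        return [e.item_id for e in self.entries]


class AssociationRow(BaseModel):
    model_config = ConfigDict(frozen=True)

    item_id: str
    support: float = Field(ge=0, le=1)
    confidence: float = Field(ge=0, le=1)
    lift: float = Field(ge=0)


class AssociationTable(BaseModel):
    model_config = ConfigDict(frozen=True)

    anchor: str
    rows: tuple[AssociationRow, ...]

    @model_validator(mode="after")
    def _anchor_not_listed(self) -> "AssociationTable":
        if any(r.item_id == self.anchor for r in self.rows):
            raise ValueError("anchor listed as its own associate")
        return self

    def top_items(self, m: int) -> list[str]:
        return [r.item_id for r in self.rows[:m]]


def _lines_frame(receipts: Iterable[ReceiptLine]) -> pd.DataFrame:
    return pd.DataFrame(
        [(l.receipt_id, l.item_id, l.weight_kg) for l in receipts],
        columns=["receipt_id", "item_id", "weight_kg"],
    )


def rank_protein_sources(
    receipts: Iterable[ReceiptLine], catalog: Catalog, k: int
) -> ProteinRanking:
    """Top-*k* protein sources by total sold weight, with shares normalized
    over the top *k*. Items carrying an exclusion tag (snack/spread, egg)
    never enter the ranking."""
    if k < 1:
        raise ValueError("k must be >= 1")
    df = _lines_frame(receipts)
    if df.empty:
        raise ValueError("no receipt lines given")

    def eligible(item_id: str) -> bool:
        item = catalog.item(item_id)
        return bool(item.categories & PROTEIN_CATEGORIES) and item.excluded_as == "none"

    totals = df.groupby("item_id")["weight_kg"].sum()
    totals = totals[[eligible(i) for i in totals.index]]
    if len(totals) < k:
        raise ValueError(
            f"only {len(totals)} eligible protein items in the receipts, need k={k}"
        )
    # stable order: weight descending, item_id ascending on ties
    totals = totals.reset_index().sort_values(
        ["weight_kg", "item_id"], ascending=[False, True]
    )
    top = totals.head(k)
    total_weight = top["weight_kg"].sum()
    entries = tuple(
        RankedProtein(
            item_id=row.item_id,
            total_weight_kg=float(row.weight_kg),
            share_of_top_k=float(row.weight_kg / total_weight),
        )
        for row in top.itertuples(index=False)
    )
    return ProteinRanking(entries=entries, k=k)


def association_scores(
    receipts: Iterable[ReceiptLine], anchor: str, min_support: float = 0.0
) -> AssociationTable:
    """Support/confidence/lift of every item against ``anchor`` over
    receipt-level co-occurrence (an item counts once per receipt). Rows
    with support below ``min_support`` are dropped; the table is sorted by
    lift descending, ties broken by support then item_id."""
    df = _lines_frame(receipts)
    baskets = df.groupby("receipt_id")["item_id"].agg(set)
    n = len(baskets)
    if n == 0:
        raise ValueError("no receipts given")
    anchor_baskets = baskets[[anchor in b for b in baskets]]
    n_anchor = len(anchor_baskets)
    if n_anchor == 0:
        raise ValueError(f"anchor {anchor!r} absent from all receipts")

    item_counts: dict[str, int] = {}
    for b in baskets:
        for item in b:
            item_counts[item] = item_counts.get(item, 0) + 1
    both_counts: dict[str, int] = {}
    for b in anchor_baskets:
        for item in b:
            if item != anchor:
                both_counts[item] = both_counts.get(item, 0) + 1

    rows = []
    for item, both in both_counts.items():
        support = both / n
        if support < min_support:
            continue
        confidence = both / n_anchor
        p_item = item_counts[item] / n
        rows.append(
            AssociationRow(
                item_id=item,
                support=support,
                confidence=confidence,
                lift=confidence / p_item,
            )
        )
    rows.sort(key=lambda r: (-r.lift, -r.support, r.item_id))
    return AssociationTable(anchor=anchor, rows=tuple(rows))


def is_weak_anchor(table: AssociationTable, lift_floor: float = 1.5) -> bool:
    """An anchor is weakly associated when even its best associate fails the
    lift floor — no dish can credibly be built around it from basket data."""
    return not table.rows or table.rows[0].lift < lift_floor


def assemble_dishes(
    table: AssociationTable, recipe_library: Sequence[Recipe], top_m: int = 10
) -> list[tuple[Recipe, float]]:
    """Score each library recipe by the fraction of its ingredients found
    among the anchor's top-``top_m`` associated items; sorted by overlap
    descending, ties broken by recipe_id."""
    top_ids = set(table.top_items(top_m))
    scored = [
        (recipe, len(recipe.ingredient_ids() & top_ids) / len(recipe.ingredient_ids()))
        for recipe in recipe_library
    ]
    scored.sort(key=lambda pair: (-pair[1], pair[0].recipe_id))
    return scored
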