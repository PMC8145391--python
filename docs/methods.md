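# Methods

## Unit of analysis and data model

The package analyzes single prepared meals ("dishes") rather than whole
diets. Its inputs mirror what a food retailer and the public Swedish data
sources provide: receipt lines (receipt id, item id, weight), a food
catalog with category tags and substitute links, a nutrient composition
table per 100 g edible food, a climate-factor table in kg CO2e per kg
purchased food, and recipes with as-purchased ingredient amounts and a
serving count.

Two modelling conventions keep aggregation linear:

* **Fractions, not components.** Wholegrain and fruit+vegetable content are
  mass fractions of an ingredient (a 60% wholegrain bread contributes 0.6 g
  wholegrain per gram). How composite products split into fractions is a
  convention of this package, not something the source data dictate.
* **As-purchased amounts.** No cooked-yield conversion is applied; the
  climate factors themselves exclude post-purchase processing (packaging,
  cooking, domestic transport), so purchased mass is the consistent basis.

## Guideline derivation

Daily reference values (energy 1700–3200 kcal; protein 10–20 E%; fat
25–40 E%; saturated fat <10 E%; wholegrain 70–90 g; fiber 25–35 g;
fruit+vegetables 500 g) scale to one main meal with meal fraction 0.30,
the school-lunch convention for a main meal's share of daily intake.
E%→gram conversion uses Atwater factors (4 kcal/g protein, 9 kcal/g fat)
at the meal-energy **midpoint** (735 kcal): this is the only choice that
reproduces all four published gram bounds (18, 37, 20, 33) simultaneously.

Rounding conventions are fixed and uniform: grams from E% round to the
nearest integer, half away from zero; the weekly CO2e budget to the
nearest integer; daily and meal CO2e to one decimal. With these, every
published per-meal number is reproduced exactly except saturated fat:
10 E% of 735 kcal at 9 kcal/g computes to 8.2 g while the published bound
is 9 g. The guideline therefore carries the published 9 g as the operative
bound by default (`saturated_fat_printed_g=9`), keeps the computed value in
`saturated_fat_computed_g`, and lets callers opt into the computed bound.
The discrepancy is documented, not resolved.

The annual food carbon allowance defaults to 590 kg CO2e per capita. The
published derivation chain (1.1 t total × 50% to food = 550) does not
equal the printed 590; the printed figure is taken as authoritative and
the allowance is an input parameter, never derived.

Per-meal components are typed: energy, protein and fat are two-sided
ranges; saturated fat and CO2e are upper bounds; wholegrain, fiber and
fruit+vegetables are lower bounds with no ceiling (average intakes of
these are far below recommendations, so a surplus is not penalized).

## Deviation scoring

Each component of a per-portion profile is reported as
`100 × (value − reference) / reference`, rounded to the nearest integer
percent for reporting (raw values are retained). The reference is the
midpoint for ranges and the bound for one-sided specs — the convention
that uniquely reproduces the published percentages (+236% for 1.68 kg
CO2e vs 0.5; +66% for 44.1 g fat vs the 26.5 midpoint; −44%/−59% for
fiber/fruit+veg below their minima; +132%/+31%/+115% for the altered
dishes above them). Two published figures are not integer-consistent with
any rounding of their printed gram values (97 vs 96 for saturated fat
17.7/9); they derive from unrounded internals unavailable to us and are
excluded from exact checks. Cohort reporting uses deviation-of-means (the
mean profile is scored), matching how each published percentage pairs with
a mean gram value; mean-of-deviations is the documented alternative not
taken. Compliance is evaluated against the actual low/high bounds, never
the reference, so a fiber level far above its minimum deviates +200% and
still complies.

## Basket statistics

The retailer's internal association measure is unpublished. We use the
standard, auditable triple on receipt-level co-occurrence (an item counts
once per receipt): support = P(anchor ∧ item), confidence = P(item |
anchor), lift = confidence / P(item), with a minimum-support filter
(default 0.05) and deterministic ordering (lift desc, support desc,
item id). Protein ranking sums sold weight per item over receipt lines,
keeps items carrying any protein tag that are not excluded as
snack/spread/egg, and normalizes shares over the reported top k only
("relative percentage of 100%"). An anchor whose best associate's lift
falls below a configurable floor (default 1.5) is flagged *weak*; the
published analysis handled such anchors (bacon, whole chicken) by
reassigning their dish slots to stronger anchors, and the flag makes that
manual step an explicit, testable rule. Dish assembly scores each library
recipe by the fraction of its ingredients appearing among the anchor's
top-m associates.

## Repair loop

Repair is a deterministic greedy loop: evaluate, and while non-compliant
apply the first rule whose trigger matches the highest-priority violation,
with priority CO2e > saturated fat > fat > wholegrain > fiber >
fruit+vegetables > energy. Triggers are direction-aware ("fat above",
"fiber below"); a violation with no rule in its direction (fat or protein
*below* range) ends in status `infeasible` — infeasibility is a status,
never an exception, and likewise when the iteration cap (default 50) or a
rule's application bound is reached.

The six default rules and their conventions:

1. **Meat → plant protein** on a climate violation: red/processed meat and
   poultry are replaced *fully* (reducing them cannot reach the meal budget
   while keeping protein adequate). Replacement is protein-equalized:
   substitute amount = old amount × old protein density / new protein
   density. The published alteration does not state substitute amounts;
   protein equalization is this package's convention and is labelled as
   such in traces.
2. **High-impact seafood → low-impact seafood** (salmon→mussels,
   shrimp→clams), protein-equalized.
3. **Full-fat dairy → plant dairy** (fallback low-fat dairy), triggered by
   climate, saturated-fat or fat violations. Gram-for-gram: equalizing the
   ~2 g/100 g protein of cream against oat cream would double sauce
   volumes for no nutritional gain.
4. **Wholegrain**: refined grains swap gram-for-gram to their wholegrain
   substitutes. A dish with no grain at all (potato dishes) instead gains
   the most fiber-dense wholegrain catalog item in 50 g steps — without
   this extension the published "wholegrain couscous was added" edits would
   be unreachable and potato dishes unrepairable.
5. **Vegetable additions** for fiber/fruit+veg shortfalls: 50 g steps of
   the most fiber-dense, lowest-energy vegetable (deterministic pick).
6. **Fat reduction**: added fats/oils scale down by 25% per application for
   residual fat/energy excess.

Every edit appends a trace entry (rule, item, old→new amount); the input
recipe is never mutated, and replaying the recorded rule sequence on the
original reproduces the repaired dish exactly. No numeric optimizer is
used — the published procedure is rule-based, and the greedy loop is the
auditable encoding of it; a minimal-change formulation is a possible
extension, not the default.

## Synthetic data

The generators emulate the statistical structure the pipeline assumes,
not the Swedish market: each receipt draws one anchor protein from planted
popularity shares, adds the anchor's dish-mates with probability 0.9 and
each filler with probability 0.2, and draws line weights uniformly
(0.2–1.0 kg). One seeded NumPy generator drives everything; no global
random state. Planted popularity is recovered as a *weight* share because
all protein anchors share one weight distribution by default; with
per-category weight ranges the recovered quantity would be frequency, not
weight. Random catalogs sample per-category composition ranges with energy
set consistently from the sampled macronutrients, and per-category CO2e
ranges whose midpoints preserve the published qualitative ordering (red
meat > processed meat > high-impact fish > poultry > low-impact seafood >
dairy > plant) — generator defaults, not measurements.

The standard fixture is a curated ~50-item Swedish-style catalog with
realistic per-100 g composition and kg CO2e/kg factors, ten dishes built
around the most-sold protein anchors (two each for chicken breast and
minced beef, covering the two weak anchors' slots), and a receipt
configuration whose dish-mate map uses each dish's distinctive ingredients
(pantry staples are fillers). Prawns are tagged as starter items, so they
are recipe ingredients but not ranking candidates. The fixture dishes are
deliberately meat-anchored, wholegrain-free and vegetable-sparse; their
cohort mean of ~1.69 kg CO2e per portion (≈3.4× the meal budget) mirrors
the published finding qualitatively, by construction. What passing tests
show is that the pipeline recovers planted structure and that the repair
rules drive this cohort to compliance — not that real retail data would
yield the same shares, grams or footprints. Seasonality, promotions,
store effects, price and consumer acceptance are not modelled.

## Sizes, tolerances, degenerate inputs

Statistical tests run at the sizes where planted effects are many standard
errors wide: rank recovery uses 5 anchors with shares separated by 0.05 at
10,000 receipts over 20 seeds (a 0.05 gap is ≈8 s.e., so ≥19/20 recovery
is expected with large margin); lift separation uses 5,000 receipts, where
the weakest planted dish-mate lift (~1.8) sits well above filler lifts
(~1.0 ± 0.1). Anchor-frequency checks use ±3 binomial standard errors.
Portion aggregation is validated against a brute-force per-ingredient
summation oracle at 1e-9 relative tolerance. Degenerate inputs are
defined, not special-cased: zero receipts yield an empty list, an empty
association table yields all-zero assembly overlaps, an already-compliant
recipe returns an empty trace after one iteration, and a zero deviation
reference raises an error.
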