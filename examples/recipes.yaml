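recipes:
- recipe_id: bolognese
  name: Spaghetti Bolognese
  servings: 4
  anchor_protein: minced_beef
  provenance: original
  trace: []
  ingredients:
  - item: minced_beef
    amount_g: 500.0
  - item: spaghetti
    amount_g: 250.0
  - item: crushed_tomatoes
    amount_g: 300.0
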