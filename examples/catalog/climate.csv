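item_id,co2e_per_kg
crushed_tomatoes,0.6
minced_beef,26.0
soy_mince,1.1
spaghetti,0.8
wholegrain_spaghetti,0.8
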