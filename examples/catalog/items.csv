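item_id,name,categories,excluded_as,substitutes
crushed_tomatoes,Crushed tomatoes,vegetable,none,
minced_beef,Minced meat (beef),protein_red_meat,none,soy_mince:plant_protein
soy_mince,Soy mince (hydrated),protein_plant,none,
spaghetti,Spaghetti (dry),grain_refined,none,wholegrain_spaghetti:wholegrain
wholegrain_spaghetti,Wholegrain spaghetti (dry),grain_whole,none,
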