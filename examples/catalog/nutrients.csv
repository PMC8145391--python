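item_id,energy_kcal,protein_g,fat_g,saturated_fat_g,fiber_g,wholegrain_fraction,fruit_veg_fraction
crushed_tomatoes,30.0,1.2,0.2,0.0,1.3,0.0,1.0
minced_beef,240.0,19.0,18.0,8.0,0.0,0.0,0.0
soy_mince,105.0,16.0,6.0,0.8,5.0,0.0,0.0
spaghetti,360.0,12.0,1.5,0.3,3.0,0.0,0.0
wholegrain_spaghetti,350.0,13.0,2.5,0.4,7.0,1.0,0.0
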