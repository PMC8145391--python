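receipt_id,item_id,weight_kg
r000001,minced_beef,0.5
r000001,spaghetti,1.0
r000001,crushed_tomatoes,0.4
r000002,minced_beef,0.8
r000002,soy_mince,0.3
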