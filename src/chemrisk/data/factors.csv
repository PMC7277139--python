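group,soil_intake_mg_per_day,body_weight_kg,lifetime_days
0-9,80,13.3,30186
10-18,80,53.6,30186
19-65,40,63.3,30186
>65,40,60.7,30186
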