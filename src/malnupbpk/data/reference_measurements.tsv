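measurement	mild	intermediate	severe	iw	uw
weight_kg	52.03	48.24	42.52	70.9	46.3
height_cm	156	157	156	178	165
bwt_ht_kg_m	33.3	30.8	27.4	39.8	28.1
pct_standard_bwt_ht	89.5	82.7	73.9		
serum_albumin_g_100ml	3.8	3.0	2.1		
hematocrit_pct	44.4	37.2	32		
fat_mass_pct	17.7	19.8	15.2		
brain_kg				1.51	1.13
heart_kg				0.33	0.22
liver_kg				1.64	0.94
spleen_kg				0.23	0.11
kidney_kg				0.36	0.21
bone_mineral_content_kg				2.68	1.93
lean_soft_tissue_trunk_kg				24.1	16.9
skeletal_muscle_mass_kg				27.6	16.6
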