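sex	age_months	median_kg	sd_kg
male	3	6.4	0.75
male	6	7.9	0.85
male	12	9.6	1.05
male	24	12.2	1.35
male	36	14.3	1.6
male	48	16.3	1.9
male	60	18.3	2.2
male	120	32.0	5.5
female	3	5.8	0.75
female	6	7.3	0.85
female	12	8.9	1.05
female	24	11.5	1.35
female	36	13.9	1.65
female	48	16.1	2.0
female	60	18.2	2.35
female	120	33.0	6.0
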