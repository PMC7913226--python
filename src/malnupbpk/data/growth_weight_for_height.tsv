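sex	height_cm	median_kg	sd_kg
male	65	7.4	0.65
male	70	8.4	0.72
male	75	9.4	0.8
male	80	10.4	0.9
male	85	11.5	1.0
male	90	12.7	1.1
male	95	14.1	1.22
male	100	15.6	1.35
male	105	17.2	1.52
male	110	18.7	1.7
male	115	20.7	1.95
male	120	22.9	2.2
female	65	7.2	0.65
female	70	8.2	0.75
female	75	9.1	0.84
female	80	10.2	0.95
female	85	11.4	1.05
female	90	12.5	1.15
female	95	13.9	1.3
female	100	15.4	1.45
female	105	17.0	1.65
female	110	18.8	1.9
female	115	21.0	2.15
female	120	23.5	2.45
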