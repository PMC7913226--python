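index	segment	fluid_volume_mL	transit_h	ph_fasted	ph_fed	length_cm	radius_cm	saef
1	stomach	50	0.25	2.0	4.5	20	4.0	1
2	duodenum	30	0.26	6.0	5.4	25	1.6	500
3	upper_jejunum	50	0.95	6.2	6.2	60	1.5	500
4	lower_jejunum	50	0.75	6.4	6.4	60	1.4	500
5	upper_ileum	40	0.65	6.8	6.8	60	1.3	500
6	lower_ileum	40	0.69	7.2	7.2	60	1.2	500
7	caecum	30	4.0	6.0	6.0	7	3.5	4
8	ascending_colon	25	8.0	6.3	6.3	20	2.4	2
9	transverse_colon	20	8.0	6.6	6.6	45	2.4	2
10	descending_colon	15	8.0	7.0	7.0	30	2.4	2
11	sigmoid_colon	10	8.0	7.0	7.0	40	2.0	2
12	rectum	5	8.0	7.0	7.0	15	2.0	0
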