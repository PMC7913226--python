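tissue	f_ew	f_iw	f_nl	f_np	ap_mg_g	ratio_alb	ratio_lip	f_protein
adipose	0.135	0.017	0.846	0.0016	0.40	0.049	0.068	0.05
bone	0.100	0.346	0.017	0.0017	0.67	0.100	0.050	0.20
brain	0.162	0.620	0.039	0.0015	0.40	0.048	0.041	0.11
gut	0.282	0.475	0.038	0.0125	2.41	0.158	0.0141	0.15
stomach	0.282	0.475	0.038	0.0125	2.41	0.158	0.0141	0.15
heart	0.320	0.456	0.014	0.0111	2.25	0.157	0.0160	0.16
kidney	0.273	0.483	0.012	0.0240	5.03	0.130	0.0137	0.16
liver	0.161	0.573	0.014	0.0240	4.56	0.086	0.0161	0.20
lung	0.336	0.446	0.022	0.0128	3.91	0.212	0.0168	0.15
muscle	0.118	0.630	0.010	0.0072	1.53	0.064	0.0059	0.19
pancreas	0.120	0.664	0.041	0.0093	1.67	0.060	0.0203	0.15
skin	0.382	0.291	0.060	0.0044	1.32	0.277	0.0096	0.30
spleen	0.207	0.579	0.0077	0.0113	3.18	0.097	0.0207	0.18
gonads	0.150	0.626	0.017	0.0092	2.30	0.075	0.0165	0.15
plasma	0.945	0.0	0.0035	0.00225	0.04	1.0	1.0	0.06
erythrocyte	0.0	0.603	0.0017	0.0029	0.50	0.0	0.0	0.35
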