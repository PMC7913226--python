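# Caffeine — CYP1A2-cleared methylxanthine, oral solution.
name: caffeine
logP: 0.87
fu_p: 0.7
mw_g_mol: 194.2
pka:
  - {value: 0.8, type: base}
solubility:
  - {mg_ml: 21.6, ph: 7.0, prandial: any}
distribution_method: pksim
p_int_1e6_cm_min: 223.0
renal:
  gfr_fraction: 0.0
  cl_spec_per_min: 2.46e-3
hepatic:
  vmax_pmol_min_mg: 73.1
  km_um: 14.7
  pathway: CYP1A2
erythrocytes:
  f_proteins: 0.0
  f_lipid: 0.0
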