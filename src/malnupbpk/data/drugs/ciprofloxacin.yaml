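# Ciprofloxacin — fluoroquinolone ampholyte, oral suspension.
# Absorption constrained to the proximal gut: caecum surface-area enhancement
# optimized to 26.24 and the remaining large intestine set to 0.
name: ciprofloxacin
logP: 0.95
fu_p: 0.67
mw_g_mol: 331.3
pka:
  - {value: 6.09, type: acid}
  - {value: 8.62, type: base}
solubility:
  - {mg_ml: 38.4, ph: 7.0, prandial: any}
distribution_method: pksim
p_int_1e6_cm_min: 1.57
saef_overrides:
  caecum: 26.24
  ascending_colon: 0.0
  transverse_colon: 0.0
  descending_colon: 0.0
  sigmoid_colon: 0.0
  rectum: 0.0
renal:
  gfr_fraction: 1.0
  cl_spec_per_min: 1.61
hepatic:
  cl_spec_per_min: 0.043
  pathway: CYP1A2
  biliary_cl_spec_per_min: 0.096
erythrocytes:
  f_proteins: 0.0
  f_lipid: 0.0
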