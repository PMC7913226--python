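# Cefoxitin — renally eliminated cephamycin, intravenous use.
# Renal elimination: glomerular filtration plus active tubular secretion.
name: cefoxitin
logP: 0.84
fu_p: 0.48
mw_g_mol: 427.45
pka:
  - {value: 3.58, type: acid}
solubility:
  - {mg_ml: 0.2, ph: 7.0, prandial: any}
distribution_method: rodgers_rowland
p_int_1e6_cm_min: 0.161
renal:
  gfr_fraction: 1.0
  cl_spec_per_min: 3.8
hepatic: null
erythrocytes:
  f_proteins: 0.0
  f_lipid: 0.0
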