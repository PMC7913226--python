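# Pyrimethamine — antifolate with unspecific hepatic elimination plus
# glomerular filtration; erythrocyte partitioning tuned via the blood-cell
# protein fraction (V_f.proteins = 0.19, V_f.lipid = 0).
name: pyrimethamine
logP: 3.14
fu_p: 0.095
mw_g_mol: 248.71
pka:
  - {value: 6.9, type: base}
solubility:
  - {mg_ml: 0.12, ph: 5.0, prandial: any}
distribution_method: rodgers_rowland
p_int_1e6_cm_min: 6370.0
renal:
  gfr_fraction: 1.0
hepatic:
  cl_spec_per_min: 0.089
  pathway: unspecific_hepatic
dissolution:
  any: {t50_min: 10.0, shape: 1.0}
erythrocytes:
  f_proteins: 0.19
  f_lipid: 0.0
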