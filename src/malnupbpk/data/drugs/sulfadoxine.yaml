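# Sulfadoxine — long-acting sulfonamide; renal elimination slower than
# filtration (GFR fraction 0.21, net tubular reabsorption). Erythrocyte
# partitioning tuned via V_f.proteins = 0.06, V_f.lipid = 0.
name: sulfadoxine
logP: 3.74
fu_p: 0.036
mw_g_mol: 310.33
pka:
  - {value: 6.2, type: acid}
solubility:
  - {mg_ml: 0.474, ph: 5.0, prandial: any}
distribution_method: rodgers_rowland
p_int_1e6_cm_min: 1690.0
renal:
  gfr_fraction: 0.21
hepatic: null
dissolution:
  any: {t50_min: 10.0, shape: 1.0}
erythrocytes:
  f_proteins: 0.06
  f_lipid: 0.0
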