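# Lumefantrine — highly lipophilic, highly protein-bound antimalarial cleared
# by CYP3A4. Solubility and dissolution are prandial-state specific; the fed
# entry carries the milk-anchored solubility used for a nutritional drink.
name: lumefantrine
logP: 3.09
fu_p: 0.0029
mw_g_mol: 528.9
pka:
  - {value: 9.35, type: base}
solubility:
  - {mg_ml: 0.0097, ph: 6.5, prandial: fasted}
  - {mg_ml: 0.05, ph: 5.0, prandial: fed}
  - {mg_ml: 0.18, ph: 5.0, prandial: fed_high_fat}
distribution_method: pksim
p_int_1e6_cm_min: 24.4
renal:
  gfr_fraction: 1.0
hepatic:
  cl_int_ul_min_mg: 93.7
  pathway: CYP3A4
dissolution:
  fasted: {t50_min: 270.0, shape: 6.9}
  fed: {t50_min: 217.0, shape: 1.9}
erythrocytes:
  f_proteins: 0.0
  f_lipid: 0.0
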