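# Study registry: per drug, the administration setups replicating the
# reference simulations (adult model development and pediatric evaluation).
caffeine:
  adult:
    route: oral_solution
    prandial: fasted
    dose_mg: 300.0
    age_range: [30.0, 30.0]
    duration_h: 36.0
  pediatric:
    route: oral_solution
    prandial: fed
    meal: {volume_ml: 100.0, kcal: 75.0}
    dose_mg: 40.0
    dose_mg_per_kg: 3.2
    age_range: [1.3, 4.5]
    duration_h: 48.0
cefoxitin:
  adult:
    route: iv_infusion
    infusion_min: 5.0
    prandial: fasted
    dose_mg: 2000.0
    age_range: [30.0, 30.0]
    duration_h: 12.0
  pediatric:
    route: iv_infusion
    infusion_min: 5.0
    prandial: fasted
    dose_mg: 520.0
    dose_mg_per_kg: 40.0
    age_range: [1.33, 3.33]   # mean 28 months +/- 12 months
    duration_h: 12.0
ciprofloxacin:
  adult:
    route: oral_suspension
    particle_radius_um: 10.0
    prandial: fasted
    dose_mg: 750.0
    age_range: [30.0, 30.0]
    duration_h: 36.0
  pediatric:
    route: oral_suspension
    particle_radius_um: 10.0
    prandial: fed
    meal: {volume_ml: 200.0, kcal: 300.0}
    dose_mg: 120.0
    dose_mg_per_kg: 10.0
    age_range: [1.8, 2.2]
    duration_h: 36.0
lumefantrine:
  development:
    route: oral_solid
    dissolution: weibull
    prandial: fed
    dose_mg: 480.0
    age_range: [30.0, 30.0]
    duration_h: 264.0
  pediatric:
    route: oral_solid
    dissolution: weibull
    prandial: fed
    meal: {volume_ml: 100.0, kcal: 75.0}
    dose_mg: 120.0
    dose_mg_per_kg: 12.0
    age_range: [0.5, 5.0]
    duration_h: 264.0
pyrimethamine:
  development:
    route: oral_solid
    dissolution: weibull
    prandial: fasted
    dose_mg: 25.0
    age_range: [30.0, 30.0]
    duration_h: 504.0
  pediatric:
    route: oral_solid
    dissolution: weibull
    prandial: fasted
    dose_mg: 25.0
    dose_mg_per_kg: 1.8
    age_range: [0.5, 5.0]
    duration_h: 504.0
sulfadoxine:
  development:
    route: oral_solid
    dissolution: weibull
    prandial: fasted
    dose_mg: 500.0
    age_range: [30.0, 30.0]
    duration_h: 504.0
  pediatric:
    route: oral_solid
    dissolution: weibull
    prandial: fasted
    dose_mg: 500.0
    dose_mg_per_kg: 36.0
    age_range: [0.5, 5.0]
    duration_h: 504.0
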