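# Reference model configuration for the HER2-positive gastric/GEJ
# adenocarcinoma evaluation: pembrolizumab + trastuzumab + chemotherapy (PEM)
# vs. trastuzumab + chemotherapy (TRAS).  All costs in 2024 USD.
schema_version: 1
population: total
# willingness-to-pay anchor: three times Chinese per-capita GDP (2024 USD/QALY)
wtp: 39999.86

engine:
  cycle_length_days: 21
  horizon_years: 30
  discount_rate: {base: 0.05, low: 0.00, high: 0.08, dist: fixed}

patient:
  weight_kg: {base: 60.0, low: 48.0, high: 72.0, dist: fixed}
  bsa_m2: {base: 1.6, low: 1.28, high: 1.92, dist: fixed}

utilities:
  pfs: {base: 0.797, low: 0.598, high: 0.966, dist: beta}
  pd: {base: 0.577, low: 0.433, high: 0.721, dist: beta}

costs:
  follow_up_per_cycle: {base: 45.01, low: 36.01, high: 54.02, dist: gamma}
  administration_per_cycle: {base: 62.40, low: 49.92, high: 74.89, dist: gamma}
  end_of_life: {base: 2122.47, low: 1697.97, high: 2546.96, dist: gamma}
  best_supportive_care_per_cycle: {base: 348.00, low: 278.40, high: 417.61, dist: gamma}

drugs:
  pembrolizumab:
    unit_size_mg: 100
    unit_cost: {base: 2495.13, low: 1996.10, high: 2495.13, dist: gamma}
    dose_rule: flat_mg
    dose_amount: 200
    admins_per_cycle: 1
    line: first
    arms: [PEM]
    component: backbone
  trastuzumab:
    unit_size_mg: 1
    unit_cost: {base: 1.74, low: 1.39, high: 2.09, dist: gamma}
    dose_rule: per_kg
    dose_amount: 6
    loading_per_kg: 8
    admins_per_cycle: 1
    line: first
    component: backbone
  fluorouracil:
    unit_size_mg: 100
    unit_cost: {base: 1.80, low: 1.44, high: 2.16, dist: gamma}
    dose_rule: per_m2
    dose_amount: 800
    admins_per_cycle: 5          # days 1-5 of each 3-week cycle
    line: first
    component: fp
  cisplatin:
    unit_size_mg: 10
    unit_cost: {base: 1.19, low: 0.95, high: 1.43, dist: gamma}
    dose_rule: per_m2
    dose_amount: 80
    admins_per_cycle: 1
    line: first
    component: fp
  capecitabine:
    unit_size_mg: 1000
    unit_cost: {base: 0.59, low: 0.47, high: 0.71, dist: gamma}
    dose_rule: per_m2
    dose_amount: 1000
    admins_per_cycle: 28         # twice daily, days 1-14
    line: first
    component: capox
  oxaliplatin:
    unit_size_mg: 100
    unit_cost: {base: 57.98, low: 46.38, high: 69.57, dist: gamma}
    dose_rule: per_m2
    dose_amount: 130
    admins_per_cycle: 1
    line: first
    component: capox
  ramucirumab:
    unit_size_mg: 1
    unit_cost: {base: 6.09, low: 4.87, high: 7.31, dist: gamma}
    dose_rule: per_kg
    dose_amount: 8
    admins_per_cycle: 2          # days 1 and 15 of a 28-day cycle
    line: second
    component: second
    cycle_days: 28
  paclitaxel:
    unit_size_mg: 10
    unit_cost: {base: 2.58, low: 2.07, high: 3.10, dist: gamma}
    dose_rule: per_m2
    dose_amount: 80
    admins_per_cycle: 3          # days 1, 8 and 15 of a 28-day cycle
    line: second
    component: second
    cycle_days: 28

first_line:
  cap_cycles: 35
  chemo_mix:
    PEM: {fp: 0.15, capox: 0.85}
    TRAS: {fp: 0.14, capox: 0.86}

subsequent_treatment:
  rate:
    PEM: {base: 0.39, low: 0.00, high: 1.00, dist: fixed}
    TRAS: {base: 0.47, low: 0.00, high: 1.00, dist: fixed}

adverse_events:
  costs:
    neutropenia: {base: 551.40, low: 441.12, high: 661.68, dist: gamma}
    platelet_count_decreased: {base: 1648.55, low: 1318.84, high: 1978.26, dist: gamma}
    anemia: {base: 486.62, low: 389.30, high: 583.95, dist: gamma}
    diarrhea: {base: 46.01, low: 36.81, high: 55.21, dist: gamma}
    neutrophil_count_decreased: {base: 551.40, low: 441.12, high: 661.68, dist: gamma}
  disutilities:
    neutropenia: {base: 0.39, low: 0.31, high: 0.47, dist: gamma}
    platelet_count_decreased: {base: 0.11, low: 0.08, high: 0.14, dist: gamma}
    anemia: {base: 0.07, low: 0.05, high: 0.09, dist: gamma}
    diarrhea: {base: 0.04, low: 0.03, high: 0.05, dist: gamma}
    neutrophil_count_decreased: {base: 0.20, low: 0.15, high: 0.25, dist: gamma}
  incidence:
    PEM:
      neutropenia: {base: 0.0629, low: 0.0503, high: 0.0754, dist: beta}
      platelet_count_decreased: {base: 0.0629, low: 0.0503, high: 0.0754, dist: beta}
      anemia: {base: 0.0600, low: 0.0480, high: 0.0720, dist: beta}
      diarrhea: {base: 0.0886, low: 0.0709, high: 0.1063, dist: beta}
      neutrophil_count_decreased: {base: 0.0800, low: 0.0640, high: 0.0960, dist: beta}
    TRAS:
      platelet_count_decreased: {base: 0.0665, low: 0.0532, high: 0.0798, dist: beta}
      anemia: {base: 0.0578, low: 0.0462, high: 0.0694, dist: beta}
      diarrhea: {base: 0.0780, low: 0.0624, high: 0.0936, dist: beta}
      neutrophil_count_decreased: {base: 0.0867, low: 0.0694, high: 0.1040, dist: beta}

# Patient-assistance program for pembrolizumab: the first free_after_n
# cycles are self-paid; later cycles of the course are program-funded.
assistance:
  mode: free_after_n
  free_after_n: 4

pd_costing:
  bsc_additive: false

selection:
  criterion: aic

curves:
  fixture: paper_like_total
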