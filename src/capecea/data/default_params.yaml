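# Base-case parameterization of the capecitabine-maintenance cost-effectiveness
# model. All monetary amounts in 2020 USD (fixed rate $1 = ¥6.4665); ranges are
# the deterministic sensitivity bounds; "distribution" is the PSA sampling law.
entries:
  cost_capecitabine_month:
    {base: 306.48, low: 26.84, high: 306.48, distribution: gamma, kind: cost}
  cost_monitoring_month:
    {base: 46.83, low: 37.46, high: 56.20, distribution: gamma, kind: cost}
  cost_relapse_month:
    {base: 1546.43, low: 773.22, high: 2319.65, distribution: gamma, kind: cost}
  cost_followup_lt3y:
    {base: 38.39, low: 30.71, high: 46.07, distribution: gamma, kind: cost}
  cost_followup_3to5y:
    {base: 21.32, low: 17.06, high: 25.58, distribution: gamma, kind: cost}
  cost_followup_gt5y:
    {base: 12.78, low: 10.22, high: 15.34, distribution: gamma, kind: cost}
  cost_time_y1_capecitabine:
    {base: 49.97, low: 39.97, high: 59.96, distribution: gamma, kind: cost}
  cost_time_y1_observation:
    {base: 16.66, low: 13.33, high: 19.99, distribution: gamma, kind: cost}
  cost_time_1to2y:
    {base: 16.66, low: 13.33, high: 19.99, distribution: gamma, kind: cost}
  cost_time_3to5y:
    {base: 8.33, low: 6.66, high: 10.00, distribution: gamma, kind: cost}
  cost_time_gt5y:
    {base: 4.16, low: 3.33, high: 4.99, distribution: gamma, kind: cost}
  cost_travel_y1_capecitabine:
    {base: 12.37, low: 9.90, high: 14.84, distribution: gamma, kind: cost}
  cost_travel_y1_observation:
    {base: 4.12, low: 3.30, high: 4.94, distribution: gamma, kind: cost}
  cost_travel_1to2y:
    {base: 4.12, low: 3.30, high: 4.94, distribution: gamma, kind: cost}
  cost_travel_3to5y:
    {base: 2.06, low: 1.65, high: 2.47, distribution: gamma, kind: cost}
  cost_travel_gt5y:
    {base: 1.03, low: 0.82, high: 1.24, distribution: gamma, kind: cost}
  cost_ae_hand_foot:
    {base: 15.46, low: 12.37, high: 18.55, distribution: gamma, kind: cost}
  cost_ae_diarrhea:
    {base: 44.30, low: 28.50, high: 54.60, distribution: gamma, kind: cost}
  incidence_hand_foot:
    {base: 0.1345, low: 0.1144, high: 0.1547, distribution: beta, kind: probability}
  incidence_diarrhea:
    {base: 0.0319, low: 0.0215, high: 0.0422, distribution: beta, kind: probability}
  utility_dfs:
    {base: 0.80, low: 0.73, high: 0.87, distribution: beta, kind: utility}
  utility_relapse:
    {base: 0.73, low: 0.66, high: 0.80, distribution: beta, kind: utility}
  disutility_hand_foot:
    {base: 0.12, low: 0.096, high: 0.144, distribution: beta, kind: utility}
  disutility_diarrhea:
    {base: 0.10, low: 0.08, high: 0.12, distribution: beta, kind: utility}
  annual_discount_rate:
    {base: 0.05, low: 0.0, high: 0.10, distribution: fixed, kind: rate}
  transition_multiplier:
    {base: 1.0, low: 0.95, high: 1.05, distribution: uniform, kind: multiplier}

# Log-normal survival fits (location mu on log time, scale sigma); the time
# unit of the printed fits is unresolved ("model-fit") and is re-anchored to
# months against the 5-year trial survival before use (survival_input_mode).
survival:
  capecitabine:
    dfs: {distribution: lognormal, mu: 6.400, sigma: 0.908, time_unit: model-fit}
    os: {distribution: lognormal, mu: 6.074, sigma: 0.627, time_unit: model-fit}
  observation:
    dfs: {distribution: lognormal, mu: 5.437, sigma: 0.753, time_unit: model-fit}
    os: {distribution: lognormal, mu: 5.555, sigma: 0.505, time_unit: model-fit}

# 5-year Kaplan-Meier anchors (time in months, survival fraction)
anchors:
  capecitabine:
    dfs: [[60.0, 0.828]]
    os: [[60.0, 0.855]]
  observation:
    dfs: [[60.0, 0.730]]
    os: [[60.0, 0.813]]

model:
  wtp_threshold: 28130.0
  horizon_cycles: 360
  cycles_per_year: 12
  start_age: 45.0
  retirement_age: 55.0
  treatment_cycles: 12

options:
  relapse_death_mode: os_formula
  survival_input_mode: calibrated
  followup_during_treatment: true
  half_cycle_correction: false
  relapse_cost_mode: occupancy
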