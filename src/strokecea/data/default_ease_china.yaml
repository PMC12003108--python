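# Base-case model inputs: Chinese healthcare system perspective, 2023 CNY.
# Ranges are published 95% intervals (or plausible ranges read as such).
mrs_distribution:        # month-3 mRS distribution, standard-therapy arm
  point: [0.116, 0.211, 0.175, 0.231, 0.112, 0.092, 0.063]
  low:   [0.080, 0.165, 0.132, 0.184, 0.077, 0.060, 0.035]
  high:  [0.152, 0.257, 0.218, 0.278, 0.148, 0.125, 0.090]
risk_ratios:             # argatroban vs control, per mRS category, with 95% CI
  point: [1.63, 0.99, 0.92, 1.07, 0.90, 0.58, 0.64]
  low:   [1.10, 0.72, 0.64, 0.81, 0.56, 0.32, 0.32]
  high:  [2.40, 1.34, 1.32, 1.43, 1.43, 1.05, 1.30]
probabilities:
  p_sich_argatroban: {point: 0.009, low: 0.0, high: 0.020}
  p_sich_control:    {point: 0.007, low: 0.0, high: 0.018}
  annual_recurrence: {point: 0.112, low: 0.096, high: 0.128}   # annual incidence
  recurrence_case_fatality: {point: 0.21, low: 0.189, high: 0.232}
hazard_ratios:           # non-stroke death hazard ratio per alive mRS state
  point: [1.0, 1.0, 1.11, 1.27, 1.71, 2.37]
  low:   [1.0, 1.0, 1.00, 1.02, 1.37, 1.90]
  high:  [1.2, 1.2, 1.30, 1.52, 2.05, 2.84]
mortality_table:         # background annual death probability, China
  - {age_low: 66, age_high: 70, annual_probability: 0.01266}
  - {age_low: 70, age_high: 75, annual_probability: 0.02159}
  - {age_low: 75, age_high: 80, annual_probability: 0.03731}
  - {age_low: 80, age_high: 85, annual_probability: 0.0634}
  - {age_low: 85, age_high: null, annual_probability: 0.1512}
utilities:
  point: [0.95, 0.89, 0.67, 0.44, 0.16, 0.10, 0.0]
  low:   [0.94, 0.87, 0.54, 0.29, 0.09, 0.00, 0.0]
  high:  [0.96, 0.96, 0.83, 0.60, 0.23, 0.21, 0.0]
  u_recurrence:    {point: 0.42, low: 0.11, high: 0.71}
  sich_disutility: {point: 0.38, low: 0.30, high: 0.46}
costs:                   # 2023 CNY
  # 1.614 is the national median procurement price; it reproduces the
  # published 355 CNY per 220 mg course (Table value 1.61 is rounded).
  drug_price_per_mg:        {point: 1.614, low: 1.58, high: 7.05}
  acute_mrs01:              {point: 12472, low: 7204, high: 15704}
  acute_mrs25:              {point: 16490, low: 9063, high: 21624}
  acute_death:              {point: 14133, low: 6640, high: 18679}
  sich_cost:                {point: 3012,  low: 654,  high: 6285}
  annual_post_mrs01:        {point: 8867,  low: 2655, high: 11311}
  annual_post_mrs25:        {point: 13492, low: 3393, high: 16968}
  recurrent_stroke_cost:    {point: 18380, low: 13785, high: 22976}
  infusion_first_hour:      {point: 15.6,  low: 5.0,  high: 30.0}
  infusion_additional_hour: {point: 1.0,   low: 0.5,  high: 2.0}
settings:
  discount_rate: {point: 0.05, low: 0.0, high: 0.08}
  start_age: 66
  horizon_years: 30
  cycle_length: 0.25
  wtp_1x: 89358      # 1x Chinese per-capita GDP 2023, CNY per QALY
  wtp_3x: 268074     # 3x per-capita GDP
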