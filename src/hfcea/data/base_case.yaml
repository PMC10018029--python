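# Base-case model inputs: monthly transition probabilities, costs (USD, 2021),
# utilities, discounting and PSA hyper-parameters, plus the age-banded monthly
# non-cardiovascular mortality table and the healthcare CPI chain used for
# cost inflation and the discount-rate derivation.
parameters:
  # cardiovascular death, vulnerable phase (hospitalized month + 2 months post-discharge)
  p_cvd_early_sv: {base: 0.0114, low: 0.0044, high: 0.0185, sd: 0.0035, dist: beta}
  p_cvd_early_ena: {base: 0.0172, low: 0.0086, high: 0.0258, sd: 0.0044, dist: beta}
  # cardiovascular death, stable phase (>= 3 non-hospitalized months)
  p_cvd_late_sv: {base: 0.0053, low: 0.0048, high: 0.0057, sd: 0.0002, dist: beta}
  p_cvd_late_ena: {base: 0.0066, low: 0.0061, high: 0.0071, sd: 0.0003, dist: beta}
  # hospitalization / readmission
  p_hosp_early_sv: {base: 0.0406, low: 0.0275, high: 0.0539, sd: 0.0067, dist: beta}
  p_hosp_early_ena: {base: 0.0717, low: 0.0545, high: 0.0893, sd: 0.0089, dist: beta}
  p_hosp_late_sv: {base: 0.0256, low: 0.0228, high: 0.0285, sd: 0.0014, dist: beta}
  p_hosp_late_ena: {base: 0.0339, low: 0.0306, high: 0.0373, sd: 0.0017, dist: beta}
  # costs (USD): sac-val drug price per month; enalapril + standard care per
  # month; one hospitalization event
  cost_sv_month: {base: 50.5, low: 25.2, high: 180.7, sd: 18.0, dist: gamma}
  cost_ena_month: {base: 37.9, low: 18.9, high: 75.7, sd: 3.8, dist: gamma}
  cost_hosp_event: {base: 2361.5, low: 1180.7, high: 4722.9, sd: 236.0, dist: gamma}
  # utilities (QALY per month; hospitalization is a one-off decrement per event)
  u_sv_month: {base: 0.0698, low: 0.0628, high: 0.0768, sd: 0.0036, dist: beta}
  u_ena_month: {base: 0.0691, low: 0.0622, high: 0.076, sd: 0.0035, dist: beta}
  u_hosp_event: {base: -0.1, low: -0.08, high: -0.13, sd: 0.0128, dist: beta}
  # annual discount rate: one-way range only, fixed in the PSA
  discount_annual: {base: 0.03, low: 0.0, high: 0.06}
wtp: 37654.5        # USD per QALY, three times 2021 per-capita GDP
start_age: 60       # years
horizon_cycles: 480 # monthly cycles (lifetime horizon, age 60 -> 100)
life_table:         # band-start age -> monthly non-cardiovascular death probability
  60: 0.0004
  65: 0.0007
  70: 0.0010
  75: 0.0017
  80: 0.0026
  85: 0.0054
cpi:
  years: [2015, 2016, 2017, 2018, 2019, 2020, 2021]
  multipliers: [1.027, 1.038, 1.06, 1.043, 1.024, 1.018, 1.004]
  cny_per_usd: 6.4515
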