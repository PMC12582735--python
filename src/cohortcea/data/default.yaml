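# Default model configuration: published Jordanian payer-perspective inputs.
#
# Transition probabilities (per 3-month cycle, constant over the horizon),
# their standard errors, per-mg drug prices with SEs, adverse-event annual
# probabilities, and healthcare-service unit costs are the published values.
#
# NOTE ON DOSES: the published analysis priced treatments from median daily
# doses that are not reproduced here.  The dose entries below are
# ASSUMPTIONS taken from the products' label ranges (titration in cycle 1,
# maintenance afterwards) and should be replaced with setting-specific
# values before any real decision use.

reference: BRV

treatments:
  BRV:
    transitions:
      p_sf: 0.065
      p_pr: 0.355
      p_nr: 0.370
      p_disc: 0.210
      se_sf: 0.003
      se_pr: 0.018
      se_nr: 0.011
      se_disc: 0.011
    ae_annual_probabilities:
      ataxia: 0.030
      dizziness: 0.130
      fatigue: 0.110
      nausea: 0.050
      somnolence: 0.140
    dose:                      # assumption (label range), not a published value
      titration_daily_dose_mg: 50
      maintenance_daily_dose_mg: 100
    drug_cost_per_mg: 0.042
    drug_cost_se: 0.016
  ESL:
    transitions:
      p_sf: 0.032
      p_pr: 0.330
      p_nr: 0.469
      p_disc: 0.169
      se_sf: 0.002
      se_pr: 0.017
      se_nr: 0.009
      se_disc: 0.009
    ae_annual_probabilities:
      ataxia: 0.060
      dizziness: 0.230
      fatigue: 0.060
      nausea: 0.120
      somnolence: 0.120
    dose:                      # assumption (label range), not a published value
      titration_daily_dose_mg: 400
      maintenance_daily_dose_mg: 800
    drug_cost_per_mg: 0.004
    drug_cost_se: 0.004
  LCM:
    transitions:
      p_sf: 0.030
      p_pr: 0.308
      p_nr: 0.448
      p_disc: 0.214
      se_sf: 0.002
      se_pr: 0.016
      se_nr: 0.011
      se_disc: 0.011
    ae_annual_probabilities:
      ataxia: 0.080
      dizziness: 0.240
      fatigue: 0.060
      nausea: 0.110
      somnolence: 0.100
    dose:                      # assumption (label range), not a published value
      titration_daily_dose_mg: 100
      maintenance_daily_dose_mg: 400
    drug_cost_per_mg: 0.013
    drug_cost_se: 0.003
  PER:
    transitions:
      p_sf: 0.035
      p_pr: 0.296
      p_nr: 0.493
      p_disc: 0.176
      se_sf: 0.002
      se_pr: 0.015
      se_nr: 0.009
      se_disc: 0.009
    ae_annual_probabilities:
      ataxia: 0.040
      dizziness: 0.230
      fatigue: 0.070
      nausea: 0.010
      somnolence: 0.140
    dose:                      # assumption (label range), not a published value
      titration_daily_dose_mg: 2
      maintenance_daily_dose_mg: 8
    drug_cost_per_mg: 0.804
    drug_cost_se: 0.267

services:
  inpatient_night: 100
  emergency_visit: 30
  neurologist_visit: 14
  gp_visit: 8
  eeg: 100
  cost_variation: 0.25

ae_drug_costs:
  acetazolamide:
    cost_per_mg: 0.001
    cost_se: 0.001
  cinnarizine:
    cost_per_mg: 0.001
    cost_se: 0.001

ae_management:
  ataxia:
    drug: acetazolamide
    daily_dose_mg: 500       # assumption: typical adult daily dose
    treated_days: 90
  dizziness:
    drug: cinnarizine
    daily_dose_mg: 75        # assumption: typical adult daily dose
    treated_days: 90
  nausea:
    drug: cinnarizine
    daily_dose_mg: 75
    treated_days: 90
  fatigue: {}
  somnolence: {}

state_bundles:
  SEIZURE_FREE:
    neurologist_visits: 1
    eeg_tests: 1
  PARTIAL_RESPONSE:
    neurologist_visits: 1
    eeg_tests: 1
  NON_RESPONSE:
    neurologist_visits: 1
    eeg_tests: 1
    emergency_visits: 1
    inpatient_nights: 1
  DISCONTINUED:
    neurologist_visits: 1

model:
  cycle_length_days: 90
  n_cycles: 8
  structural_variant: absorbing_sf_disc
  effect_definition: ever_sf

discount:
  annual_rate: 0.035
  psa_low: 0.0
  psa_high: 0.05

psa:
  n_iterations: 2000
  seed: 0
  ae_probability_pct: 0.25
  discount_rate_se: 0.00625

ae_accrual: all_cycles
wtp_threshold: 9000
wtp_grid_max: 12000
wtp_grid_step: 500
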