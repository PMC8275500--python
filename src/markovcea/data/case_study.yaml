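states:
- SD
- PD
- Dead
cycle_days: 28.0
absorption_threshold: 0.99
transition_source: table
population:
  cohort_size: 1000
  start_age: 63.0
  male_fraction: 0.505
transitions:
  sd_pd_control: 0.0854
  sd_pd_intervention: 0.0183
  sd_d_control: 0.0095
  sd_d_intervention: 0.0073
  pd_d_control: 0.0216
  pd_d_intervention: 0.0116
  ci_sd_pd_intervention:
  - 0.0119
  - 0.0283
  ci_sd_d_intervention:
  - 0.0059
  - 0.0088
  ci_pd_d_intervention:
  - 0.0093
  - 0.0139
  profile_sd_pd: exponential
  profile_death: gamma
  gamma_shape: 1.833
  gamma_rate: 5.5
hazard_ratios:
  hr_pfs: 0.21
  hr_os: 0.54
  hr_sd_vs_pd: 0.44
  ci_pfs:
  - 0.14
  - 0.33
  ci_os: null
  ci_sd_vs_pd:
  - 0.24
  - 0.79
utilities:
  u_sd: 0.771
  u_sd_range:
  - 0.509
  - 0.818
  u_sd_ae_control: 0.666
  u_sd_ae_control_range:
  - 0.619
  - 0.709
  u_sd_ae_intervention: 0.687
  u_sd_ae_intervention_range:
  - 0.642
  - 0.73
  u_pd: 0.612
  u_pd_range:
  - 0.564
  - 0.659
  u_dead: 0.0
  ae_affected_fraction_control: 0.1
  ae_affected_fraction_intervention: 0.2
  ae_window_cycles: 1
costs:
  lo_price_initial: 16000.0
  lo_price_increased: 90000.0
  lo_n_injections: 4
  lo_injection_cycles:
  - 0
  - 2
  - 4
  - 6
  lo_admin_per_injection: 1000.0
  olar_cycle_control: 4025.0
  olar_cycle_intervention: 1375.0
  ae_management_control: 500.0
  ae_management_intervention: 1500.0
  pd_followup_visit: 150.0
  pd_followup_interval_months: 6.0
  indirect:
    annual_at_start_age: 3600.0
    annual_growth_per_year: 0.05
    end_of_life: 24000.0
  currency_year: 2019
discounting:
  annual_rate_costs: 0.04
  annual_rate_effects: 0.015
life_table:
  csv_path: null
  max_age: 105
  q63_male: 0.0115
  q63_female: 0.0077
  doubling_years: 8.0
wtp_threshold: 80000.0
price_scenario: increased
psa:
  n_draws: 10000
  seed: 20190101
  default_interval: 0.2
  cost_cv: 0.2
scenario: base_case
followup_months: 25.0
life_table_override: switch
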