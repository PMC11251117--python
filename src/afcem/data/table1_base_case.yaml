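meta:
  name: table1_base_case
  currency_note: all monetary fields are EUR
  provenance:
    costs: published
    utilities.state_decrements: published
    utilities.stroke_short_term: published
    utilities.stroke_long_term: published
    utilities.hf_decrements: published
    utilities.baseline_by_age: assumed
    clinical: synthetic
    events.cha2ds2vasc_distribution: assumed
    events.stroke_risk_by_score: assumed
    events.stroke_severity_split: assumed
    events.hf_incidence_by_age: assumed
    events.general_mortality: assumed
    demographics: assumed
settings:
  cycle_length_months: 3
  horizon_years: 40
  decision_tree_years: 1
  discount_rate_costs: 0.03
  discount_rate_qalys: 0.03
  wtp_threshold: 23200
  cohort_size: 1000
  max_total_ablations: 3
  psa_iterations: 5000
  currency: EUR
  half_cycle_correction: false
demographics:
  start_age: 58.0
  fraction_female: 0.35
costs:
  index_procedure: 4554
  reablation_procedure: 4554
  cv_hospitalisation: 1996
  ae_visit: 322
  outpatient: 59
  cardioversion_pharm: 1314
  cardioversion_elec: 1314
  pharma_per_cycle:
    cryo: 64
    aad: 89
  stroke_event:
    non_disabling: 15615
    moderate: 15615
    severe: 15615
  stroke_followup_per_cycle: 756
  hf_per_cycle:
    I: 909
    II: 909
    III: 909
    IV: 909
utilities:
  baseline_by_age:
  - - 40
    - 0.854
    - 0.864
  - - 60
    - 0.834
    - 0.844
  - - 70
    - 0.794
    - 0.804
  - - 80
    - 0.734
    - 0.744
  - - 90
    - 0.664
    - 0.674
  state_decrements:
    NSR: 0.0
    ST_EPISODIC: 0.09
    LT_PERSISTENT: 0.08
    PERMANENT: 0.11
  stroke_short_term:
    non_disabling: 0.0
    moderate: 0.37
    severe: 0.65
  stroke_long_term:
    non_disabling: 0.03
    moderate: 0.18
    severe: 0.36
  hf_decrements:
    I: 0.0
    II: 0.07
    III: 0.16
    IV: 0.3
clinical:
  rr_recurrence_by_count:
  - 1.0
  - 1.0
  - 1.0
  - 1.0
  rr_resolution_by_count:
  - 1.0
  - 1.0
  - 1.0
  - 1.0
  rr_success_by_count:
  - 1.0
  - 1.0
  - 1.0
  - 1.0
  per_arm:
    cryo:
      recurrence: 0.016
      resolution: 0.175
      progression_st_lt: 0.0055
      progression_lt_perm: 0.017
      reablation_uptake_st: 0.028
      reablation_uptake_lt: 0.015
      reablation_success: 0.8
      year1:
        recurrence: 0.03
        resolution: 0.42
        progression_st_lt: 0.005
        reablation_uptake: 0.033
        reablation_success: 0.8
      contact_rates:
        NSR:
          hospitalisation: 0.0112
          ae_visit: 0.0093
          outpatient: 0.4185
          cardioversion_pharm: 0.0009
          cardioversion_elec: 0.0009
        ST_EPISODIC:
          hospitalisation: 0.0372
          ae_visit: 0.0326
          outpatient: 0.651
          cardioversion_pharm: 0.0074
          cardioversion_elec: 0.0074
        LT_PERSISTENT:
          hospitalisation: 0.0446
          ae_visit: 0.0372
          outpatient: 0.744
          cardioversion_pharm: 0.0093
          cardioversion_elec: 0.0093
        PERMANENT:
          hospitalisation: 0.0279
          ae_visit: 0.0186
          outpatient: 0.465
          cardioversion_pharm: 0.0
          cardioversion_elec: 0.0
      year1_contact_rates:
        NSR:
          hospitalisation: 0.0149
          ae_visit: 0.0121
          outpatient: 0.5394
          cardioversion_pharm: 0.0009
          cardioversion_elec: 0.0009
        ST_EPISODIC:
          hospitalisation: 0.0484
          ae_visit: 0.0418
          outpatient: 0.8463
          cardioversion_pharm: 0.0093
          cardioversion_elec: 0.0093
        LT_PERSISTENT:
          hospitalisation: 0.0577
          ae_visit: 0.0484
          outpatient: 0.9672
          cardioversion_pharm: 0.0121
          cardioversion_elec: 0.0121
        PERMANENT:
          hospitalisation: 0.0363
          ae_visit: 0.0242
          outpatient: 0.6045
          cardioversion_pharm: 0.0
          cardioversion_elec: 0.0
    aad:
      recurrence: 0.036
      resolution: 0.165
      progression_st_lt: 0.009
      progression_lt_perm: 0.017
      reablation_uptake_st: 0.0705
      reablation_uptake_lt: 0.04
      reablation_success: 0.8
      year1:
        recurrence: 0.06
        resolution: 0.3
        progression_st_lt: 0.008
        reablation_uptake: 0.105
        reablation_success: 0.8
      contact_rates:
        NSR:
          hospitalisation: 0.0167
          ae_visit: 0.013
          outpatient: 0.4836
          cardioversion_pharm: 0.0019
          cardioversion_elec: 0.0019
        ST_EPISODIC:
          hospitalisation: 0.0465
          ae_visit: 0.0391
          outpatient: 0.7068
          cardioversion_pharm: 0.0102
          cardioversion_elec: 0.0102
        LT_PERSISTENT:
          hospitalisation: 0.0558
          ae_visit: 0.0465
          outpatient: 0.8184
          cardioversion_pharm: 0.0121
          cardioversion_elec: 0.0121
        PERMANENT:
          hospitalisation: 0.0279
          ae_visit: 0.0186
          outpatient: 0.465
          cardioversion_pharm: 0.0
          cardioversion_elec: 0.0
      year1_contact_rates:
        NSR:
          hospitalisation: 0.0214
          ae_visit: 0.0167
          outpatient: 0.6324
          cardioversion_pharm: 0.0028
          cardioversion_elec: 0.0028
        ST_EPISODIC:
          hospitalisation: 0.0605
          ae_visit: 0.0512
          outpatient: 0.9207
          cardioversion_pharm: 0.013
          cardioversion_elec: 0.013
        LT_PERSISTENT:
          hospitalisation: 0.0725
          ae_visit: 0.0605
          outpatient: 1.0602
          cardioversion_pharm: 0.0158
          cardioversion_elec: 0.0158
        PERMANENT:
          hospitalisation: 0.0363
          ae_visit: 0.0242
          outpatient: 0.6045
          cardioversion_pharm: 0.0
          cardioversion_elec: 0.0
events:
  cha2ds2vasc_distribution:
  - 0.45
  - 0.33
  - 0.13
  - 0.06
  - 0.02
  - 0.01
  - 0.0
  - 0.0
  - 0.0
  - 0.0
  stroke_risk_by_score:
  - 0.000873
  - 0.002608
  - 0.009581
  - 0.013935
  - 0.020897
  - 0.03135
  - 0.042271
  - 0.048766
  - 0.047021
  - 0.05312
  stroke_rr_by_state:
    NSR: 1.0
    ST_EPISODIC: 1.48
    LT_PERSISTENT: 1.88
    PERMANENT: 2.05
  stroke_severity_split:
  - 0.45
  - 0.35
  - 0.2
  stroke_case_fatality: 0.12
  hf_incidence_by_age:
  - - 40
    - 0.000658
  - - 60
    - 0.001974
  - - 70
    - 0.004606
  - - 80
    - 0.007896
  hf_rr_by_state:
    NSR: 1.0
    ST_EPISODIC: 1.0
    LT_PERSISTENT: 1.0
    PERMANENT: 1.0
  hf_nyha_split:
  - 0.35
  - 0.4
  - 0.2
  - 0.05
  hf_case_fatality: 0.1
  general_mortality:
  - - 55
    - 0.0038
    - 0.0055
  - - 60
    - 0.0059
    - 0.0085
  - - 65
    - 0.0093
    - 0.0132
  - - 70
    - 0.0153
    - 0.0213
  - - 75
    - 0.0255
    - 0.0357
  - - 80
    - 0.0467
    - 0.0638
  - - 85
    - 0.085
    - 0.1105
  - - 90
    - 0.153
    - 0.187
  - - 95
    - 0.255
    - 0.289
currency_rates:
  gbp_to_dkk: 8.73
  eur_to_dkk: 7.45
  dkk_to_eur_presentation: 0.13
psa:
  cost_se_frac: 0.2
  probability_se_frac: 0.2
  rate_se_frac: 0.2
  utility_decrement_se_frac: 0.2
  baseline_utility_se: 0.012
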