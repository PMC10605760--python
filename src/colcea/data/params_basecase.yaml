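# Base-case model inputs: Thai stage III colorectal cancer adjuvant
# chemotherapy decision model, all monetary values in 2021 USD.
# Quantities published without a standard error carry no `se` key.

settings:
  start_age: 63
  cycle_length: 1
  discount_rate: 0.03
  wtp_threshold: 5003
  horizon_age: 100
  bsa: 1.7
  body_weight: 60
  treated_fraction_of_first_cycle: 0.5

transitions:
  sd_to_pd:
    5-FU/LV: {value: 0.175, se: 0.012}
    capecitabine: {value: 0.149, se: 0.010}
    FOLFOX: {value: 0.133, se: 0.009}
    CAPOX: {value: 0.140, se: 0.010}
  sd_to_death:
    5-FU/LV:
      year1: 0.053
      year2: 0.152
      year3: 0.199
      year4: 0.108
      subsequent: 0.121
    capecitabine:
      year1: 0.057
      year2: 0.073
      year3: 0.108
      year4: 0.105
      subsequent: 0.072
    FOLFOX:
      year1: 0.000
      year2: 0.082
      year3: 0.060
      year4: 0.063
      subsequent: 0.068
    CAPOX:
      year1: 0.012
      year2: 0.037
      year3: 0.071
      year4: 0.069
      subsequent: 0.030
  pd_to_death:
    FOLFOX:
      year1: 0.208
      year2: 0.351
      year3: 0.514
      subsequent: 0.222
    CAPOX:
      year1: 0.176
      year2: 0.435
      year3: 0.318
      subsequent: 0.267
    FOLFIRI:
      year1: 0.474
      year2: 0.574
      year3: 0.462
      subsequent: 0.500

utilities:
  sd_on_iv: {value: 0.600, se: 0.063}
  sd_on_oral: {value: 0.651, se: 0.047}
  sd_off: {value: 0.850, se: 0.100}
  pd_on_iv: {value: 0.560, se: 0.101}
  pd_off: {value: 0.624, se: 0.043}

unit_costs:
  drug_prices:
    5-FU: {usd_per_package: 4, mg_per_package: 1000}       # 1000 mg vial
    LV: {usd_per_package: 9, mg_per_package: 300}          # 300 mg vial
    capecitabine: {usd_per_package: 2, mg_per_package: 500}  # 500 mg tab
    oxaliplatin: {usd_per_package: 39, mg_per_package: 100}  # 100 mg vial
    irinotecan: {usd_per_package: 43, mg_per_package: 100}   # 100 mg vial
  administration:
    opd_bolus: 14
    opd_infusion: 32
    ipd_infusion: 122
    dispensing: 0
  food: {value: 2, se: 0.4}
  transportation: {value: 5, se: 0.2}

care_costs:  # other healthcare costs, USD per person-year
  sd_year1_opd: 2041
  sd_year1_ipd: 7321
  sd_year2: 2041
  sd_year3plus: 1875
  pd_year1_opd: 3789
  pd_year1_ipd: 8445
  pd_year2: 3789
  pd_year3plus: 3136

visits:
  per_course:
    5-FU/LV: 30
    capecitabine: 6   # monthly dispensing visit, no administration fee
    FOLFOX: 12
    CAPOX: 8
    FOLFIRI: 12
  state_year:  # hospital visits outside the chemotherapy course
    sd_year1_off: 6     # latter half of year 1, off treatment
    sd_year2: 13
    sd_year3plus: 12
    pd_year1_off: 9
    pd_year2: 20
    pd_year3plus: 18

regimens:
  5-FU/LV:
    dose_rules:
      - {agent: LV, dose_mg_per_m2: 20, days_per_cycle: 5, cycles_per_course: 6, route: iv_bolus}
      - {agent: 5-FU, dose_mg_per_m2: 400, days_per_cycle: 5, cycles_per_course: 6, route: iv_bolus}
    admin_modality: opd_bolus
    care_setting: OPD
  capecitabine:
    dose_rules:
      - {agent: capecitabine, dose_mg_per_m2: 2000, days_per_cycle: 14, cycles_per_course: 8, route: oral}
    admin_modality: dispensing
    care_setting: OPD
  FOLFOX:
    dose_rules:
      - {agent: oxaliplatin, dose_mg_per_m2: 85, days_per_cycle: 1, cycles_per_course: 12, route: iv_infusion}
      - {agent: LV, dose_mg_per_m2: 400, days_per_cycle: 1, cycles_per_course: 12, route: iv_infusion}
      - {agent: 5-FU, dose_mg_per_m2: 400, days_per_cycle: 1, cycles_per_course: 12, route: iv_bolus}
      - {agent: 5-FU, dose_mg_per_m2: 2400, days_per_cycle: 1, cycles_per_course: 12, route: iv_cont_infusion}
    admin_modality: ipd_infusion   # 46 h continuous infusion requires admission
    care_setting: IPD
  CAPOX:
    dose_rules:
      - {agent: capecitabine, dose_mg_per_m2: 2000, days_per_cycle: 14, cycles_per_course: 8, route: oral}
      - {agent: oxaliplatin, dose_mg_per_m2: 130, days_per_cycle: 1, cycles_per_course: 8, route: iv_infusion}
    admin_modality: opd_infusion
    care_setting: OPD
  FOLFIRI:
    dose_rules:
      - {agent: irinotecan, dose_mg_per_m2: 180, days_per_cycle: 1, cycles_per_course: 12, route: iv_infusion}
      - {agent: LV, dose_mg_per_m2: 400, days_per_cycle: 1, cycles_per_course: 12, route: iv_infusion}
      - {agent: 5-FU, dose_mg_per_m2: 400, days_per_cycle: 1, cycles_per_course: 12, route: iv_bolus}
      - {agent: 5-FU, dose_mg_per_m2: 2400, days_per_cycle: 1, cycles_per_course: 12, route: iv_cont_infusion}
    admin_modality: ipd_infusion
    care_setting: IPD

bia:
  # National population is an explicit input, not a published model value.
  population: 70000000
  incidence_per_100k: 39.72
  accessibility: 0.80
  population_growth: 0.003
  horizon_years: 5
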