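# First-year portion of the Thai EPI childhood schedule, as shipped default.
# Recommended ages are a documented stand-in for the national guideline table;
# load a custom document to follow any guideline revision.
name: thai-epi-first-year
on_time_window_days: 28
doses:
  - {antigen: BCG, dose_index: 1, label: BCG, recommended_age_months: 0}
  - {antigen: HB, dose_index: 1, label: HB1, recommended_age_months: 0}
  - {antigen: DTP, dose_index: 1, label: DTP1, recommended_age_months: 2}
  - {antigen: OPV, dose_index: 1, label: OPV1, recommended_age_months: 2}
  - {antigen: HB, dose_index: 2, label: HB2, recommended_age_months: 2}
  - {antigen: DTP, dose_index: 2, label: DTP2, recommended_age_months: 4}
  - {antigen: OPV, dose_index: 2, label: OPV2, recommended_age_months: 4}
  - {antigen: DTP, dose_index: 3, label: DTP3, recommended_age_months: 6}
  - {antigen: OPV, dose_index: 3, label: OPV3, recommended_age_months: 6}
  - {antigen: HB, dose_index: 3, label: HB3, recommended_age_months: 6}
  - {antigen: MMR, dose_index: 1, label: M/MMR1, recommended_age_months: 9}
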