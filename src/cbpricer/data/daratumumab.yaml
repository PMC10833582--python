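# Reconstructed drug profile for the daratumumab case study.
# Cost block, patent window, vial content and incidence rates are published
# inputs (launch-year-adjusted euros). The eligibility cascades are a
# reconstruction: per-indication eligible_share values are calibrated so that
# the cumulative launch-year per-vial price equals EUR 31,941 and the
# cheapest-year per-vial price equals EUR 823 against the packaged
# population table; all other cascade fractions, doses and competitor
# schedules are plausible choices, not published data.
schema_version: 1
name: daratumumab
region: UN-MDR
launch_year: 2015
patent_expiry: 2025
vial_grams: 1.8
cost:
  initial_rd: 3795249282.0
  rd_per_new_indication: 267020244.0
  manufacturing_per_gram: 42.61
  profit_margin: 0.2
  sales_marketing_margin: 0.3
indications:
- label: multiple myeloma, >=3 prior lines, monotherapy
  approval_year: 2015
  incidence_per_100k: 7.6
  grams_per_treatment: 41.4
  cascade:
    subtype_share: 1.0
    stage_share: 1.0
    line_share: 0.1
    symptomatic_share: 1.0
    eligible_share: 0.0939902654155975
    untreated_fraction: 0.05
    trial_fraction: 0.1
  competitor_schedule: []
- label: relapsed multiple myeloma, >=1 prior line, combination
  approval_year: 2016
  incidence_per_100k: 7.6
  grams_per_treatment: 36.0
  cascade:
    subtype_share: 1.0
    stage_share: 1.0
    line_share: 0.45
    symptomatic_share: 1.0
    eligible_share: 0.41440367050277865
    untreated_fraction: 0.05
    trial_fraction: 0.1
  competitor_schedule: []
- label: relapsed/refractory multiple myeloma, >=2 prior lines, pomalidomide combination
  approval_year: 2017
  incidence_per_100k: 7.6
  grams_per_treatment: 36.0
  cascade:
    subtype_share: 1.0
    stage_share: 1.0
    line_share: 0.25
    symptomatic_share: 1.0
    eligible_share: 0.4494139659404233
    untreated_fraction: 0.05
    trial_fraction: 0.1
  competitor_schedule: []
- label: newly diagnosed multiple myeloma, transplant-ineligible
  approval_year: 2018
  incidence_per_100k: 7.6
  grams_per_treatment: 32.4
  cascade:
    subtype_share: 1.0
    stage_share: 1.0
    line_share: 0.55
    symptomatic_share: 0.9
    eligible_share: 0.6134219227467265
    untreated_fraction: 0.0
    trial_fraction: 0.1
  competitor_schedule: []
- label: newly diagnosed multiple myeloma, transplant-eligible induction
  approval_year: 2019
  incidence_per_100k: 7.6
  grams_per_treatment: 28.8
  cascade:
    subtype_share: 1.0
    stage_share: 1.0
    line_share: 0.4
    symptomatic_share: 0.9
    eligible_share: 0.8390495721425553
    untreated_fraction: 0.0
    trial_fraction: 0.1
  competitor_schedule: []
- label: AL amyloidosis
  approval_year: 2021
  incidence_per_100k: 1.2
  grams_per_treatment: 28.8
  cascade:
    subtype_share: 1.0
    stage_share: 0.8
    line_share: 1.0
    symptomatic_share: 1.0
    eligible_share: 0.39
    untreated_fraction: 0.0
    trial_fraction: 0.1
  competitor_schedule: []
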