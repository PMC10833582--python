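# Reconstructed drug profile for the pembrolizumab case study.
# Cost block, patent window, vial content and incidence rates are published
# inputs (launch-year-adjusted euros). The eligibility cascades are a
# reconstruction: per-indication eligible_share values are calibrated so that
# the cumulative launch-year per-vial price equals EUR 885 and the
# cheapest-year per-vial price equals EUR 52 against the packaged
# population table; all other cascade fractions, doses and competitor
# schedules are plausible choices, not published data.
schema_version: 1
name: pembrolizumab
region: UN-MDR
launch_year: 2014
patent_expiry: 2028
vial_grams: 0.1
cost:
  initial_rd: 3165890999.0
  rd_per_new_indication: 222740834.0
  manufacturing_per_gram: 35.55
  profit_margin: 0.2
  sales_marketing_margin: 0.3
indications:
- label: unresectable/metastatic melanoma
  approval_year: 2014
  incidence_per_100k: 21.7
  grams_per_treatment: 3.4
  cascade:
    subtype_share: 1.0
    stage_share: 0.35
    line_share: 1.0
    symptomatic_share: 1.0
    eligible_share: 0.44556695614896313
    untreated_fraction: 0.25
    trial_fraction: 0.1
  competitor_schedule:
  - - 2015
    - 1
  - - 2016
    - 2
- label: NSCLC, previously treated, PD-L1 positive
  approval_year: 2015
  incidence_per_100k: 69.5
  grams_per_treatment: 3.0
  cascade:
    subtype_share: 0.7
    stage_share: 0.6
    line_share: 0.3
    symptomatic_share: 1.0
    eligible_share: 0.7861886447009595
    untreated_fraction: 0.25
    trial_fraction: 0.1
  competitor_schedule:
  - - 2015
    - 1
- label: NSCLC, first line, PD-L1 high, monotherapy
  approval_year: 2016
  incidence_per_100k: 69.5
  grams_per_treatment: 5.0
  cascade:
    subtype_share: 0.3
    stage_share: 0.65
    line_share: 0.65
    symptomatic_share: 1.0
    eligible_share: 0.7593659277037432
    untreated_fraction: 0.25
    trial_fraction: 0.1
  competitor_schedule:
  - - 2020
    - 1
- label: recurrent/metastatic head and neck squamous cell carcinoma
  approval_year: 2016
  incidence_per_100k: 21.8
  grams_per_treatment: 4.0
  cascade:
    subtype_share: 1.0
    stage_share: 0.6
    line_share: 0.6
    symptomatic_share: 1.0
    eligible_share: 0.6917027278287441
    untreated_fraction: 0.25
    trial_fraction: 0.1
  competitor_schedule:
  - - 2016
    - 1
- label: locally advanced/metastatic urothelial carcinoma
  approval_year: 2017
  incidence_per_100k: 26.3
  grams_per_treatment: 3.4
  cascade:
    subtype_share: 1.0
    stage_share: 0.55
    line_share: 0.5
    symptomatic_share: 1.0
    eligible_share: 0.8170203314568174
    untreated_fraction: 0.25
    trial_fraction: 0.1
  competitor_schedule:
  - - 2017
    - 1
- label: gastric/oesophageal adenocarcinoma, PD-L1 positive
  approval_year: 2017
  incidence_per_100k: 32.1
  grams_per_treatment: 3.2
  cascade:
    subtype_share: 0.8
    stage_share: 0.65
    line_share: 0.5
    symptomatic_share: 1.0
    eligible_share: 0.8591678108425489
    untreated_fraction: 0.25
    trial_fraction: 0.1
  competitor_schedule: []
- label: melanoma, adjuvant after resection
  approval_year: 2018
  incidence_per_100k: 21.7
  grams_per_treatment: 3.6
  cascade:
    subtype_share: 1.0
    stage_share: 0.4
    line_share: 1.0
    symptomatic_share: 1.0
    eligible_share: 0.856089844152885
    untreated_fraction: 0.25
    trial_fraction: 0.1
  competitor_schedule:
  - - 2018
    - 1
- label: NSCLC, first line, chemotherapy combination
  approval_year: 2019
  incidence_per_100k: 69.5
  grams_per_treatment: 5.0
  cascade:
    subtype_share: 0.7
    stage_share: 0.65
    line_share: 0.7
    symptomatic_share: 1.0
    eligible_share: 0.9037300739750751
    untreated_fraction: 0.25
    trial_fraction: 0.1
  competitor_schedule:
  - - 2020
    - 1
- label: small cell lung cancer, previously treated
  approval_year: 2019
  incidence_per_100k: 69.5
  grams_per_treatment: 3.0
  cascade:
    subtype_share: 0.13
    stage_share: 0.7
    line_share: 0.6
    symptomatic_share: 1.0
    eligible_share: 0.8513635148308987
    untreated_fraction: 0.25
    trial_fraction: 0.1
  competitor_schedule: []
- label: renal cell carcinoma, first line combination
  approval_year: 2019
  incidence_per_100k: 19.3
  grams_per_treatment: 5.0
  cascade:
    subtype_share: 1.0
    stage_share: 0.5
    line_share: 0.75
    symptomatic_share: 1.0
    eligible_share: 0.8570479763840163
    untreated_fraction: 0.25
    trial_fraction: 0.1
  competitor_schedule:
  - - 2019
    - 1
- label: advanced endometrial carcinoma, lenvatinib combination
  approval_year: 2019
  incidence_per_100k: 33.7
  grams_per_treatment: 3.0
  cascade:
    subtype_share: 1.0
    stage_share: 0.4
    line_share: 0.6
    symptomatic_share: 1.0
    eligible_share: 0.9061696560679026
    untreated_fraction: 0.25
    trial_fraction: 0.1
  competitor_schedule: []
- label: relapsed/refractory classical Hodgkin lymphoma
  approval_year: 2020
  incidence_per_100k: 2.5
  grams_per_treatment: 4.0
  cascade:
    subtype_share: 1.0
    stage_share: 0.45
    line_share: 0.4
    symptomatic_share: 1.0
    eligible_share: 0.75
    untreated_fraction: 0.25
    trial_fraction: 0.1
  competitor_schedule:
  - - 2020
    - 1
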