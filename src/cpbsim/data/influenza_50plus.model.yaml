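# Birth-cohort CPB model for influenza vaccination of adults 50+.
# Two independent age strata, each with mortality / hospitalization /
# illness channels.  Person-years: ~50 million for the 65+ band; the 50-64
# figure is the 4M cohort times the 15-year band width.
name: influenza_50plus
birth_cohort_size: 4000000
adherence: adherence
denominator: delivered
strata:
  - label: 50-64
    person_years: 60000000.0
    coverage: coverage_50_64
    channels:
      - name: mortality
        incidence: mortality_rate_50_64
        efficacy: efficacy_mortality
        qaly_weight: 1.0
      - name: hospitalization
        incidence: hosp_rate_50_64
        efficacy: efficacy_hospitalization
        qaly_weight: qaly_weight_sickness
      - name: illness
        incidence: illness_rate_50_64
        efficacy: efficacy_illness
        qaly_weight: qaly_weight_illness
  - label: 65+
    person_years: 50000000.0
    coverage: coverage_65plus
    channels:
      - name: mortality
        incidence: mortality_rate_65plus
        efficacy: efficacy_mortality
        qaly_weight: 1.0
      - name: hospitalization
        incidence: hosp_rate_65plus
        efficacy: efficacy_hospitalization
        qaly_weight: qaly_weight_sickness
      - name: illness
        incidence: illness_rate_65plus
        efficacy: efficacy_illness
        qaly_weight: qaly_weight_illness
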