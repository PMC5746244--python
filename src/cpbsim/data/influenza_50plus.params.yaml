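# Influenza-vaccination parameter ranges for the 50+ birth-cohort model.
# Ranges without "[placeholder]" in their units are printed in the burden
# literature; placeholder ranges are plausibility choices standing in for
# values that were never published (see docs/methods.md) and should be
# replaced before any substantive use.
intervention: influenza_50plus
parameters:
  - name: mortality_rate_65plus
    low: 9.4
    high: 15.6
    units: per 100,000 person-years
    kind: rate_per_100k
  - name: efficacy_mortality
    low: 0.35
    high: 0.55
    units: fraction of deaths averted
    kind: probability
  - name: efficacy_illness
    low: 0.10
    high: 0.30
    units: fraction of illnesses averted
    kind: probability
  - name: coverage_65plus
    low: 0.43
    high: 0.72
    units: current vaccination prevalence
    kind: probability
  - name: adherence
    low: 0.75
    high: 0.95
    units: acceptance when offered
    kind: probability
  - name: qaly_weight_sickness
    low: 0.20
    high: 0.40
    units: QALY decrement per event
    kind: qaly_weight
  - name: mortality_rate_50_64
    low: 1.0
    high: 3.0
    units: per 100,000 person-years [placeholder]
    kind: rate_per_100k
  - name: hosp_rate_65plus
    low: 90.0
    high: 210.0
    units: per 100,000 person-years [placeholder]
    kind: rate_per_100k
  - name: hosp_rate_50_64
    low: 20.0
    high: 60.0
    units: per 100,000 person-years [placeholder]
    kind: rate_per_100k
  - name: illness_rate_65plus
    low: 2000.0
    high: 8000.0
    units: per 100,000 person-years [placeholder]
    kind: rate_per_100k
  - name: illness_rate_50_64
    low: 2000.0
    high: 8000.0
    units: per 100,000 person-years [placeholder]
    kind: rate_per_100k
  - name: coverage_50_64
    low: 0.30
    high: 0.50
    units: current vaccination prevalence [placeholder]
    kind: probability
  - name: efficacy_hospitalization
    low: 0.25
    high: 0.45
    units: fraction of hospitalizations averted [placeholder]
    kind: probability
  - name: qaly_weight_illness
    low: 0.02
    high: 0.10
    units: QALY decrement per event [placeholder]
    kind: qaly_weight
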