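# QALYs saved per 10^3 interventions.
#
# "simulated" rows summarise 10^6-iteration Monte Carlo runs over
# literature-derived parameter ranges (mean, sample SD, 95% quantile
# interval).  "literature" rows are published cohort-level means without
# simulable detail; their SDs use the fixed coefficient-of-variation rule
# sd = mean / 3, stored here rounded to two significant figures as published
# (load with sd="derived" for the exact mean/3).
simulated:
  - intervention: tobacco_screening
    mean: 1.5
    sd: 0.22
    qi: [1.1, 1.9]
  - intervention: alcohol_screening
    mean: 1.2
    sd: 0.47
    qi: [0.51, 2.2]
  - intervention: hypertension_screening
    mean: 2.9
    sd: 1.0
    qi: [1.4, 5.2]
  - intervention: condom_distribution
    mean: 0.33
    sd: 0.12
    qi: [0.12, 0.59]
  - intervention: influenza_vaccine_50plus
    mean: 2.1
    sd: 0.45
    qi: [1.4, 3.1]
  - intervention: influenza_vaccine_15_49
    mean: 0.067
    sd: 0.022
    qi: [0.030, 0.12]
literature:
  - intervention: obesity_screening_adults
    mean: 6.0
    sd: 2.0
    citation: obesity-screening-cpb
  - intervention: depression_screening
    mean: 0.50
    sd: 0.16
    citation: depression-screening-cpb
  - intervention: hiv_risk_screening
    mean: 0.27
    sd: 0.09
    citation: hiv-screening-cpb
  - intervention: syphilis_risk_screening
    mean: 0.030
    sd: 0.010
    citation: syphilis-screening-cpb
  - intervention: diabetes_screening
    mean: 2.0
    sd: 0.66
    citation: diabetes-screening-cpb
  - intervention: cholesterol_screening
    mean: 2.5
    sd: 0.83
    citation: cholesterol-screening-cpb
  - intervention: colon_cancer_screening
    mean: 33
    sd: 11
    citation: colonoscopy-cpb
  - intervention: breast_cancer_screening
    mean: 17
    sd: 5.6
    citation: mammography-cpb
  - intervention: cervical_cancer_screening
    mean: 10
    sd: 3.3
    citation: pap-smear-cpb
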