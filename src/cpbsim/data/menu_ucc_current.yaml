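# Current annual service menu of the urban student-run clinic.
# Universal services reach the full ~500 patients/year; targeted services
# use estimated counts from the past year.  Volumes fluctuate ~20% between
# years (volume_cv).
name: ucc_current
volume_cv: 0.20
services:
  - intervention: obesity_screening_adults
    annual_volume: 500
  - intervention: hypertension_screening
    annual_volume: 500
  - intervention: tobacco_screening
    annual_volume: 500
  - intervention: alcohol_screening
    annual_volume: 500
  - intervention: condom_distribution
    annual_volume: 500
  - intervention: hiv_risk_screening
    annual_volume: 500
  - intervention: syphilis_risk_screening
    annual_volume: 500
  - intervention: influenza_vaccine_50plus
    annual_volume: 5
  - intervention: influenza_vaccine_15_49
    annual_volume: 50
  - intervention: diabetes_screening
    annual_volume: 100
  - intervention: breast_cancer_screening
    annual_volume: 10
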