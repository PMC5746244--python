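# Candidate additions to the clinic's service menu ("what-if" scenario):
# universal depression screening, 50 cholesterol screenings, and 10
# colonoscopy referrals per year.
name: ucc_prospective
volume_cv: 0.20
services:
  - intervention: colon_cancer_screening
    annual_volume: 10
  - intervention: depression_screening
    annual_volume: 500
  - intervention: cholesterol_screening
    annual_volume: 50
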