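# Null-effect cohort: true PR = 1, 10% outcome prevalence, no
# age-exposure or age-outcome association.
n: 5810
seed: 1
exposure_prevalence: 0.30
exposure_age_logodds: [0.0, 0.0, 0.0, 0.0]
age:
  shares: [0.419, 0.240, 0.140, 0.202]
  mean: 28.2
  sd: 7.1
outcomes:
  - label: outcome
    target_prevalence: 0.10
    pr: 1.0
    age_log_effects: [0.0, 0.0, 0.0, 0.0]
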