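# Emulation of the motivating workforce survey: n = 5810, ages 18-56
# (mean 28.2, SD 7.1; group shares 41.9/24.0/14.0/20.2%), binary depression
# exposure (marginal prevalence set to 30%, a realistic screening-positive
# share; the survey did not publish it), five outcomes spanning the
# published marginal prevalences 1.8% ... 96.1%.
#
# True PRs are set to the published age-adjusted point estimates where a
# log-link Bernoulli model can represent them; for the two high-prevalence
# outcomes the effects are capped so that no support point implies a
# probability above 1 (alcohol keeps the published 1.243; the 96.1%
# outcome uses 1.0585, the published 1.086 being unrepresentable at this
# exposure prevalence).  The survey found no age confounding for the 96.1%
# outcome (adjusted = crude), so its age effects are zero and the exposed
# cell probability sits at 0.9997 — the near-saturated regime in which
# log-binomial fitting hits the mu < 1 boundary.  For the other outcomes,
# age effects on exposure and outcome share a sign, which makes the crude
# PR exceed the adjusted PR as in the survey.
n: 5810
seed: 20231004
exposure_prevalence: 0.30
exposure_age_logodds: [0.0, 0.2, 0.35, 0.5]
age:
  shares: [0.419, 0.240, 0.140, 0.202]
  mean: 28.2
  sd: 7.1
overdispersion_sd: 0.0
outcomes:
  - label: cocaine
    target_prevalence: 0.018
    pr: 2.931
    age_log_effects: [0.0, 0.15, 0.25, 0.35]
  - label: marijuana
    target_prevalence: 0.096
    pr: 3.444
    age_log_effects: [0.0, 0.15, 0.25, 0.35]
  - label: cigarette
    target_prevalence: 0.213
    pr: 2.175
    age_log_effects: [0.0, 0.10, 0.15, 0.20]
  - label: alcohol
    target_prevalence: 0.857
    pr: 1.243
    age_log_effects: [0.0, 0.005, 0.008, 0.01]
  - label: risk
    target_prevalence: 0.961
    pr: 1.0585
    age_log_effects: [0.0, 0.0, 0.0, 0.0]
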