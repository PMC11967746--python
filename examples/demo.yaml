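# Demo cohort: 10,000 patients with a planted availability bias — the odds of
# a medication record and of an observation period are halved for the Black or
# African group (log-odds -0.69).
n_patients: 10000
race_probs:
  White: 0.55
  Black or African: 0.25
  Asian: 0.15
  Unknown: 0.05
ethnicity_probs:
  Hispanic or Latino: 0.2
  Non-Hispanic or non-Latino: 0.7
  Unknown: 0.1
group_multipliers:
  Black or African:
    medication: 0.5
    observation_period: 0.5
seed: 7
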