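# Reduced-scale demonstration: simulate a four-group cohort with a true
# standardized stress increase of 0.5 in the depression (DP) group only,
# then run the by-group robust change analysis and the covariate regression.
simulate:
  group_sizes: {GAD: 60, DP: 120, SP: 6, HC: 200}
  variables: [[stress, 0, 20]]
  true_change:
    GAD/stress: [0.0, 2.5, 30.0]
    DP/stress: [1.25, 2.5, 30.0]
    SP/stress: [0.0, 2.5, 30.0]
    HC/stress: [0.0, 2.5, 30.0]
  baseline: {stress: [8.0, 4.0]}
  seed: 21
plan:
  - {variable: stress, kind: by_group}
regression:
  variable: stress
  covariates: [age, relationship]
chains: 2
draws_per_chain: 800
warmup: 300
ess_target: 100
psrf_threshold: 1.1
seed: 31
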