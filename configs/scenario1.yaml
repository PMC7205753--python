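# Worked design example, effect scenario 1: control 10%, doses 15/25/30% by 3 years.
design:
  event_rates: [0.10, 0.15, 0.25, 0.30]
  arm_names: [control, low, mid, high]
  n_stage1_per_arm: 20
  n_stage2_per_arm: 124
  threshold_delta: 0.3
  surrogate_maturation_weeks: 26
  followup_weeks: 156
  dropout_3yr: 0.05
  alpha_one_sided: 0.025
oc:
  n_replicates: 5000
  parameter_mode: fixed
  fixed_params: [0.16, -1.37, 1.53]
  master_seed: 1
  compute_counterfactual: true
prior:
  shape: 0.001
  rate: 0.001
mcmc:
  draws: 6000
  burnin: 1000
  seed: 0
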