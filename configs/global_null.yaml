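# Global null: every arm at the 10% control event rate (threshold selection / FWER checks).
design:
  event_rates: [0.10, 0.10, 0.10, 0.10]
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
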