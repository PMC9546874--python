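# Study-condition calibration for the commitment-circuit generator.
# Transcribed quantities: 12-min sampling (dt = 0.2 h), 14-h fixation horizon,
# earliest CDK4/6 onset 3 h after mitogen stimulation, reporter cross-talk
# coefficient 0.35, CDK2 commitment threshold ~1 reporter unit, mitogen
# withdrawal CDK4/6 inactivation delay 4-5 h; onset_scale is set so that
# ~40% of CDK4/6-activating cells lack CDK2 activation at the 14-h horizon.
circuit:
  p_active: 0.7
  onset_min: 3.0
  onset_scale: 10.0
  a46_max: 1.0
  rise_tau: 0.2
  theta_rb: 0.98
  e2f_rate: 0.97
  e2f_decay: 0.35
  cdk2_rate: 0.15
  cdk2_decay: 0.25
  a2_baseline: 0.1
  theta_commit: 1.0
  theta_apc: 1.2
  degron_rate: 0.25
  crosstalk_rho: 0.35
  noise_sd: 0.05
  dt: 0.2
  horizon: 14.0
perturbation:
  mode: none
  t_treat: 11.0
  fast_decay_tau: 0.25
  withdrawal_delay_range: [4.0, 5.0]
imaging:
  pixel_size_um: 0.65
  nucleus_radius_um: 8.0
  cyto_radius_um: 16.0
  field_shape: [512, 512]
  background: 100.0
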