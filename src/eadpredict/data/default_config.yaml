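# Default simulation configuration.
# Any subset of these keys may be overridden from a user config file
# (ead-predict --config); unknown keys are rejected.
pacing:
  period_ms: 3000.0
  stimulus_duration_ms: 3.0
  stimulus_amplitude_uA_per_uF: -25.5
  stimulus_offset_ms: 0.0
solver:
  rtol: 1.0e-5
  atol: 1.0e-7
  output_dt_ms: 0.1
  steady_state_norm: 1.0e-6
  max_paces: 10000
  max_dt_ms: 1.0
interventions:
  ICaL_scale:
    interval: [1.0, 80.0]
    eads_at_high: true
    gap: 1.0e-4
  INa_shift:
    interval: [0.0, 20.0]
    eads_at_high: true
    gap: 1.0e-4
  IKr_scale:
    interval: [0.0, 1.0]
    eads_at_high: false
    gap: 1.0e-4
# Hill coefficient for the pore-block model. Changing this is logged; the
# block model is only calibrated for 1.
hill_coefficient: 1.0
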