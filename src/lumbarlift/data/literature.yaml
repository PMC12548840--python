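# Literature reference values used by the validation worked example:
# indicator -> [mean, sd].  The paired "simulated" values are the published
# subject-specific FE results these indicators were validated against;
# they are inputs to the relative-error arithmetic, not outputs of this
# package's idealised geometry.
literature:
  L5_cortical_peak_MPa: [820.0, 30.0]
  L4_L5_disc_peak_MPa: [37.5, 2.0]
  L5_trabecular_peak_MPa: [2.5, 0.3]
  compression_stiffness_N_mm: [1230.0, 50.0]
reference_simulated:
  L5_cortical_peak_MPa: 815.0
  L4_L5_disc_peak_MPa: 36.9
  L5_trabecular_peak_MPa: 2.6
  compression_stiffness_N_mm: 1250.0
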