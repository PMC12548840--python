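# Deadlift-variant action templates.
#
# Flexion ranges and first-peak lumbar torques follow the reported study
# conditions for the traditional (DL), straight-leg (SLDL) and hexagonal-
# barbell (TBDL) deadlift with a 120 kg barbell: flexion 32-90 / 0-90 /
# 35-90 degrees and first peaks 749 / 893 / 640 N*m.  The straight-leg
# first peak arrives earlier in the lift.  Second peaks, baseline and peak
# timing are set to the qualitative double-peak profile (second peak below
# the first); marker noise is 0.5 mm SD.
DL:
  action_id: DL
  flexion_start_deg: 32.0
  flexion_end_deg: 90.0
  first_peak_torque_Nm: 749.0
  second_peak_torque_Nm: 599.0
  peak_time_fractions: [0.35, 0.75]
  trial_duration_s: 2.0
  barbell_mass_kg: 120.0
  noise_sd_mm: 0.5
  seed: 0
SLDL:
  action_id: SLDL
  flexion_start_deg: 0.0
  flexion_end_deg: 90.0
  first_peak_torque_Nm: 893.0
  second_peak_torque_Nm: 714.0
  peak_time_fractions: [0.28, 0.72]
  trial_duration_s: 2.0
  barbell_mass_kg: 120.0
  noise_sd_mm: 0.5
  seed: 0
TBDL:
  action_id: TBDL
  flexion_start_deg: 35.0
  flexion_end_deg: 90.0
  first_peak_torque_Nm: 640.0
  second_peak_torque_Nm: 512.0
  peak_time_fractions: [0.38, 0.76]
  trial_duration_s: 2.0
  barbell_mass_kg: 120.0
  noise_sd_mm: 0.5
  seed: 0
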