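# Default pipeline configuration.  All physical constants used by the
# computation stages live here, not in code.
filters:
  kinematics: {order: 4, cutoff_hz: 10.0}
  forces: {order: 4, cutoff_hz: 100.0}
sampling:
  marker_hz: 100.0
  force_hz: 500.0
trunk:
  frustum_a1_m: 0.17
  frustum_b1_m: 0.12
  frustum_a2_m: 0.16
  frustum_b2_m: 0.11
  frustum_h_m: 0.50
  density_kg_m3: 1050.0
  com_distance_m: 0.25
  subject_mass_kg: 75.0
geometry:
  vertebra_depth_mm: 32.0
  vertebra_width_mm: 45.0
  vertebra_height_mm: 28.0
  disc_height_mm: 10.0
  endplate_thickness_mm: 0.5
  cortical_offset_mm: 1.0
  nucleus_radius_fraction: 0.4
  annulus_layer_fractions: [0.2, 0.2, 0.2]
  target_edge_mm: 5.0        # desk-scale default; --coarse keeps it, 2.0 is the full-resolution value
  ligament_area_mm2: 30.0
loads:
  vertical_load_N: 1425.0
  gravity_m_s2: 9.81
thresholds:
  beta: 0.8
  gamma: 1.27
  cortical_damage_MPa: 1000.0
  trabecular_fatigue_MPa: 3.0
  disc_tolerance_MPa: 40.0
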