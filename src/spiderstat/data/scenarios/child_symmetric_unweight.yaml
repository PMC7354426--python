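# 12 kg child, four thin cords at 10 deg COG-level angle, 100 mm stretch:
# gentle symmetric unweighting of about 16% of body weight, equal
# left/right foot forces.
subject:
  mass_kg: 12
  height_m: 0.88
  age_class: child
  cog_height_m: 0.51
cords:
  - {kind: thin, characteristic: reference_child_thin, cog_level_angle_deg: 10, elongation_mm: 100, azimuth_deg: 45}
  - {kind: thin, characteristic: reference_child_thin, cog_level_angle_deg: 10, elongation_mm: 100, azimuth_deg: 135}
  - {kind: thin, characteristic: reference_child_thin, cog_level_angle_deg: 10, elongation_mm: 100, azimuth_deg: 225}
  - {kind: thin, characteristic: reference_child_thin, cog_level_angle_deg: 10, elongation_mm: 100, azimuth_deg: 315}
stance:
  width_m: 0.20
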