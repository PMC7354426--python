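# 75 kg adult, four thick cords at 45 deg COG-level angle, 250 mm stretch:
# symmetric vertical support of about 15% of body weight.
subject:
  mass_kg: 75
  height_m: 1.75
  cog_height_m: 0.98
cords:
  - {kind: thick, characteristic: reference_adult_thick, cog_level_angle_deg: 45, elongation_mm: 250, azimuth_deg: 45}
  - {kind: thick, characteristic: reference_adult_thick, cog_level_angle_deg: 45, elongation_mm: 250, azimuth_deg: 135}
  - {kind: thick, characteristic: reference_adult_thick, cog_level_angle_deg: 45, elongation_mm: 250, azimuth_deg: 225}
  - {kind: thick, characteristic: reference_adult_thick, cog_level_angle_deg: 45, elongation_mm: 250, azimuth_deg: 315}
stance:
  width_m: 0.30
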