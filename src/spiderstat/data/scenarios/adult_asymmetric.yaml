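# 75 kg adult, asymmetric setup: cords 1-2 at 45 deg / 250 mm, cord 3
# nearly level (6 deg, 240 mm), cord 4 high (48 deg, 310 mm) — shifts
# support toward one side to engage the weaker limb.
subject:
  mass_kg: 75
  height_m: 1.75
  cog_height_m: 0.98
cords:
  - {kind: thick, characteristic: reference_adult_thick, cog_level_angle_deg: 45, elongation_mm: 250, azimuth_deg: 45}
  - {kind: thick, characteristic: reference_adult_thick, cog_level_angle_deg: 45, elongation_mm: 250, azimuth_deg: 135}
  - {kind: thick, characteristic: reference_adult_thick, cog_level_angle_deg: 6, elongation_mm: 240, azimuth_deg: 225}
  - {kind: thick, characteristic: reference_adult_thick, cog_level_angle_deg: 48, elongation_mm: 310, azimuth_deg: 315}
stance:
  width_m: 0.30
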