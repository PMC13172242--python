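# Default synthetic prostate phantom configuration.
#
# Zone tissue values are configurable defaults chosen for qualitative realism
# of a 3-T axial prostate exam (bright peripheral zone on T2 and high ADC,
# intermediate transition zone, dark rectal gas); they are not fitted to any
# dataset. ADC in mm^2/s, geometry in mm, signals in arbitrary units.
image_size_px: [128, 128]
pixel_spacing_mm: [0.5, 0.5]
prostate_semi_axes_mm: [16.0, 20.0]   # (anteroposterior, left-right)
pz_thickness_mm: 7.0
rectum_radius_mm: 10.0
rectum_gap_mm: 2.0
zone_adc_mm2_per_s:
  pz: 1.8e-3
  tz: 1.3e-3
  background: 1.6e-3
  rectum: 0.0
zone_s0:
  pz: 1000.0
  tz: 800.0
  background: 400.0
  rectum: 0.0
zone_t2_intensity:
  pz: 0.9
  tz: 0.55
  background: 0.35
  rectum: 0.05
noise_sigma: 15.0
b_values_s_per_mm2: [50.0, 400.0, 800.0]
seed: 0
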