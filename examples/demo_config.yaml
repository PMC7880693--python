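# Demo study configuration for `glandscan run --config examples/demo_config.yaml`.
# Identical to the built-in defaults (glandscan.pipeline.default_study_config);
# edit cohort parameters to explore other study conditions.
timepoint: "120h"
n_glands: 5
volume_fold: 5.66          # hypertrophic radius = control radius * fold^(1/3)
image:
  shape: [140, 200]        # rows, cols
  gland_length_px: 150
  gland_width_px: 36
  rotations_deg: [0.0, 10.0, 20.0, 30.0, 40.0]
  bend_amplitude_px: 0.0
  pixel_size_um: 0.65
stack:
  shape: [24, 110, 160]    # Z, Y, X
  gland_length_px: 140
  gland_width_px: 60
  voxel_size_um: [1.0, 0.5, 0.5]
  n_proximal: 12
  n_distal: 12
hemocyte:
  patch_radius_px: 4.0
  threshold: 100.0
  intensity: 200.0
profile:
  n_bins: 128
  loess_span: 0.05
  loess_degree: 2
nuclei:
  threshold: otsu
  min_size_voxels: 64
  connectivity: 26
cohorts:
  control:
    nuclear_radius_um: 2.3
    hemocyte_fraction: 0.02
    hemocyte_restrict_to: whole
    reporter: {kind: linear, params: [150.0, -100.0]}   # proximal-high gradient
    phalloidin_level: 120.0
    channel_log_correlation: 0.8
  hypertrophic:
    nuclear_radius_um: null   # derived from control radius and volume_fold
    hemocyte_fraction: 0.10
    hemocyte_restrict_to: DP
    reporter: {kind: linear, params: [150.0, -100.0]}
    phalloidin_level: 120.0
    channel_log_correlation: 0.8
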