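# Desk-scale preset: small grids and short training schedules, sized so the
# full pipeline runs on one CPU in minutes.  This is the configuration the
# test suite exercises end to end.
seed: 0
fov_halfwidth: 40.0
render_spacing: 2.5
folds: 4
val_frac: 0.15
phantom:
  n: 32
  grid_shape: [72, 72, 96]
  spacing: 1.25
  pose_rotation_deg: 8.0
  pose_translation_mm: 5.0
geometry:
  detector_shape: [32, 32]
  pixel_spacing: 2.5
  step_length: 1.0
augment:
  factor_3d: 8
  rotation_range_deg: 30.0
  translation_range_mm: 30.0
  factor_2d: 12
  affine_translation_mm: 10.0
  affine_rotation_deg: 10.0
  affine_scale: [0.9, 1.1]
  affine_shear_deg: 5.0
degradation:
  soft_tissue_weight: 0.8
  noise_sigma: 0.015
  gamma: 1.4
  vignette_strength: 0.3
  clutter_amp: 0.4
registration:
  enabled: true
  xray_rotation_deg: 4.0
  xray_translation_mm: 4.0
translator:
  image_shape: [32, 32]
  gen_hidden: [512]
  disc_patch: 8
  disc_hidden: [64]
  adversarial_weight: 1.0
  l1_weight: 100.0
  lr: 0.0002
  epochs: 40
  batch_size: 8
  seed: 0
tlnet:
  label_shape: [16, 16, 16]
  image_shape: [32, 32]
  n_classes: 3
  latent_dim: 64
  encoder_hidden: [128]
  decoder_hidden: [128]
  predictor_hidden: [128]
  lambda1: 1.0e-4
  lambda2: 1.0e-4
  noise_sigma: 0.1
  stage_iters: [1200, 1200, 600]
  stage_lrs: [1.0e-4, 1.0e-4, 1.0e-5]
  batch_size: 8
  seed: 0
  squared_consistency: false
  fov_halfwidth: 40.0
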