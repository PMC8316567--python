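# Full-scale preset:
# 400^3 volumes at 0.625 mm, 500x625 images at 0.4 mm, 100x 2D affine and
# 40x 3D rigid augmentation within +/-30 deg / +/-30 mm, a +/-40 mm field of
# view, lambda1 = lambda2 = 1e-4, 35000/35000/15000 training iterations at
# learning rates 1e-4/1e-4/1e-5.  Provided for fidelity and validation;
# running it requires hours-to-days of compute and is not part of the
# routine test path.
seed: 0
fov_halfwidth: 40.0
render_spacing: 0.625
folds: 4
val_frac: 0.15
phantom:
  n: 173
  grid_shape: [400, 400, 400]
  spacing: 0.625
  pose_rotation_deg: 8.0
  pose_translation_mm: 5.0
geometry:
  detector_shape: [500, 625]
  pixel_spacing: 0.4
  step_length: 0.5
augment:
  factor_3d: 40
  rotation_range_deg: 30.0
  translation_range_mm: 30.0
  factor_2d: 100
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
  image_shape: [500, 625]
  gen_hidden: [1024]
  disc_patch: 125
  disc_hidden: [256]
  adversarial_weight: 1.0
  l1_weight: 100.0
  lr: 0.0002
  epochs: 100
  batch_size: 8
  seed: 0
tlnet:
  label_shape: [128, 128, 128]
  image_shape: [500, 625]
  n_classes: 3
  latent_dim: 64
  encoder_hidden: [512]
  decoder_hidden: [512]
  predictor_hidden: [512]
  lambda1: 1.0e-4
  lambda2: 1.0e-4
  noise_sigma: 0.1
  stage_iters: [35000, 35000, 15000]
  stage_lrs: [1.0e-4, 1.0e-4, 1.0e-5]
  batch_size: 8
  seed: 0
  squared_consistency: false
  fov_halfwidth: 40.0
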