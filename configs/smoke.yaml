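seed: 0
out_dir: runs/smoke
n_train_pairs: 48
n_eval_pairs: 4
disc_preset: reduced
phantom:
  shape:
  - 64
  - 64
  - 16
  spacing:
  - 4.0
  - 4.0
  - 8.0
  body_hu: 40.0
  lung_hu: -800.0
  fat_hu: -100.0
  aorta_hu_pre: 45.0
  aorta_hu_post: 250.0
  node_hu_pre: 45.0
  node_hu_post: 90.0
  n_nodes: 3
  node_diameter_range:
  - 5.0
  - 15.0
  n_vessels: 6
  vessel_radius_range:
  - 2.0
  - 5.0
  noise_sd: 10.0
  seed: 0
model:
  input_shape:
  - 64
  - 64
  - 16
  in_channels: 3
  out_channels: 3
  n_encoder_blocks: 3
  base_filters: 32
  filter_growth: 2.0
  max_filters: 128
  leaky_slope: 0.2
  upsample_mode: nearest
training:
  lambda_l1: 100.0
  adv_weight: 1.0
  lr: 0.005
  beta1: 0.5
  decay_rate: 0.1
  decay_start_epoch: 4
  batch_size: 1
  epochs: 5
  label_smooth_real: 0.9
  max_shift_px: 6
  gan_mode: bce
  seed: 0
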