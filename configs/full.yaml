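# Full-scale profile matching the clinical acquisition geometry
# (304x448 frames, 5-frame clips) and the published training protocol:
# 10 residual blocks x 128 channels, Adam, lr 1e-4 with linear decay after
# epoch 50, batch 8, 200 epochs, loss weights (1, 20, 1).
# Intended for GPU-free experimentation only at reduced epoch counts.
phantom:
  height_px: 304
  width_px: 448
  n_layers: 8
  layer_curvature: 18.0
  frames_per_sequence: 5

simulate:
  n_lr_sequences: 256
  n_hr_images: 256

training:
  profile: default
  lr: 1.0e-4
  decay_start_epoch: 50
  epochs: 200
  batch_size: 8
  seq_len: 5
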