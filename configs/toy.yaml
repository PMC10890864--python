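# Desk-scale profile: 64x64 phantoms, ~300 optimisation steps on one CPU.
phantom:
  height_px: 64
  width_px: 64
  frames_per_sequence: 5

simulate:
  n_lr_sequences: 32
  n_hr_images: 32

training:
  profile: toy
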