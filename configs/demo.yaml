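# Desk-scale demonstration: 10 train / 4 test phantom subjects, tiny networks.
name: demo
seed: 0
phantom:
  grid_size: 64
  n_train: 10
  n_test: 4
  noise_sd_hu: 15.0
paradigms: [supervised_baseline, supervised_phase]
train:
  steps: 300
  patch_size: 32
  gen_layers: 3
  gen_channels: 4
  disc_layers: 2
  disc_channels: 8
  lr_gen: 1.0e-3
stitch:
  stride: 16
eval:
  n_boot: 300
  n_slices: 5
out_dir: runs/demo
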