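# Example experiment: composed model on the built-in "easy" synthetic profile.
# For real data replace `data` with e.g.
#   data: {dir: runs/, mode: lcms, mass_range: [400, 1600], bin_width: 0.1,
#          window: 10, tic_threshold: 1.0e4, test_frac: 0.10}
seed: 0
data:
  profile: easy
use_msmce: true
msmce:          # scaled-down dimensions for CPU runs; defaults are
  hidden: 256   # hidden=2048, d=1024, C=256, C_mid=128, dropout_p=0.3
  d: 128
  C: 16
  C_mid: 8
  dropout_p: 0.1
classifier:
  family: cnn1d   # or lstm / transformer
  width: 16
  depth: 1
train:
  k: 6
  max_epochs: 30
  batch_size: 32
  lr: 1.0e-3
  weight_decay: 1.0e-5
out_dir: scratch/easy_run
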