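# Desk-scale configuration: small model and a two-epoch training budget so
# the whole worked example runs in about a minute on a laptop CPU.
# Unset values keep the package defaults (which carry the full-scale
# reference protocol: 100 epochs x 1000 batches x batch 512, etc.).
seed: 5
sim:
  read_len_mean: 1000
  read_len_sd: 100
  samples_per_base: 5.33
model:
  n_blocks: 2
  base_filters: 16
  stem_stride: 4
train:
  epochs: 2
  batch_size: 64
  batches_per_epoch: 60
  val_batches_per_epoch: 10
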