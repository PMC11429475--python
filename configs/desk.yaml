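augment_budgets:
  POAG/NTG: 10
  glaucoma: 30
  normal: 30
  referable: 20
  suspect: 10
batch_size: 50
contour_high: 0.3
contour_kernel: 5
contour_low: 0.1
cvgan_budgets: {}
epochs: 10
image_size: 64
master_seed: 0
out_root: runs
split_fractions:
- 0.7
- 0.15
- 0.15
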