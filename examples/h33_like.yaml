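# Expression-dependent TSS deposition (H3.3-like demo profile)
seed: 1
out_dir: scratch/h33_like
simulate:
  coupling_mode: dependent
  coupling_exponent: 1.0
analysis:
  bin_size: 1000
  aggregation_window: 3000
  increment_window: 2000
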