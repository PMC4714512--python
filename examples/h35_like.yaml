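# Expression-independent TSS deposition (H3.5-like demo profile)
seed: 1
out_dir: scratch/h35_like
simulate:
  coupling_mode: independent
analysis:
  bin_size: 1000
  aggregation_window: 3000
  increment_window: 2000
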