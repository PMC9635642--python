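# End-to-end demo: simulate a redundancy study, build kernels, fit GTCBLUP
# with forward masking of generation 11, and evaluate the predictions.
seed: 1
model: GTCBLUP
simulate:
  n_individuals: 478
  n_markers: 1000
  n_genes: 2000
  h2_direct: 0.15
  t2_mediated: 0.45
  prop_cis: 0.7
  generation_sizes: {4: 47, 5: 47, 7: 192, 11: 192}
chain: {n_iter: 6000, burn_in: 2000, thin: 5}
split: generation:11
bootstrap: 2000
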