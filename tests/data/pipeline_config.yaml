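# Small end-to-end fixture: simulated three-tissue design, analyzed fully.
seed: 20240601
simulate:
  n_amino_acids: 10
  n_mt: 4
  library_size: 300000
  n_genes: 200
  cds_length_codons: [80, 160]
  coupling_strength: 1.0
  te_noise_sd: 0.3
min_fpkm: 1.0
top_fraction: 0.05
n_perm: 300
rpm_denominator: all_mapped
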