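# Bundled toy configuration: a complete synthetic cohort small enough to
# run every pipeline stage in minutes on one CPU.
seed: 1
outdir: enhevo_out
thresholds:
  n_shuffles: 200        # override of the standard 1000 for the toy genome
synthetic:
  n_chroms: 2
  chrom_length: 400000
  n_enhancers: 200
  n_snps: 1000
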