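# Demo pipeline configuration: a small synthetic cohort that runs
# end-to-end in well under a minute on one CPU. Analysis thresholds keep
# their standard defaults (alpha 0.05, gene frequency 5%, hypermutation
# threshold 23, GWAS suggestive cut 1e-5, 200 kb / 1000 bp functional
# windows, 1 Mb clumping).
seed: 17
outdir: demo_run
simulate:
  n_samples: 400
  n_blocks: 24
  variants_per_block: 8
  n_genes: 24
  gwas_n_variants: 4000
phenotype:
  method: fixed
  fixed_threshold: 23
  min_gene_freq: 0.05
sets:
  gwas_p_cut: 1.0e-5
  functional_max_dist: 200000
  promoter_bp: 1000
scan:
  alpha: 0.05
grs:
  enabled: true
cna_gwas:
  window_bp: 1000000
  known_radius: 1000000
  alpha: 0.05
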