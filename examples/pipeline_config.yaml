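# Full-pipeline configuration for `introgmap run --config ...`.
# Unknown keys are rejected; every referenced input path must exist.
seed: 42
outdir: introgmap_out
log_level: INFO

simulate:               # remove this block to run on your own files
  n_chrom: 2
  genes_per_chrom: 200
  depth_lambda: 100.0   # fragments per allele copy per kb
  crossmap_f: 0.3333333333333333
  donor_specific_insertions: [[0, 100]]
  recomb_cM_per_interval: 5.0
  locus_effect_a: 30.0  # days per donor allele dose
  pheno_mu: 60.0
  pheno_sigma: 3.0
  n_progeny: 200

synteny:
  min_score: 0.0
  max_gap: 5
  gap_penalty: 1.0
  min_block_size: 3

genotyping:
  pseudocount: 0.1
  min_count: 10
  smoothing_window: 5
  min_segment_genes: 3

mapping:
  phenotype_band_k: 1.0
  segregation_ratio: [1, 2, 1]
  association_method: anova
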