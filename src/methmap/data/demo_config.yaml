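# Demo run: a small two-chromosome genome exercising all three chemistries
# across two developmental stages.
genome:
  chromosome_lengths: [150000, 100000]
  background_gc: 0.42
  n_genes: 12
  exons_per_gene: [2, 5]
  gene_len: [2000, 8000]
  promoter_len: 5000
  n_cpg_islands: 8
  island_len: [400, 1200]
  island_gc: 0.65
  satellite_array_count: 2
  array_len: 60
  interspersed_repeat_classes:
    SINE: [300, 6]
    LINE: [1500, 3]
    LTR: [500, 3]

mark_model:
  p_mc_cpg_island: 0.7
  p_mc_cpg_nonisland: 0.25
  p_hmc_cpg: 0.05
  p_hmc_noncpg_ctag: 0.2
  repeat_multipliers:
    Satellite: 1.2
  stage_overrides:
    D7:
      p_hmc_cpg: 0.03
      p_hmc_noncpg_ctag: 0.15
    D12:
      p_hmc_cpg: 0.08
      p_hmc_noncpg_ctag: 0.3

stages: [D7, D12]
protocols: [ME_RDA, HME_RDA, HELP_COCKTAIL]

library:
  coverage: 3
  error_rate: 0.0

pipeline: {}

bin_bp: 50000
seed: 0
out_dir: demo_run
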