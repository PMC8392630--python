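# Bundled 5 Mb synthetic fixture: 19 MZ + 19 DZ pairs, 16 spiked regions.
# Tests and the reproduction script override `outdir` (and set
# `gene_model_path` to the bundled GTF) at run time.
seed: 11
window_size: 50
fragment_size: 200
min_region_size: 150
join_gap: 200
cutoff_fdr: 0.05
signal_fdr: 0.10
phase1_q: 0.01
phase2_p: 0.01
n_train_pairs: 12
n_restarts: 1000
simulate:
  chrom_lengths:
    chrS1: 3000000
    chrS2: 2000000
  n_pairs_mz: 19
  n_pairs_dz: 19
  baseline_mean: 20.0
  dispersion: 0.2
  pair_effect_sd: 0.15
  libsize_cv: 0.2
  spikes:
    - {chrom: chrS1, start: 200000, end: 200600, log2fc: 2.5}
    - {chrom: chrS1, start: 350000, end: 350600, log2fc: 2.5}
    - {chrom: chrS1, start: 500000, end: 500600, log2fc: 2.5}
    - {chrom: chrS1, start: 650000, end: 650600, log2fc: 2.5}
    - {chrom: chrS1, start: 800000, end: 800600, log2fc: 2.5}
    - {chrom: chrS1, start: 950000, end: 950600, log2fc: 2.5}
    - {chrom: chrS1, start: 1100000, end: 1100600, log2fc: 2.5}
    - {chrom: chrS1, start: 1250000, end: 1250600, log2fc: 2.5}
    - {chrom: chrS1, start: 1400000, end: 1400600, log2fc: 2.5}
    - {chrom: chrS1, start: 1550000, end: 1550600, log2fc: 2.5}
    - {chrom: chrS1, start: 1700000, end: 1700600, log2fc: -2.5}
    - {chrom: chrS1, start: 1850000, end: 1850600, log2fc: -2.5}
    - {chrom: chrS1, start: 2000000, end: 2000600, log2fc: -2.5}
    - {chrom: chrS1, start: 2150000, end: 2150600, log2fc: -2.5}
    - {chrom: chrS1, start: 2300000, end: 2300600, log2fc: -2.5}
    - {chrom: chrS1, start: 2450000, end: 2450600, log2fc: -2.5}
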