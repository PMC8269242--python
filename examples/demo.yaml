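# Demo run configuration: the universal 515Y/926R pair evaluated against a
# small synthetic fixture. Coordinates are 1-based inclusive positions on the
# E. coli K-12 MG1655 16S rRNA gene (the synthetic references embed the
# primer windows at the same coordinates).
primers:
  - name: 515Y
    sequence: GTGYCAGCMGCCGCGGTAA
    orientation: forward
    ref_start: 515
    ref_end: 533
  - name: 926R
    sequence: CCGYCAATTYMTTTRAGTTT
    orientation: reverse
    ref_start: 906
    ref_end: 925
pairs:
  - [515Y, 926R]
thresholds:
  mismatch_levels: [0, 1, 2]
  exclusion_mismatches: 6
  min_mean_quality: 30
  design_abundance: 0.02
flank: 5
require_both_flanks: false
pair_rule: product
seed: 0
simulation:
  reference_length: 1600
  read_length: 150
  n_reads: 500
  n_samples: 3
  groups: [Bacteria, Cyanobacteria_plastid]
  n_taxa: 12
  n_table_groups: 5
  n_table_samples: 10
  table_noise_sigma: 0.0
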