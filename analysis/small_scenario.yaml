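n_genomes: 60
n_phenotypes: 14
n_asvs: 160
seq_length: 120
n_datasets: 2
group_sizes: {HC: 16, CD: 8, UC: 8}
planted_effects:
  - {target_kind: phenotype, target_id: phen_rand_01, direction: enrich, log2_fc: 2.0, statuses: [CD, UC]}
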