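n_genes: 200
gene_length_codons: 150
fixed_diff_density: 0.01
clonal_divergence: 0.001
pi_s_targets:
  ibericus: 0.00045
  structor_wild: 0.0014
  structor_clonal: 0.00027
pi_n_over_pi_s_targets:
  ibericus: 0.21
  structor_wild: 0.21
  structor_clonal: 0.43
composition:
- caste: queen
  nominal_species: ibericus
  father_lineage: none
  count: 50
  androgenetic: false
- caste: male
  nominal_species: ibericus
  father_lineage: none
  count: 24
  androgenetic: false
- caste: male
  nominal_species: structor
  father_lineage: none
  count: 53
  androgenetic: false
- caste: worker
  nominal_species: ibericus
  father_lineage: clonal
  count: 144
  androgenetic: false
- caste: worker
  nominal_species: ibericus
  father_lineage: wild
  count: 20
  androgenetic: false
- caste: male
  nominal_species: structor
  father_lineage: clonal
  count: 24
  androgenetic: false
- caste: egg
  nominal_species: ibericus
  father_lineage: clonal
  count: 6
  androgenetic: false
- caste: egg
  nominal_species: ibericus
  father_lineage: clonal
  count: 2
  androgenetic: true
- caste: spermatheca
  nominal_species: ibericus
  father_lineage: clonal
  count: 1
  androgenetic: false
mito_length: 2000
mito_divergence: 0.02
mito_pi: 0.0005
depth_mean: 30.0
quality_model:
  mean: 60.0
  sd: 15.0
genotyping_error: 0.0
seed: 20240501
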