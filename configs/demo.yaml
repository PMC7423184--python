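# Demo pipeline config: a small synthetic cohort with the study's group
# sizes, two planted burden genes and one planted frequency shift.
seed: 7
flank_bp: 40000

simulate:
  n_per_group: {long_survivor: 26, stroke: 23, random: 56, control: 58}
  n_genes: 30
  theta: 60.0
  variants_per_gene: [10, 200]
  ne_epochs: [[1, 1000000]]
  planted_burden: {G05: 4.0, G12: 4.0}
  planted_diff:
    G20: {groups: [stroke, long_survivor], delta: 0.3}
  sensitivity: 0.95
  specificity: 0.95
  predictor_correlation: 0.3
  p_deleterious: 0.05
  missing_rate: 0.02
  gmt_sets: 6

prioritize:
  min_damaging: 17
  max_pop_freq: 0.01

burden:
  alpha: 0.05

differentiate:
  contrasts: [stroke:long_survivor, long_survivor:random, stroke:random]
  n_permutations: 500

skato:
  n_permutations: 500
  permute: residual
  n_pcs: 2

enrich:
  source: burden
  group: random
  top_n: 10
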