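# Toy end-to-end run: 20-node synthetic interactome, 2 synthetic diseases,
# 4-patient cohorts. Small on purpose; useful as a smoke test and template.
run_id: toy
seed: 17
outdir: results
base_disease: disease_0
synthetic:
  n_nodes: 20
  attachment: 2
  n_diseases: 2
  effectors_per_disease: 6
  overlap_with_base: [0.3]
  base_union_overlap: 0.3
  signed_fraction: 0.3
  directed_fraction: 0.2
  seed: 17
scoring:
  n_null: 49
cohorts:
  n: 4
  min_n: 4
  dose_mg: 70.0
  ec50: 0.05
netmodel:
  n_steps: 3
  accuracy_min: 0.85
  max_draws: 60
  n_restrictions: 3
moa:
  threshold: 0.5
  activation_min: 0.8
  frequency_min: 1.0
reverted_tables:
  bed: bed_reverted.tsv
  depression: depression_reverted.tsv
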