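# Desk-scale demo: a reduced synthetic pouch cohort that exercises every
# pipeline stage in a few minutes on one CPU.
seed: 11
simulate:
  n_normal_pouch: 12
  n_pouchitis: 12
  mean_samples_per_subject: 3.0
  depth: 200000
  separability: 1.5
thresholds:
  butyrate_identity: 90.0
  bai_identity: 70.0
  aln_len: 25
  evalue: 1.0e-5
  hk_identity: 97.0
  min_gyrA: 5
normalization:
  prevalence: 5.0
  abundance: 0.1
statistics:
  permutations: 199
  fdr_level: 0.1
classifier:
  k: 5
  repeats: 5
  top_k: 20
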