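# pouchflow

Targeted functional metagenomics of the ileal pouch: a tested, reusable
implementation of the computations used to characterize dysbiosis in
pouchitis — from translated-search hit tables to a normal-pouch vs
pouchitis classifier — together with a synthetic-cohort generator that
makes every stage verifiable against known ground truth, without any
sequence download.

## Who this is for

Microbiome researchers quantifying *specific* gene functions from shotgun
metagenomes (rather than whole-profile summaries): butyrate-synthesis
terminal genes (*but*, *buk*, *ato*, *4hbt*), the secondary-bile-acid
*bai* operon (*baiA*–*baiI*), and strain-variable *Ruminococcus gnavus*
mucin glycoside hydrolases (GH29/GH95/GH33) — plus the ecology,
mixed-model and machine-learning layers that turn those quantities into
phenotype comparisons.

## What it computes

**Targeted quantification.** Hits from a translated search (12-column
tabular alignment format) are E-value-gated (E ≤ 1e-5), reduced to the top
hit per read, then filtered at ≥90% identity and ≥25 aa alignment
(butyrate; ≥70% for *bai*). Retained counts c are converted to

    RPKM = c / (L̃_kb × N / 10^6)

with L̃_kb the family's median reference length in nucleotide-equivalent
kilobases (3 × median aa length / 1000) and N the metagenome's read count.
Reads are attributed to taxa via their best-hit reference gene.

**Strain fractions.** The percentage of *R. gnavus* strains carrying a
mucin GH is the length-normalized GH coverage over single-copy gyrA
coverage, F = 100 · (c_GH/L_GH)/(c_gyrA/L_gyrA), with GH reads at ≥90%
identity, housekeeping reads at ≥97% (closely related strains only), and
samples with fewer than 5 gyrA reads excluded as missing.

**Community scores & ecology.** Composite mucin-degradation and
oxidative-stress scores (each the sum of seven configured EC numbers);
CPM total-sum scaling, species prevalence/abundance filtering and
cross-cohort feature intersection; Shannon diversity (nats), Bray-Curtis
dissimilarity, PCoA (classical MDS), marginal single-variable PERMANOVA
with permutation p-values, tie-corrected Kruskal-Wallis with Dunn's
pairwise z-tests, and Spearman correlation — all implemented from first
principles and cross-checked against independent oracles in the tests.

**Differential abundance.** Per-feature linear mixed models on
log2-transformed abundances (per-sample minimum-nonzero smoothing of
zeros), phenotype + age + antibiotics as fixed effects, subject and cohort
as random intercepts, Benjamini-Hochberg FDR across all tests.

**Classification.** Subject-averaged profiles feed an XGBoost classifier
(learning rate 0.1, 250 trees, depth 3, subsample 0.5, colsample 0.5 —
0.1 for enzymes — gamma 0.1, L1 0.01, L2 0.5) evaluated by stratified
5-fold cross-validation repeated 100 times, with gain-importance-based
top-k feature selection and external-cohort validation (AUC, sensitivity,
specificity, accuracy, confusion matrix).

## Worked example

```python
from pouchflow import (make_toy_database, butyrate_profile, bai_profile,
                       estimate_fraction)
from pouchflow.synthetic import SimulationConfig, simulate_cohort, simulate_hits

db = make_toy_database(seed=1)
cfg = SimulationConfig(seed=7, n_subjects={"normal_pouch": 3, "pouchitis": 3})
truths, metadata = simulate_cohort(cfg)

t = next(t for t in truths if t.phenotype == "pouchitis")
hits, total_reads = simulate_hits(t, db, cfg)
but = butyrate_profile(hits, db, total_reads, sample_id=t.sample_id)
bai = bai_profile(hits, db, total_reads, sample_id=t.sample_id)
gh29 = estimate_fraction(hits, db, "GH29", sample_id=t.sample_id)

print(f"sample {t.sample_id} ({t.phenotype}), {total_reads:,} reads")
print(f"but RPKM      : {but.rpkm['but']:.1f}  (planted rate {t.gene_copy_rate['but']:.1f})")
print(f"bai operon    : {bai.rpkm['bai']:.1f} RPKM over {bai.read_count['bai']} reads")
print(f"GH29 fraction : {gh29.fraction_percent:.1f}% of R. gnavus strains "
      f"(planted {100*t.gh_carrier_fraction['GH29']:.1f}%, gyrA reads={gh29.gyrA_read_count})")
```

prints

```
sample S004_t0 (pouchitis), 1,000,000 reads
but RPKM      : 14.3  (planted rate 13.0)
bai operon    : 21.2 RPKM over 32 reads
GH29 fraction : 29.6% of R. gnavus strains (planted 41.3%, gyrA reads=78)
```

The *but* abundance of this simulated pouchitis sample sits near its
planted per-sample rate (the population median for pouchitis is 12 RPKM),
the eight *bai* genes aggregate to an operon-level RPKM, and the GH29
strain fraction — a single noisy Poisson draw here — scatters around the
planted carrier fraction; averaged over many samples the estimator is
unbiased (see the tests).

A full run (simulate → quantify → strain fractions → scores → ecology →
differential abundance → classify) from one config:

```sh
pouchflow run --config configs/demo.yaml --out runs/demo
```

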