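# Methods

## Scope and model of the data

The package operates downstream of read QC, host-read depletion and
taxonomic/functional profiling: its inputs are (a) translated-search hit
tables in the 12-column tabular alignment dialect (qseqid, sseqid, pident,
length, mismatch, gapopen, qstart, qend, sstart, send, evalue, bitscore),
(b) amino-acid reference databases with a gene → (family, taxon) annotation
table, (c) features × samples abundance tables (species relative %, pathway
and enzyme CPM), and (d) per-sample clinical metadata (subject, cohort,
phenotype ∈ {healthy, UC, CD, normal_pouch, pouchitis}, age, antibiotic
window, fecal calprotectin, total read count). Aligners, profilers and HMM
curation are out of scope; their outputs are contracts, not code.

## Targeted quantification

Processing order mirrors an aligner invocation in which the E-value cutoff
and single-target reporting happen at alignment time: hits are first gated
at E ≤ 1e-5, then reduced to one hit per read (maximal bitscore, ties by
lower E-value, then lexicographically smallest gene id — fully
deterministic), then filtered on identity and alignment length. All
thresholds are inclusive. Defaults: identity ≥90% and alignment ≥25 aa for
butyrate genes and the *R. gnavus* GHs, identity ≥70% for the *bai* operon
(its reference set is less comprehensive), ≥97% for housekeeping markers.
The ≥25 aa cutoff is applied to all screens for uniformity and is a config
knob.

RPKM uses the family's **median** reference length (robust to length
outliers among homologs), converted to nucleotide-equivalent kilobases
(×3/1000) because the numerator counts nucleotide reads. Families with
zero retained reads are reported as explicit zeros: absence of a gene
family from a metagenome is data. N is the per-metagenome read count
supplied in metadata; whether it counts reads or pairs is the caller's
convention (reads by default, mates being independent records).

## Strain fractions

The fraction of *R. gnavus* strains encoding GH29/GH95/GH33 is
length-normalized GH coverage over length-normalized single-copy-marker
coverage, ×100. Here each reference gene's **own** length is used (the GH
and housekeeping references are single sequences from strain ATCC 29149),
not a family median. gyrA is the default marker; a three-marker variant
(mean of gyrA, recA, rplB) is provided as the documented alternative.
Samples with fewer than 5 gyrA reads are excluded and propagate as missing
values — never zeros — into downstream statistics. Fractions above 100%
are possible (multi-copy GH, cross-mapping) and are reported as computed
with a flag; truncation would bias the recovery tests.

## Composite scores and table rules

The mucin-degradation score sums seven functionally characterized
mucin-active glycoside hydrolase ECs; the oxidative-stress score sums
seven oxygen-detoxifying enzyme ECs (glutamate-cysteine ligase 6.3.2.2,
glutathione synthase 6.3.2.3, glutathione-disulfide reductase 1.8.1.7,
superoxide dismutase 1.15.1.1, peroxiredoxin 1.11.1.15,
peptide-methionine sulfoxide reductase 1.8.4.11, catalase 1.11.1.6). Both
sets live in `pouchflow/data/ec_sets.yaml`, editable without code changes.
Missing ECs contribute zero with a warning; both scores are linear in the
per-sample abundance vector, and per-taxon contributions of stratified
rows conserve the community total.

The species removal rule is read conjunctively: a species is removed only
when its prevalence is below 5% of samples **and** it never reaches 0.1%
relative abundance in any sample (the disjunctive reading is available via
`rule="or"`). No renormalization follows removal. Community abundance
units are carried through verbatim and never converted between CPM and
RPKM.

## Ecology statistics

All five statistics are implemented from the definitions and pinned
against independent implementations (scipy, scikit-bio, statsmodels) in
the tests. Shannon diversity uses the natural log. Bray-Curtis is
Σ|x−y| / Σ(x+y) per sample pair; all-zero pairs get distance 0 with a
warning. PCoA eigendecomposes the Gower-centered −½ J D² J; negative
eigenvalues are reported but their axes dropped, proportions explained are
over positive eigenvalues only (no Cailliez/Lingoes correction, matching
classical-MDS defaults), and axis signs are fixed so the lexicographically
smallest sample id has non-negative coordinates — orientation is
theoretically arbitrary, so downstream correlations are assessed by
magnitude.

PERMANOVA is marginal (one variable at a time, avoiding order dependence):
R² = tr(H G H)/tr(G) with H the variable's hat matrix, pseudo-F with
(df_model, n − df_model − 1). Permutations shuffle whole samples; the
random scheme reports p = (1 + #{F* ≥ F})/(1 + B), and an exact mode
enumerates all n! relabelings for tiny designs (p = #{F* ≥ F}/n!, identity
included). Longitudinal samples are permuted freely, as when subject-level
variables are fitted on all samples; a within-subject-restricted scheme
would be the conservative alternative and is noted as a caveat rather than
implemented as default. Kruskal-Wallis H is tie-corrected (H = 0, p = 1
when every observation is tied); Dunn pairwise z-tests use the pooled-tie
variance, with Benjamini-Hochberg adjustment by default (Bonferroni and
none selectable) — consistent with the FDR convention used everywhere
else. Spearman drops incomplete pairs pairwise (calprotectin is missing
for a subset of samples in practice) and uses the t approximation for p.

## Differential abundance

Zeros are replaced per sample by that sample's minimum nonzero value, then
log2 is applied ("replace" smoothing; "add half the minimum" is
selectable; base is configurable and recorded). Each feature is modeled
with fixed effects phenotype (healthy reference) + age + antibiotic window
(a two-level factor, 1–6 months vs >6 months off antibiotics; current use
is excluded upstream) and random intercepts for subject and cohort.
Because subjects are nested in cohorts, the REML fit (statsmodels MixedLM)
uses cohort groups with a subject variance component; features whose full
model fails to converge are refitted with a subject-only random intercept
and flagged if still failing. Wald p-values per phenotype coefficient are
BH-adjusted across the full feature × phenotype family. Zero-variance
features are skipped with `converged=False`. Compositional (log-ratio) and
zero-inflated models are deliberately out of scope.

## Classification protocol

Longitudinal samples are arithmetically averaged per subject (optionally
appending mean calprotectin as a predictor). The learner is XGBoost with
the fixed hyperparameters given in the README; the only per-model change
is colsample_bytree (0.5 for species/pathways, 0.1 for enzymes).
Evaluation is stratified 5-fold CV repeated 100 times, each repeat seeded
from the master seed, so a report is bit-reproducible. Feature importances
("gain", configurable) are averaged over all repeat × fold fits; the top-k
by mean importance (ties lexicographic) feed a final model refitted on the
full discovery set and scored on an external cohort (probability ≥ 0.5 →
pouchitis). Two selection modes exist: pooled-importance selection (the
reproduction protocol) and nested within-fold selection. Pooled selection
reuses held-out folds and can inflate apparent performance on null data;
the test suite demonstrates the difference, and nested mode is the safer
choice for new data.

## The synthetic-data generator

The generator emulates the pouch study design as its default conditions:
35 normal-pouch + 34 pouchitis subjects, 1 + Poisson(2) samples per
subject (median 3), depth 10^6 reads per sample (a desk-scale stand-in for
~6.2M-read metagenomes). Per-phenotype gene abundances are planted on the
RPKM scale at the reported medians (*but* 78 vs 12 RPKM for normal pouch
vs pouchitis, *bai* cluster 44.6 vs 21.3, etc.), with log-normal subject
and sample jitter; read counts are Poisson(rate × depth/10^6 × L_kb), so
the RPKM estimator's expectation is the planted rate. On-target identities
are clipped normal (mean 97, sd 2, ≥92; housekeeping mean 99, ≥97); decoys
are uniform on 60–88% identity with E-values spanning 1e-5, capped below
70% on *bai* genes so that off-target reads stay below every screen's
threshold. GH read rates are tied to the gyrA rate so that the expected
length-normalized GH/gyrA ratio equals the planted carrier fraction
(per-phenotype defaults at the reported medians, e.g. GH29 39.6% in
pouchitis). Fecal calprotectin follows log10(cal) = 2 + 0.5·dysbiosis +
N(0, 0.3); the feature-table dysbiosis loadings (sd 0.35) are calibrated
so PCoA axis-1 vs calprotectin sits in the |ρ| ≈ 0.4 regime. A single
separability parameter gates all phenotype-linked signal in the feature
tables: 0 gives chance-level classification, large values near-perfect.

What the generator does **not** emulate: sequence-level errors (alignment
statistics are drawn directly; a tiny exact-match translated matcher
exists only for one end-to-end smoke test), compositional coupling between
the targeted genes and the profiled tables, realistic phylogenetic
correlation among species, informative dropout, or batch effects beyond a
log-scale cohort intercept. Green tests therefore certify the estimators
and protocol logic under a faithful *statistical* model of the data, not
performance on real metagenomes.

## Numerical choices and problem sizes

Tie-breaks (top-hit selection, importance ranking) are lexicographic, and
every stochastic component takes an explicit seed, so all pipelines are
reproducible bit-for-bit. The verification suite uses deliberately chosen
problem sizes: 100 simulated metagenomes at depth 10^6 for strain-fraction
recovery (tolerance ±5 percentage points), 200 simulations × 99
permutations for the PERMANOVA type-I calibration, 500 randomized cases
for the brute-force rank-statistic checks, 100 mixed-model fits for CI
coverage plus 500 null features for FDR behavior, CV repeats reduced to 10
for the classifier checks, and a demo pipeline of 12+12 subjects at depth
2×10^5 — sizes at which every check completes in seconds to a few minutes
on a single core while keeping Monte-Carlo error well inside the stated
tolerances.

## Known limitations

- PERMANOVA free permutation ignores repeated measures; with strong
  within-subject correlation its p-values are anti-conservative.
- The cohort variance component is weakly identified with few cohorts;
  the subject-only fallback keeps fixed effects honest at the cost of
  absorbing cohort variance into the residual/subject terms.
- The pooled-importance selection mode reproduces the published protocol
  and is optimistic on null data by construction; use the nested mode for
  honest error estimates on new cohorts.
- Strain fractions assume single-copy references in a single target
  species; multi-copy GHs or cross-mapping inflate fractions (flagged,
  not corrected).
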