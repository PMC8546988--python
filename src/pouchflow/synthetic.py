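"""Synthetic cohort, hit-table and abundance-table generators.

Every input the pipeline consumes can be generated here with known ground
truth: a toy reference database, longitudinal IBD cohorts (healthy, UC, CD,
normal pouch, pouchitis) with subject/cohort structure, translated-search
hit tables whose alignment statistics mimic a DIAMOND BLASTX run, and
species/pathway/enzyme abundance tables with planted phenotype effects.

The defaults emulate the pouch study design: 35 normal-pouch and 34
pouchitis subjects sampled longitudinally (median 3 samples per subject),
with per-phenotype gene abundances anchored to the reported medians
(e.g. *but* RPKM 78 in normal pouch vs 12 in pouchitis, *bai* cluster
44.6 vs 21.3) and *R. gnavus* GH29/GH95/GH33 carrier fractions at the
reported per-phenotype medians. Sequencing depth defaults to 10^6 reads per
sample — a desk-scale stand-in for the study's ~6.2M reads per metagenome.

All generators are pure functions of (config, seed): rerunning with the
same configuration reproduces outputs byte-identically.
"""

from __future__ import annotations

import dataclasses
import json
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .reference_db import (
    BAI_FAMILIES,
    BUTYRATE_FAMILIES,
    GH_FAMILIES,
    HOUSEKEEPING_FAMILIES,
    GeneDatabase,
    ReferenceGene,
)
from .scores import MUCIN_ECS, OXIDATIVE_ECS, AbundanceTable

PHENOTYPES = ("healthy", "UC", "CD", "normal_pouch", "pouchitis")

#: 12-column tabular alignment dialect (BLAST/DIAMOND outfmt 6).
HIT_COLUMNS = [
    "qseqid", "sseqid", "pident", "length", "mismatch", "gapopen",
    "qstart", "qend", "sstart", "send", "evalue", "bitscore",
]

# Per-phenotype expected gene abundance on the RPKM scale (reads per kb of
# reference per million reads). Butyrate and bai values follow the reported
# per-phenotype medians; the bai total is split evenly over its 8 genes.
# gyrA tracks R. gnavus load (enriched in the pouch, highest in pouchitis);
# recA/rplB recruit slightly fewer reads than gyrA after normalization.
_BAI_TOTal = {"healthy": 90.0, "UC": 72.6, "CD": 71.0,
              "normal_pouch": 44.6, "pouchitis": 21.3}
DEFAULT_PHENOTYPE_RATES: dict[str, dict[str, float]] = {
    pheno: {
        "but": {"healthy": 150.0, "UC": 136.0, "CD": 126.0,
                "normal_pouch": 78.0, "pouchitis": 12.0}[pheno],
        "buk": {"healthy": 25.3, "UC": 14.7, "CD": 6.6,
                "normal_pouch": 8.4, "pouchitis": 4.75}[pheno],
        "ato": {"healthy": 3.0, "UC": 2.0, "CD": 1.0,
                "normal_pouch": 0.3, "pouchitis": 0.2}[pheno],
        "4hbt": {"healthy": 2.5, "UC": 1.5, "CD": 1.0,
                 "normal_pouch": 0.25, "pouchitis": 0.15}[pheno],
        **{fam: _BAI_TOTal[pheno] / len(BAI_FAMILIES) for fam in BAI_FAMILIES},
        "gyrA": {"healthy": 3.0, "UC": 4.0, "CD": 8.0,
                 "normal_pouch": 15.0, "pouchitis": 30.0}[pheno],
        "recA": 0.8 * {"healthy": 3.0, "UC": 4.0, "CD": 8.0,
                       "normal_pouch": 15.0, "pouchitis": 30.0}[pheno],
        "rplB": 0.9 * {"healthy": 3.0, "UC": 4.0, "CD": 8.0,
                       "normal_pouch": 15.0, "pouchitis": 30.0}[pheno],
    }
    for pheno in PHENOTYPES
}

# Reported per-phenotype median carrier fractions for the R. gnavus GHs.
DEFAULT_GH_CARRIER: dict[str, dict[str, float]] = {
    "healthy":      {"GH29": 0.05, "GH95": 0.04, "GH33": 0.02},
    "UC":           {"GH29": 0.06, "GH95": 0.05, "GH33": 0.02},
    "CD":           {"GH29": 0.183, "GH95": 0.13, "GH33": 0.053},
    "normal_pouch": {"GH29": 0.113, "GH95": 0.101, "GH33": 0.02},
    "pouchitis":    {"GH29": 0.396, "GH95": 0.25, "GH33": 0.024},
}

# Latent dysbiosis score per phenotype (arbitrary units; healthy = 0).
_DYSBIOSIS_BASE = {"healthy": 0.0, "UC": 1.0, "CD": 1.2,
                   "normal_pouch": 1.0, "pouchitis": 2.0}


@dataclass
class SimulationConfig:
    """Knobs of the synthetic study.

    ``n_subjects`` maps phenotype to subject count (default: the pouch
    discovery design, 35 normal pouch + 34 pouchitis). Rates are on the
    RPKM scale; identity models give the alignment-statistic marginals of
    on-target, housekeeping and decoy hits.
    """

    n_subjects: dict[str, int] = field(
        default_factory=lambda: {"normal_pouch": 35, "pouchitis": 34}
    )
    mean_samples_per_subject: float = 3.0
    depth: int = 1_000_000
    seed: int = 0
    rates: dict[str, dict[str, float]] = field(
        default_factory=lambda: {p: dict(v) for p, v in DEFAULT_PHENOTYPE_RATES.items()}
    )
    gh_carrier: dict[str, dict[str, float]] = field(
        default_factory=lambda: {p: dict(v) for p, v in DEFAULT_GH_CARRIER.items()}
    )
    # alignment-statistic marginals
    on_target_identity: tuple[float, float, float] = (97.0, 2.0, 92.0)  # mean, sd, min
    hk_identity: tuple[float, float, float] = (99.0, 0.8, 97.0)
    decoy_identity: tuple[float, float] = (60.0, 88.0)  # uniform range
    decoy_rate: float = 200.0  # decoy reads per million
    secondary_hit_rate: float = 0.1  # fraction of reads that get a 2nd, weaker hit
    # calprotectin model: log10(cal) = a + b * dysbiosis + N(0, sd)
    calprotectin_a: float = 2.0
    calprotectin_b: float = 0.5
    calprotectin_sd: float = 0.3
    # feature-table generator
    separability: float = 1.0
    n_species: int = 60
    n_pathways: int = 40
    n_enzymes_extra: int = 56
    subject_sd: float = 0.5
    cohort_sd: float = 0.3
    sample_sd: float = 0.4
    n_cohorts: int = 2

    def __post_init__(self) -> None:
        if self.depth < 10_000:
            raise ValueError("depth must be >= 10^4 reads")
        for pheno, fams in self.rates.items():
            for fam, r in fams.items():
                if r < 0:
                    raise ValueError(f"negative rate for {pheno}/{fam}")

    def log2_effects(self, reference: str = "healthy") -> dict[str, dict[str, float]]:
        """Planted log2 fold changes of each family rate vs a reference phenotype."""
        ref = self.rates[reference]
        out: dict[str, dict[str, float]] = {}
        for pheno, fams in self.rates.items():
            out[pheno] = {
                fam: float(np.log2(r / ref[fam])) if r > 0 and ref[fam] > 0 else float("nan")
                for fam, r in fams.items()
            }
        return out

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


@dataclass
class CommunityTruth:
    """Ground truth for one simulated sample."""

    sample_id: str
    subject_id: str
    cohort_id: str
    phenotype: str
    species_rel_abund: dict[str, float]
    gh_carrier_fraction: dict[str, float]
    gene_copy_rate: dict[str, float]
    latent_dysbiosis: float
    calprotectin: float

    def __post_init__(self) -> None:
        total = sum(self.species_rel_abund.values())
        if self.species_rel_abund and abs(total - 1.0) > 1e-9:
            raise ValueError(f"species fractions sum to {total}, not 1")
        if self.calprotectin <= 0:
            raise ValueError("calprotectin must be positive")
        for gh, f in self.gh_carrier_fraction.items():
            if not 0.0 <= f <= 1.0:
                raise ValueError(f"carrier fraction {gh}={f} outside [0,1]")


# ---------------------------------------------------------------------------
# toy reference database
# ---------------------------------------------------------------------------

_AA20 = np.array(list("ACDEFGHIKLMNPQRSTVWY"))

_BUTYRATE_TAXA = [
    "Faecalibacterium_prausnitzii", "Roseburia_intestinalis",
    "Eubacterium_rectale", "Coprococcus_comes", "Anaerostipes_hadrus",
]
_BAI_TAXA = ["Clostridium_scindens", "Clostridium_hylemonae", "Clostridium_hiranonis"]
_RGNAVUS = "Ruminococcus_gnavus"
# Approximate real lengths of the single-copy R. gnavus references (aa),
# kept inside the 250-700 aa range of the toy database.
_RG_LENGTHS = {"GH29": 448, "GH95": 700, "GH33": 610,
               "gyrA": 690, "recA": 352, "rplB": 278}


def _random_protein(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(_AA20, size=length))


def make_toy_database(seed: int = 0) -> GeneDatabase:
    """A small but complete reference database with every quantified family.

    Butyrate and bai families get >=3 members spread over realistic source
    taxa with lengths in 250-700 aa; the R. gnavus GH and housekeeping
    genes are single sequences (one strain), as in the real reference set.
    Deterministic for a fixed seed.
    """
    rng = np.random.default_rng([seed, 0x0DB])
    db = GeneDatabase()
    for fam in BUTYRATE_FAMILIES:
        for i in range(4):
            length = int(rng.integers(350, 551))
            db.add(ReferenceGene(
                gene_id=f"{fam}_{i:02d}",
                sequence=_random_protein(rng, length),
                family=fam,
                taxon=_BUTYRATE_TAXA[i % len(_BUTYRATE_TAXA)],
                db_name="butyrate_toy",
            ))
    for fam in BAI_FAMILIES:
        for i in range(3):
            length = int(rng.integers(250, 701))
            db.add(ReferenceGene(
                gene_id=f"{fam}_{i:02d}",
                sequence=_random_protein(rng, length),
                family=fam,
                taxon=_BAI_TAXA[i % len(_BAI_TAXA)],
                db_name="bai_toy",
            ))
    for fam in GH_FAMILIES + HOUSEKEEPING_FAMILIES:
        db.add(ReferenceGene(
            gene_id=f"Rgnavus_{fam}",
            sequence=_random_protein(rng, _RG_LENGTHS[fam]),
            family=fam,
            taxon=_RGNAVUS,
            db_name="rgnavus_toy",
        ))
    return db


# ---------------------------------------------------------------------------
# cohort simulation
# ---------------------------------------------------------------------------

def simulate_cohort(config: SimulationConfig) -> tuple[list[CommunityTruth], pd.DataFrame]:
    """Draw a longitudinal cohort: subjects, samples, metadata, ground truth.

    Each subject keeps one phenotype and cohort across samples; the number
    of samples per subject is 1 + Poisson(mean - 1); fecal calprotectin is
    log-normal with mean increasing in the latent dysbiosis score.
    """
    for pheno, n in config.n_subjects.items():
        if pheno not in PHENOTYPES:
            raise ValueError(f"unknown phenotype {pheno!r}")
        if n <= 0:
            raise ValueError(f"phenotype {pheno!r} requests {n} subjects")
    rng = np.random.default_rng([config.seed, 0xC0])

    truths: list[CommunityTruth] = []
    meta_rows = []
    subj_counter = 0
    for pheno in PHENOTYPES:
        if pheno not in config.n_subjects:
            continue
        for _ in range(config.n_subjects[pheno]):
            subj_counter += 1
            subject_id = f"S{subj_counter:03d}"
            cohort_id = f"cohort_{rng.integers(config.n_cohorts)}"
            n_samples = 1 + rng.poisson(max(config.mean_samples_per_subject - 1, 0))
            age = float(np.clip(rng.normal(45, 12), 18, 85))
            subj_dysb = _DYSBIOSIS_BASE[pheno] + rng.normal(0, 0.3)
            subj_rate_noise = {
                fam: float(2.0 ** rng.normal(0, 0.25))
                for fam in config.rates[pheno]
            }
            for k in range(n_samples):
                sample_id = f"{subject_id}_t{k}"
                dysb = subj_dysb + rng.normal(0, 0.2)
                cal = float(10.0 ** (
                    config.calprotectin_a
                    + config.calprotectin_b * dysb
                    + rng.normal(0, config.calprotectin_sd)
                ))
                rates = {
                    fam: r * subj_rate_noise[fam] * float(2.0 ** rng.normal(0, 0.15))
                    for fam, r in config.rates[pheno].items()
                }
                gh = {
                    g: float(np.clip(f * 2.0 ** rng.normal(0, 0.1), 0.0, 1.0))
                    for g, f in config.gh_carrier[pheno].items()
                }
                truths.append(CommunityTruth(
                    sample_id=sample_id,
                    subject_id=subject_id,
                    cohort_id=cohort_id,
                    phenotype=pheno,
                    species_rel_abund={},
                    gh_carrier_fraction=gh,
                    gene_copy_rate=rates,
                    latent_dysbiosis=float(dysb),
                    calprotectin=cal,
                ))
                meta_rows.append({
                    "sample_id": sample_id,
                    "subject_id": subject_id,
                    "cohort_id": cohort_id,
                    "phenotype": pheno,
                    "age": round(age, 1),
                    "antibiotics": "1-6mo" if rng.random() < 0.16 else ">6mo",
                    "calprotectin": round(cal, 1),
                    "total_reads": config.depth,
                })
    metadata = pd.DataFrame(meta_rows).set_index("sample_id")
    return truths, metadata


# ---------------------------------------------------------------------------
# hit-table simulation
# ---------------------------------------------------------------------------

def _sample_rng(config: SimulationConfig, sample_id: str) -> np.random.Generator:
    return np.random.default_rng([config.seed, zlib.crc32(sample_id.encode()) % 2**31])


def _trunc_normal(rng, mean, sd, lo, hi, size):
    x = rng.normal(mean, sd, size=size)
    return np.clip(x, lo, hi)


def simulate_hits(
    truth: CommunityTruth, db: GeneDatabase, config: SimulationConfig
) -> tuple[pd.DataFrame, int]:
    """One sample's translated-search hit table plus its total read count.

    Per-family on-target read counts are Poisson with expectation
    ``rate × depth/10^6 × L_kb`` (L_kb = 3 × reference length / 1000), so the
    planted rate is recovered on the RPKM scale. On-target identities follow
    a clipped normal (>=92%), housekeeping hits a tighter one (>=97%), and
    decoy hits are uniform on 60-88% identity with E-values spanning the
    1e-5 threshold. The R. gnavus GH read rate is tied to the gyrA rate so
    the expected length-normalized GH/gyrA ratio equals the planted carrier
    fraction.
    """
    if config.depth < 10_000:
        raise ValueError("depth must be >= 10^4 reads")
    for fam, rate in truth.gene_copy_rate.items():
        if rate > 0 and not db.members(fam):
            raise ValueError(f"database lacks members of family {fam!r}")
    rng = _sample_rng(config, truth.sample_id)
    rows: list[dict] = []
    read_no = 0
    per_million = config.depth / 1e6

    def _emit(gene: ReferenceGene, pident: float, identity_floor: float) -> None:
        nonlocal read_no
        read_no += 1
        aln = int(rng.integers(25, 51))
        start = int(rng.integers(1, max(gene.length_aa - aln, 2)))
        evalue = float(10.0 ** (-rng.uniform(10, 40)))
        bitscore = float(np.round(2.0 * aln + rng.normal(0, 2), 1))
        read_id = f"{truth.sample_id}:r{read_no}"
        rows.append(dict(zip(HIT_COLUMNS, [
            read_id, gene.gene_id, round(pident, 1), aln,
            int(aln * (100 - pident) / 100), 0, 1, aln * 3,
            start, start + aln - 1, evalue, bitscore,
        ])))
        if rng.random() < config.secondary_hit_rate:
            other = db.members(gene.family)
            alt = other[int(rng.integers(len(other)))]
            rows.append(dict(zip(HIT_COLUMNS, [
                read_id, alt.gene_id,
                round(max(pident - rng.uniform(1, 5), identity_floor), 1),
                aln, int(aln * 0.1), 0, 1, aln * 3, start, start + aln - 1,
                evalue * 10, round(bitscore - rng.uniform(3, 15), 1),
            ])))

    gyrA_rate = truth.gene_copy_rate.get("gyrA", 0.0)
    for fam, rate in truth.gene_copy_rate.items():
        if rate <= 0:
            continue
        members = db.members(fam)
        lengths = np.array([g.length_aa for g in members], dtype=float)
        l_kb = 3.0 * float(np.median(lengths)) / 1000.0
        n = rng.poisson(rate * per_million * l_kb)
        hk = fam in HOUSEKEEPING_FAMILIES
        mean, sd, lo = config.hk_identity if hk else config.on_target_identity
        idents = _trunc_normal(rng, mean, sd, lo, 100.0, n)
        for i in range(n):
            gene = members[int(rng.integers(len(members)))]
            _emit(gene, float(idents[i]), lo)

    # R. gnavus GH reads: expectation f × gyrA_rate × depth/1e6 × L_GH_kb
    for gh, f in truth.gh_carrier_fraction.items():
        members = db.members(gh)
        if not members:
            raise ValueError(f"database lacks members of family {gh!r}")
        gene = members[0]
        lam = f * gyrA_rate * per_million * 3.0 * gene.length_aa / 1000.0
        n = rng.poisson(lam)
        mean, sd, lo = config.on_target_identity
        idents = _trunc_normal(rng, mean, sd, lo, 100.0, n)
        for i in range(n):
            _emit(gene, float(idents[i]), lo)

    # decoys: off-target noise below the identity thresholds, E-values
    # spanning the 1e-5 cutoff
    all_genes = list(db.genes.values())
    n_decoy = rng.poisson(config.decoy_rate * per_million)
    for _ in range(n_decoy):
        read_no += 1
        gene = all_genes[int(rng.integers(len(all_genes)))]
        lo_id, hi_id = config.decoy_identity
        # decoys stay below the quantification cutoff of the family they
        # land on (the bai screen accepts down to 70% identity)
        if gene.family in BAI_FAMILIES:
            hi_id = min(hi_id, 68.0)
        pident = float(rng.uniform(lo_id, hi_id))
        aln = int(rng.integers(15, 40))
        start = int(rng.integers(1, max(gene.length_aa - aln, 2)))
        evalue = float(10.0 ** (-rng.uniform(2, 8)))
        rows.append(dict(zip(HIT_COLUMNS, [
            f"{truth.sample_id}:r{read_no}", gene.gene_id, round(pident, 1),
            aln, int(aln * (100 - pident) / 100), 1, 1, aln * 3,
            start, start + aln - 1, evalue, round(aln * 1.0 + rng.normal(0, 2), 1),
        ])))

    hits = pd.DataFrame(rows, columns=HIT_COLUMNS)
    return hits, config.depth


# ---------------------------------------------------------------------------
# feature tables (profiling outputs)
# ---------------------------------------------------------------------------

_NAMED_SPECIES = [
    "Faecalibacterium_prausnitzii", "Ruminococcus_gnavus",
    "Escherichia_coli", "Bacteroides_vulgatus", "Roseburia_intestinalis",
    "Akkermansia_muciniphila", "Eubacterium_rectale", "Blautia_obeum",
]


def _feature_ids(kind: str, config: SimulationConfig) -> list[str]:
    if kind == "species":
        extra = [f"Species_{i:03d}" for i in range(config.n_species - len(_NAMED_SPECIES))]
        return _NAMED_SPECIES + extra
    if kind == "pathways":
        return [f"PWY-{1000 + i}" for i in range(config.n_pathways)]
    if kind == "enzymes":
        rng = np.random.default_rng([0xEC, 7])
        extra, seen = [], set(MUCIN_ECS) | set(OXIDATIVE_ECS)
        while len(extra) < config.n_enzymes_extra:
            ec = f"{rng.integers(1, 7)}.{rng.integers(1, 20)}.{rng.integers(1, 20)}.{rng.integers(1, 99)}"
            if ec not in seen:
                seen.add(ec)
                extra.append(ec)
        return list(MUCIN_ECS) + list(OXIDATIVE_ECS) + extra
    raise ValueError(kind)


def simulate_feature_tables(
    truths: list[CommunityTruth], config: SimulationConfig
) -> dict[str, AbundanceTable]:
    """Species (%), pathway (CPM) and enzyme (CPM) tables with planted signal.

    Log-scale model per feature f and sample s:
    ``base_f + load_f × dysbiosis_s + sep_f × separability × 1[pouchitis_s]
    + u_{subject(s),f} + v_{cohort(s),f} + e_{s,f}``, exponentiated and
    column-normalized. The first few features of each table carry the
    normal-pouch vs pouchitis separation; R. gnavus loads positively and
    F. prausnitzii negatively on the dysbiosis axis, and the enzyme table's
    informative set includes mucin ECs (down in pouchitis) and
    oxidative-stress ECs (up in pouchitis).
    """
    phenos = {t.phenotype for t in truths}
    if len(phenos) < 2:
        raise ValueError("need >=2 phenotypes to plant separable signal")
    rng = np.random.default_rng([config.seed, 0xFEA7])
    sample_ids = [t.sample_id for t in truths]
    subjects = sorted({t.subject_id for t in truths})
    cohorts = sorted({t.cohort_id for t in truths})
    dysb = np.array([t.latent_dysbiosis for t in truths])
    is_pouchitis = np.array([t.phenotype == "pouchitis" for t in truths], dtype=float)

    out: dict[str, AbundanceTable] = {}
    for kind, unit, total in (
        ("species", "relative_percent", 100.0),
        ("pathways", "CPM", 1e6),
        ("enzymes", "CPM", 1e6),
    ):
        ids = _feature_ids(kind, config)
        m = len(ids)
        base = rng.normal(0, 1.5, size=m)
        # loading scale calibrated so PCoA axis 1 vs calprotectin sits in
        # the |rho| ~ 0.4 regime under the default calprotectin model
        load = rng.normal(0, 0.35, size=m)
        sep = np.zeros(m)
        n_info = 8
        sep[:n_info] = rng.choice([-1.0, 1.0], size=n_info) * rng.uniform(0.5, 1.0, n_info)
        if kind == "species":
            load[ids.index("Ruminococcus_gnavus")] = 0.8
            load[ids.index("Faecalibacterium_prausnitzii")] = -0.8
            load[ids.index("Escherichia_coli")] = 0.6
        if kind == "enzymes":
            for ec in MUCIN_ECS:
                sep[ids.index(ec)] = -rng.uniform(0.3, 0.6)
            for ec in OXIDATIVE_ECS:
                sep[ids.index(ec)] = rng.uniform(0.3, 0.6)
                load[ids.index(ec)] = 0.3
        subj_eff = {s: rng.normal(0, config.subject_sd, size=m) for s in subjects}
        coh_eff = {c: rng.normal(0, config.cohort_sd, size=m) for c in cohorts}
        cols = {}
        for j, t in enumerate(truths):
            log_x = (
                base
                + config.separability * (load * dysb[j] + sep * is_pouchitis[j])
                + subj_eff[t.subject_id]
                + coh_eff[t.cohort_id]
                + rng.normal(0, config.sample_sd, size=m)
            )
            x = np.exp(log_x)
            cols[t.sample_id] = x / x.sum() * total
        df = pd.DataFrame(cols, index=ids).loc[:, sample_ids]
        out[kind] = AbundanceTable(df, unit=unit)
    return out


# ---------------------------------------------------------------------------
# naive translated matcher (end-to-end smoke test only)
# ---------------------------------------------------------------------------

# one fixed codon per residue; enough for an exact-match round trip
_CODON = {
    "A": "GCT", "C": "TGT", "D": "GAT", "E": "GAA", "F": "TTT", "G": "GGT",
    "H": "CAT", "I": "ATT", "K": "AAA", "L": "CTT", "M": "ATG", "N": "AAT",
    "P": "CCT", "Q": "CAA", "R": "CGT", "S": "TCT", "T": "ACT", "V": "GTT",
    "W": "TGG", "Y": "TAT",
}


def reads_from_genes(
    db: GeneDatabase, n_reads: int, seed: int = 0, read_aa: int = 30
) -> tuple[dict[str, str], dict[str, str]]:
    """Reverse-translate random windows of reference genes into nt reads.

    Returns (read_id -> nucleotide sequence, read_id -> true gene_id).
    """
    rng = np.random.default_rng([seed, 0x5EAD])
    genes = list(db.genes.values())
    reads, origin = {}, {}
    for i in range(n_reads):
        g = genes[int(rng.integers(len(genes)))]
        start = int(rng.integers(0, g.length_aa - read_aa))
        pep = g.sequence[start:start + read_aa]
        reads[f"read_{i}"] = "".join(_CODON[a] for a in pep)
        origin[f"read_{i}"] = g.gene_id
    return reads, origin


def naive_translated_search(reads: dict[str, str], db: GeneDatabase) -> pd.DataFrame:
    """Exact-substring translated search: each read's 6 frames vs each gene.

    A deliberately simple stand-in for a real translated aligner, used only
    to smoke-test the pipeline end to end on reads with known origin. Emits
    100%-identity hits with a nominal E-value/bitscore.
    """
    from Bio.Seq import Seq

    rows = []
    for read_id, nt in reads.items():
        seq = Seq(nt)
        frames = [str((seq[f:]).translate()) for f in range(3)]
        rc = seq.reverse_complement()
        frames += [str((rc[f:]).translate()) for f in range(3)]
        for gene in db.genes.values():
            best = 0
            for fr in frames:
                fr = fr.split("*")[0]
                if len(fr) >= 15 and fr in gene.sequence:
                    best = max(best, len(fr))
            if best:
                pos = gene.sequence.find(frames[0].split("*")[0]) + 1
                rows.append(dict(zip(HIT_COLUMNS, [
                    read_id, gene.gene_id, 100.0, best, 0, 0,
                    1, best * 3, max(pos, 1), max(pos, 1) + best - 1,
                    1e-30, 2.0 * best,
                ])))
    return pd.DataFrame(rows, columns=HIT_COLUMNS)


# ---------------------------------------------------------------------------
# writers
# ---------------------------------------------------------------------------

def write_hit_table(hits: pd.DataFrame, path: str | Path) -> None:
    hits.to_csv(path, sep="\t", index=False, header=False)


def read_hit_table(path: str | Path) -> pd.DataFrame:
    """Read a 12-column tabular alignment file; extra columns tolerated."""
    df = pd.read_csv(path, sep="\t", header=None)
    if df.shape[1] < 12:
        raise ValueError(f"{path}: expected >=12 columns, got {df.shape[1]}")
    df = df.iloc[:, :12]
    df.columns = HIT_COLUMNS
    return df


def write_metadata(metadata: pd.DataFrame, path: str | Path) -> None:
    metadata.to_csv(path, sep="\t")


def write_manifest(config: SimulationConfig, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump({"config": config.to_dict(), "seed": config.seed}, fh, indent=2)
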