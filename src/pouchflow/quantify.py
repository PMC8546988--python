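"""Targeted quantification of gene families from translated-search hits.

Turns 12-column tabular alignment hit tables into filtered read counts and
RPKM abundances per gene family, with taxon attribution via the reference
database. The processing order mirrors the aligner invocation: E-value
cutoff and top-hit selection first (both happen at alignment time via
``--evalue`` / ``--max-target-seqs 1``), then the identity and
alignment-length filters.

RPKM = c / (L_kb × N/10^6), with c the retained read count of a family,
L_kb the family's median reference length in nucleotide-equivalent
kilobases (3 × median aa length / 1000) and N the metagenome's total read
count.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .reference_db import BAI_FAMILIES, BUTYRATE_FAMILIES, GeneDatabase

# Alignment thresholds of the targeted screens.
BUTYRATE_MIN_IDENTITY = 90.0
BAI_MIN_IDENTITY = 70.0
MIN_ALN_LEN = 25
MAX_EVALUE = 1e-5


@dataclass
class QuantResult:
    """Per-family read counts and RPKM, with a per-taxon breakdown."""

    sample_id: str
    total_reads: int
    read_count: dict[str, int] = field(default_factory=dict)
    rpkm: dict[str, float] = field(default_factory=dict)
    taxon_breakdown: dict[tuple[str, str], float] = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "sample_id": self.sample_id,
                "family": list(self.rpkm),
                "read_count": [self.read_count[f] for f in self.rpkm],
                "rpkm": [self.rpkm[f] for f in self.rpkm],
            }
        )

    def taxa_frame(self) -> pd.DataFrame:
        rows = [
            {"sample_id": self.sample_id, "family": fam, "taxon": tax, "rpkm": v}
            for (fam, tax), v in sorted(self.taxon_breakdown.items())
        ]
        return pd.DataFrame(rows, columns=["sample_id", "family", "taxon", "rpkm"])


def filter_hits(
    hits: pd.DataFrame,
    min_identity: float,
    min_aln_len: int,
    max_evalue: float,
) -> pd.DataFrame:
    """Keep hits with identity >= min, alignment length >= min, E <= max.

    All three thresholds are inclusive: a hit at exactly 90% identity,
    25 aa and E = 1e-5 is retained.
    """
    if min_identity < 0 or min_aln_len < 0 or max_evalue < 0:
        raise ValueError("thresholds must be non-negative")
    mask = (
        (hits["pident"] >= min_identity)
        & (hits["length"] >= min_aln_len)
        & (hits["evalue"] <= max_evalue)
    )
    return hits.loc[mask]


def select_top_hit(hits: pd.DataFrame) -> pd.DataFrame:
    """One hit per read: maximal bitscore, ties by lower E-value then
    lexicographically smallest gene id (fully deterministic)."""
    if hits.empty:
        return hits
    ordered = hits.sort_values(
        ["qseqid", "bitscore", "evalue", "sseqid"],
        ascending=[True, False, True, True],
        kind="mergesort",
    )
    return ordered.drop_duplicates(subset="qseqid", keep="first")


def quantify_family_rpkm(
    hits: pd.DataFrame,
    db: GeneDatabase,
    total_reads: int,
    families: tuple[str, ...] | list[str],
    sample_id: str = "",
) -> QuantResult:
    """Count retained reads per family and convert to RPKM.

    ``hits`` must already be filtered and top-hit selected. Families with
    zero reads are reported with explicit zeros (genes absent from a sample
    are data, not missing values).
    """
    if total_reads <= 0:
        raise ValueError("total_reads must be positive")
    medians = db.family_median_length_aa
    for fam in families:
        if fam not in medians:
            raise KeyError(f"family {fam!r} absent from database")
    fam_of = {gid: g.family for gid, g in db.genes.items()}
    missing = set(hits["sseqid"]) - set(fam_of)
    if missing:
        raise KeyError(f"hit gene_id(s) not in database: {sorted(missing)[:5]}")

    res = QuantResult(sample_id=sample_id, total_reads=total_reads)
    hit_fams = hits["sseqid"].map(fam_of)
    per_million = total_reads / 1e6
    for fam in families:
        sub = hits.loc[hit_fams == fam]
        c = len(sub)
        l_kb = 3.0 * medians[fam] / 1000.0
        res.read_count[fam] = c
        res.rpkm[fam] = c / (l_kb * per_million)
        # taxon attribution: each read contributes its RPKM mass to the
        # taxon of its best-hit reference gene
        if c:
            per_read = 1.0 / (l_kb * per_million)
            taxa = sub["sseqid"].map(lambda g: db.gene_taxon(g))
            for tax, n in taxa.value_counts().items():
                res.taxon_breakdown[(fam, tax)] = n * per_read
    return res


def attribute_taxa(
    hits: pd.DataFrame, db: GeneDatabase, total_reads: int,
    families: tuple[str, ...] | list[str], sample_id: str = "",
) -> dict[tuple[str, str], float]:
    """(family, taxon) → RPKM map; shares sum to the family totals."""
    return quantify_family_rpkm(hits, db, total_reads, families, sample_id).taxon_breakdown


def _profile(
    hits: pd.DataFrame,
    db: GeneDatabase,
    total_reads: int,
    families: tuple[str, ...],
    min_identity: float,
    min_aln_len: int = MIN_ALN_LEN,
    max_evalue: float = MAX_EVALUE,
    sample_id: str = "",
) -> QuantResult:
    kept = filter_hits(hits, 0.0, 0, max_evalue)  # E-value gate (aligner level)
    kept = select_top_hit(kept)
    kept = filter_hits(kept, min_identity, min_aln_len, max_evalue)
    return quantify_family_rpkm(kept, db, total_reads, families, sample_id)


def butyrate_profile(
    hits: pd.DataFrame, db: GeneDatabase, total_reads: int, sample_id: str = "",
    min_identity: float = BUTYRATE_MIN_IDENTITY,
    min_aln_len: int = MIN_ALN_LEN, max_evalue: float = MAX_EVALUE,
) -> QuantResult:
    """RPKM of the four terminal butyrate genes (>=90% id, >=25 aa, E<=1e-5)."""
    return _profile(hits, db, total_reads, BUTYRATE_FAMILIES,
                    min_identity, min_aln_len, max_evalue, sample_id)


def bai_profile(
    hits: pd.DataFrame, db: GeneDatabase, total_reads: int, sample_id: str = "",
    min_identity: float = BAI_MIN_IDENTITY,
    min_aln_len: int = MIN_ALN_LEN, max_evalue: float = MAX_EVALUE,
) -> QuantResult:
    """RPKM of the bai operon genes (identity cutoff lowered to >=70%).

    Adds a ``bai`` aggregate: the sum of the eight per-gene RPKM values
    (the operon-level abundance reported for the cluster).
    """
    res = _profile(hits, db, total_reads, BAI_FAMILIES,
                   min_identity, min_aln_len, max_evalue, sample_id)
    res.read_count["bai"] = sum(res.read_count[f] for f in BAI_FAMILIES)
    res.rpkm["bai"] = sum(res.rpkm[f] for f in BAI_FAMILIES)
    return res
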