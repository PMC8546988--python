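"""Curated reference gene databases for targeted metagenome screening.

A database holds amino-acid sequences of the gene families the pipeline
quantifies: the four terminal butyrate-synthesis genes (*but*, *buk*, *ato*,
*4hbt*), the eight genes of the bile-acid-inducible (*bai*) operon, the
strain-variable *Ruminococcus gnavus* mucin glycoside hydrolases (GH29,
GH95, GH33) and the single-copy housekeeping markers (*gyrA*, *recA*,
*rplB*) used for strain-fraction normalization.

Sequences travel as standard amino-acid FASTA; per-gene annotations
(family, source taxon, database name) travel as a tab-separated table keyed
by ``gene_id``.
"""

from __future__ import annotations

import statistics
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

BUTYRATE_FAMILIES = ("but", "buk", "ato", "4hbt")
BAI_FAMILIES = ("baiA", "baiB", "baiCD", "baiE", "baiF", "baiG", "baiH", "baiI")
GH_FAMILIES = ("GH29", "GH95", "GH33")
HOUSEKEEPING_FAMILIES = ("gyrA", "recA", "rplB")

#: Controlled vocabulary of gene family symbols.
KNOWN_FAMILIES = frozenset(
    BUTYRATE_FAMILIES + BAI_FAMILIES + GH_FAMILIES + HOUSEKEEPING_FAMILIES
)

# 20 canonical residues plus X for ambiguity, and * for a trailing stop.
_AA_ALPHABET = frozenset("ACDEFGHIKLMNPQRSTVWYX*")

_ANNOTATION_COLUMNS = ["gene_id", "family", "taxon", "db_name"]


@dataclass(frozen=True)
class ReferenceGene:
    """One curated database entry (an amino-acid gene sequence)."""

    gene_id: str
    sequence: str
    family: str
    taxon: str
    db_name: str = ""

    def __post_init__(self) -> None:
        bad = set(self.sequence.upper()) - _AA_ALPHABET
        if bad:
            raise ValueError(
                f"gene {self.gene_id!r}: non-amino-acid characters {sorted(bad)}"
            )
        if not self.sequence:
            raise ValueError(f"gene {self.gene_id!r}: empty sequence")
        if self.family not in KNOWN_FAMILIES:
            raise ValueError(
                f"gene {self.gene_id!r}: unknown family {self.family!r}"
            )

    @property
    def length_aa(self) -> int:
        """Gene length in residues (stops excluded)."""
        return len(self.sequence.rstrip("*"))


@dataclass
class GeneDatabase:
    """A collection of :class:`ReferenceGene` with per-family length medians."""

    genes: dict[str, ReferenceGene] = field(default_factory=dict)

    @classmethod
    def from_genes(cls, genes: Iterable[ReferenceGene]) -> "GeneDatabase":
        db = cls()
        for g in genes:
            db.add(g)
        return db

    def add(self, gene: ReferenceGene) -> None:
        if gene.gene_id in self.genes:
            raise ValueError(f"duplicate gene_id {gene.gene_id!r}")
        self.genes[gene.gene_id] = gene

    def __len__(self) -> int:
        return len(self.genes)

    def __contains__(self, gene_id: str) -> bool:
        return gene_id in self.genes

    def __getitem__(self, gene_id: str) -> ReferenceGene:
        return self.genes[gene_id]

    @property
    def families(self) -> set[str]:
        return {g.family for g in self.genes.values()}

    def members(self, family: str) -> list[ReferenceGene]:
        return [g for g in self.genes.values() if g.family == family]

    @property
    def family_median_length_aa(self) -> dict[str, float]:
        """Median member length per family, recomputed on access.

        For even member counts the median is the mean of the two central
        order statistics. Families with no members are absent.
        """
        out: dict[str, float] = {}
        for fam in sorted(self.families):
            out[fam] = statistics.median(g.length_aa for g in self.members(fam))
        return out

    def gene_family(self, gene_id: str) -> str:
        try:
            return self.genes[gene_id].family
        except KeyError:
            raise KeyError(f"gene_id {gene_id!r} not in database") from None

    def gene_taxon(self, gene_id: str) -> str:
        try:
            return self.genes[gene_id].taxon
        except KeyError:
            raise KeyError(f"gene_id {gene_id!r} not in database") from None


def median_family_length(db: GeneDatabase, family: str) -> float:
    """Median reference length (aa) of a family's members.

    Raises ``KeyError`` when the family has no members in ``db``.
    """
    members = db.members(family)
    if not members:
        raise KeyError(f"family {family!r} not present in database")
    return statistics.median(g.length_aa for g in members)


def load_database(fasta_path: str | Path, annotation_path: str | Path) -> GeneDatabase:
    """Read a reference database from FASTA + annotation TSV.

    The annotation table must have columns gene_id, family, taxon, db_name
    (extra columns are ignored). Every FASTA record id must resolve to an
    annotation row; duplicates, missing annotations and non-amino-acid
    characters are hard errors.
    """
    ann = pd.read_csv(annotation_path, sep="\t", dtype=str)
    missing_cols = [c for c in _ANNOTATION_COLUMNS if c not in ann.columns]
    if missing_cols:
        raise ValueError(f"annotation table missing columns: {missing_cols}")
    if ann["gene_id"].duplicated().any():
        dups = ann.loc[ann["gene_id"].duplicated(), "gene_id"].tolist()
        raise ValueError(f"duplicate gene_id in annotation table: {dups}")
    ann = ann.set_index("gene_id")

    records = list(SeqIO.parse(str(fasta_path), "fasta"))
    if not records:
        raise ValueError(f"no records in FASTA {fasta_path}")

    db = GeneDatabase()
    for rec in records:
        if rec.id not in ann.index:
            raise ValueError(f"FASTA record {rec.id!r} has no annotation row")
        row = ann.loc[rec.id]
        db.add(
            ReferenceGene(
                gene_id=rec.id,
                sequence=str(rec.seq).upper(),
                family=row["family"],
                taxon=row["taxon"],
                db_name=row.get("db_name", "") or "",
            )
        )
    return db


def write_database(
    db: GeneDatabase, fasta_path: str | Path, annotation_path: str | Path
) -> None:
    """Write FASTA (60-column wrap) and the annotation TSV."""
    records = [
        SeqRecord(Seq(g.sequence), id=g.gene_id, description="")
        for g in db.genes.values()
    ]
    with open(fasta_path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=60)
        writer.write_file(records)
    rows = [
        {"gene_id": g.gene_id, "family": g.family, "taxon": g.taxon, "db_name": g.db_name}
        for g in db.genes.values()
    ]
    pd.DataFrame(rows, columns=_ANNOTATION_COLUMNS).to_csv(
        annotation_path, sep="\t", index=False
    )
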