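"""R. gnavus strain fractions from marker-normalized GH abundance.

The fraction of *R. gnavus* strains carrying a mucin glycoside hydrolase
(GH29, GH95 or GH33) is estimated as the length-normalized GH read count
over the length-normalized count of a single-copy housekeeping marker:

    F_GH = 100 × (c_GH / L_GH) / (c_gyrA / L_gyrA)

GH reads are filtered at >=90% identity and >=25 aa alignment;
housekeeping reads at >=97% identity, counting only closely related
strains. Lengths are each reference gene's own length (the references are
single sequences from one strain). Samples with fewer than 5 gyrA reads
are excluded — the marker coverage is too low to normalize against — and
propagate downstream as missing values, never zeros.

Fractions above 100% are possible (multi-copy GH, cross-mapping) and are
reported as computed with a flag rather than truncated.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import pandas as pd

from .quantify import MAX_EVALUE, MIN_ALN_LEN, filter_hits, select_top_hit
from .reference_db import GH_FAMILIES, HOUSEKEEPING_FAMILIES, GeneDatabase

GH_MIN_IDENTITY = 90.0
HK_MIN_IDENTITY = 97.0
MIN_GYRA_READS = 5


@dataclass
class StrainFractionResult:
    sample_id: str
    gh_family: str
    fraction_percent: float | None  # None when excluded
    gyrA_read_count: int
    excluded: bool
    over_100: bool = False

    def to_row(self) -> dict:
        return {
            "sample_id": self.sample_id,
            "gh_family": self.gh_family,
            "fraction_percent": self.fraction_percent,
            "gyrA_read_count": self.gyrA_read_count,
            "excluded": self.excluded,
        }


def _normalized_abundance(
    hits: pd.DataFrame, db: GeneDatabase, family: str,
    min_identity: float, min_aln_len: int, max_evalue: float,
) -> tuple[float, int]:
    """Sum over the family's genes of read count / gene length (aa)."""
    members = db.members(family)
    if not members:
        raise KeyError(f"family {family!r} absent from database")
    kept = filter_hits(hits, 0.0, 0, max_evalue)
    kept = select_top_hit(kept)
    kept = filter_hits(kept, min_identity, min_aln_len, max_evalue)
    total, count = 0.0, 0
    for g in members:
        c = int((kept["sseqid"] == g.gene_id).sum())
        count += c
        total += c / g.length_aa
    return total, count


def estimate_fraction(
    hits: pd.DataFrame,
    db: GeneDatabase,
    gh_family: str,
    sample_id: str = "",
    min_identity_gh: float = GH_MIN_IDENTITY,
    min_identity_hk: float = HK_MIN_IDENTITY,
    min_gyrA_reads: int = MIN_GYRA_READS,
    min_aln_len: int = MIN_ALN_LEN,
    max_evalue: float = MAX_EVALUE,
) -> StrainFractionResult:
    """Single-marker (gyrA) strain-fraction estimate for one GH family."""
    if gh_family not in GH_FAMILIES:
        raise KeyError(f"{gh_family!r} is not a recognized GH family")
    gh_norm, _ = _normalized_abundance(
        hits, db, gh_family, min_identity_gh, min_aln_len, max_evalue
    )
    gyrA_norm, gyrA_count = _normalized_abundance(
        hits, db, "gyrA", min_identity_hk, min_aln_len, max_evalue
    )
    if gyrA_count < min_gyrA_reads:
        return StrainFractionResult(sample_id, gh_family, None, gyrA_count, True)
    frac = 100.0 * gh_norm / gyrA_norm
    if frac > 100.0:
        warnings.warn(
            f"{sample_id or 'sample'}/{gh_family}: fraction {frac:.1f}% exceeds "
            "100% (multi-copy GH or cross-mapping); reported as computed"
        )
    return StrainFractionResult(
        sample_id, gh_family, frac, gyrA_count, False, over_100=frac > 100.0
    )


def estimate_fraction_multimarker(
    hits: pd.DataFrame,
    db: GeneDatabase,
    gh_family: str,
    sample_id: str = "",
    min_identity_gh: float = GH_MIN_IDENTITY,
    min_identity_hk: float = HK_MIN_IDENTITY,
    min_gyrA_reads: int = MIN_GYRA_READS,
    min_aln_len: int = MIN_ALN_LEN,
    max_evalue: float = MAX_EVALUE,
) -> StrainFractionResult:
    """Three-marker variant: denominator is the mean of the gyrA, recA and
    rplB length-normalized abundances. The single-marker gyrA estimator is
    the default; this is the documented alternative."""
    if gh_family not in GH_FAMILIES:
        raise KeyError(f"{gh_family!r} is not a recognized GH family")
    gh_norm, _ = _normalized_abundance(
        hits, db, gh_family, min_identity_gh, min_aln_len, max_evalue
    )
    marker_norms = []
    gyrA_count = 0
    for fam in HOUSEKEEPING_FAMILIES:
        norm, count = _normalized_abundance(
            hits, db, fam, min_identity_hk, min_aln_len, max_evalue
        )
        marker_norms.append(norm)
        if fam == "gyrA":
            gyrA_count = count
    denom = sum(marker_norms) / len(marker_norms)
    if gyrA_count < min_gyrA_reads or denom == 0.0:
        return StrainFractionResult(sample_id, gh_family, None, gyrA_count, True)
    frac = 100.0 * gh_norm / denom
    return StrainFractionResult(
        sample_id, gh_family, frac, gyrA_count, False, over_100=frac > 100.0
    )


def strain_fraction_table(results: list[StrainFractionResult]) -> pd.DataFrame:
    """Tidy TSV-ready table; excluded samples carry NaN fractions."""
    return pd.DataFrame([r.to_row() for r in results])
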