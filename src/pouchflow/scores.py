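"""Composite functional scores and abundance-table post-processing.

Houses the features-by-samples :class:`AbundanceTable` container, the
normalization and filtering rules applied to profiling outputs (CPM
total-sum scaling, species prevalence/abundance filter, cross-cohort
feature intersection) and the two composite community scores: mucin
degradation potential (sum of seven mucin-active glycoside hydrolase ECs)
and the combined oxidative-stress response score (sum of seven
oxygen-detoxifying enzyme ECs).

Stratified tables use the ``FEATURE|g__Genus.s__species`` row-id dialect;
an unstratified row's value equals the sum of its stratified rows.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

VALID_UNITS = ("relative_percent", "CPM", "RPKM")


def _load_ec_sets() -> dict[str, list[str]]:
    with resources.files("pouchflow.data").joinpath("ec_sets.yaml").open() as fh:
        return yaml.safe_load(fh)


_EC_SETS = _load_ec_sets()
MUCIN_ECS: tuple[str, ...] = tuple(_EC_SETS["mucin_degradation"])
OXIDATIVE_ECS: tuple[str, ...] = tuple(_EC_SETS["oxidative_stress"])


@dataclass
class AbundanceTable:
    """Non-negative features × samples matrix with a declared unit."""

    data: pd.DataFrame
    unit: str = "CPM"

    def __post_init__(self) -> None:
        if self.unit not in VALID_UNITS:
            raise ValueError(f"unit must be one of {VALID_UNITS}, got {self.unit!r}")
        if (self.data.values < 0).any():
            raise ValueError("abundance values must be non-negative")

    @property
    def features(self) -> list[str]:
        return list(self.data.index)

    @property
    def samples(self) -> list[str]:
        return list(self.data.columns)

    @property
    def is_stratified(self) -> bool:
        return any("|" in str(f) for f in self.data.index)

    def unstratified(self) -> "AbundanceTable":
        """Drop stratified (``feature|taxon``) rows."""
        keep = [f for f in self.data.index if "|" not in str(f)]
        return AbundanceTable(self.data.loc[keep], unit=self.unit)

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write(f"# unit: {self.unit}\n")
            self.data.to_csv(fh, sep="\t", index_label="feature")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "AbundanceTable":
        unit = "CPM"
        with open(path) as fh:
            first = fh.readline()
            if first.startswith("# unit:"):
                unit = first.split(":", 1)[1].strip()
            else:
                fh.seek(0)
            df = pd.read_csv(fh, sep="\t", index_col="feature")
        df.index.name = None
        return cls(df, unit=unit)


def cpm_normalize(table: AbundanceTable | pd.DataFrame) -> AbundanceTable:
    """Total-sum scale every sample column to 10^6 (copies per million)."""
    df = table.data if isinstance(table, AbundanceTable) else table
    sums = df.sum(axis=0)
    zero = sums[sums <= 0]
    if len(zero):
        raise ValueError(f"all-zero sample column(s): {list(zero.index)}")
    return AbundanceTable(df / sums * 1e6, unit="CPM")


def filter_species_table(
    table: AbundanceTable,
    min_prevalence: float = 5.0,
    min_abundance: float = 0.1,
    rule: str = "and",
) -> AbundanceTable:
    """Remove rare species from a relative-abundance (%) table.

    Default (``rule="and"``): a species is removed only when it is present
    in fewer than ``min_prevalence`` % of samples AND never reaches
    ``min_abundance`` % in any sample — the conservative reading of the
    removal rule. ``rule="or"`` removes a species failing either clause.
    Retained rows are unchanged (no renormalization).
    """
    if table.unit != "relative_percent":
        raise ValueError("species filter expects a relative_percent table")
    df = table.data
    prevalence = (df > 0).mean(axis=1) * 100.0
    max_abund = df.max(axis=1)
    low_prev = prevalence < min_prevalence
    low_abund = max_abund < min_abundance
    if rule == "and":
        remove = low_prev & low_abund
    elif rule == "or":
        remove = low_prev | low_abund
    else:
        raise ValueError(f"rule must be 'and' or 'or', got {rule!r}")
    return AbundanceTable(df.loc[~remove], unit=table.unit)


def intersect_features(tables: list[AbundanceTable]) -> list[AbundanceTable]:
    """Restrict each table to the features common to all of them.

    Feature order follows the first table; sample columns are untouched.
    """
    if len(tables) < 2:
        raise ValueError("need >=2 tables to intersect")
    common = set(tables[0].features)
    for t in tables[1:]:
        common &= set(t.features)
    if not common:
        raise ValueError("feature intersection is empty")
    order = [f for f in tables[0].features if f in common]
    return [AbundanceTable(t.data.loc[order], unit=t.unit) for t in tables]


def _composite_score(
    table: AbundanceTable, ec_set: tuple[str, ...], name: str
) -> pd.Series:
    df = table.unstratified().data
    present = [ec for ec in ec_set if ec in df.index]
    missing = [ec for ec in ec_set if ec not in df.index]
    if missing:
        warnings.warn(
            f"{name}: {len(missing)} configured feature(s) absent, "
            f"contributing 0: {missing}"
        )
    if not present:
        return pd.Series(0.0, index=df.columns, name=name)
    score = df.loc[present].sum(axis=0)
    score.name = name
    return score


def mucin_degradation_score(ec_table: AbundanceTable) -> pd.Series:
    """Per-sample community mucin degradation potential.

    Sum of the seven functionally characterized mucin-active glycoside
    hydrolase ECs (O-GlcNAcase, sialidase, beta-galactosidase, two
    N-acetylhexosaminidases, fucosidase, hexosaminidase). Missing ECs
    contribute 0 with a warning.
    """
    return _composite_score(ec_table, MUCIN_ECS, "mucin_degradation")


def oxidative_stress_score(enzyme_table: AbundanceTable) -> pd.Series:
    """Per-sample combined oxidative-stress response score (7 enzymes)."""
    return _composite_score(enzyme_table, OXIDATIVE_ECS, "oxidative_stress")


def score_contributions(
    table: AbundanceTable, ec_set: tuple[str, ...] | None = None
) -> pd.DataFrame:
    """Per-taxon contribution matrix (taxa × samples) of a composite score.

    Operates on the stratified rows (``EC|taxon``); the column sums equal
    the unstratified score when the table's stratified rows are complete.
    """
    if ec_set is None:
        ec_set = MUCIN_ECS
    df = table.data
    rows = []
    for f in df.index:
        f = str(f)
        if "|" not in f:
            continue
        feat, taxon = f.split("|", 1)
        if feat in ec_set:
            rows.append((taxon, f))
    if not rows:
        raise ValueError("table has no stratified rows for the requested ECs")
    parts = {}
    for taxon, f in rows:
        parts.setdefault(taxon, []).append(f)
    out = pd.DataFrame(
        {taxon: df.loc[fs].sum(axis=0) for taxon, fs in parts.items()}
    ).T
    return out.loc[sorted(out.index)]
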