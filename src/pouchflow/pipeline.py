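"""End-to-end orchestration: simulate → quantify → scores → ecology →
differential abundance → classify, from a single validated config.

Each stage writes into its own subdirectory of the run directory and drops
a ``_done.json`` marker; rerunning regenerates only stages whose outputs
are missing, plus their dependents. A manifest records the config, its
hash and the package version, so a rerun with the same config is
byte-identical for deterministic stages.
"""

from __future__ import annotations

import hashlib
import json
import logging
import shutil
from pathlib import Path

import numpy as np
import pandas as pd
from pydantic import BaseModel, ConfigDict, Field

from . import __version__
from .classify import GBTParams, average_by_subject, cross_validate, rank_and_select
from .differential import fit_feature_models, transform_abundance
from .ecology import bray_curtis, pcoa, permanova, shannon, spearman
from .quantify import bai_profile, butyrate_profile
from .reference_db import GH_FAMILIES, write_database
from .scores import (
    cpm_normalize,
    filter_species_table,
    mucin_degradation_score,
    oxidative_stress_score,
)
from .strainfrac import estimate_fraction, strain_fraction_table
from .synthetic import (
    SimulationConfig,
    make_toy_database,
    simulate_cohort,
    simulate_feature_tables,
    simulate_hits,
    write_hit_table,
)

log = logging.getLogger("pouchflow")

_forbid = ConfigDict(extra="forbid")


class SimulateBlock(BaseModel):
    model_config = _forbid
    n_normal_pouch: int = 35
    n_pouchitis: int = 34
    mean_samples_per_subject: float = 3.0
    depth: int = 1_000_000
    separability: float = 1.0


class ThresholdBlock(BaseModel):
    model_config = _forbid
    butyrate_identity: float = 90.0
    bai_identity: float = 70.0
    aln_len: int = 25
    evalue: float = 1e-5
    hk_identity: float = 97.0
    min_gyrA: int = 5


class NormalizationBlock(BaseModel):
    model_config = _forbid
    prevalence: float = 5.0   # %
    abundance: float = 0.1    # %


class StatisticsBlock(BaseModel):
    model_config = _forbid
    permutations: int = 999
    fdr_level: float = 0.1


class ClassifierBlock(BaseModel):
    model_config = _forbid
    k: int = 5
    repeats: int = 100
    top_k: int = 50
    colsample_bytree: float = 0.5
    with_calprotectin: bool = False


class RunConfig(BaseModel):
    model_config = _forbid
    seed: int = 0
    simulate: SimulateBlock = Field(default_factory=SimulateBlock)
    thresholds: ThresholdBlock = Field(default_factory=ThresholdBlock)
    normalization: NormalizationBlock = Field(default_factory=NormalizationBlock)
    statistics: StatisticsBlock = Field(default_factory=StatisticsBlock)
    classifier: ClassifierBlock = Field(default_factory=ClassifierBlock)

    def hash(self) -> str:
        blob = json.dumps(self.model_dump(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls.model_validate(raw)


STAGES = ["simulate", "quant", "strainfrac", "scores", "ecology", "diff", "classify"]
_DEPS = {
    "simulate": [],
    "quant": ["simulate"],
    "strainfrac": ["simulate"],
    "scores": ["simulate"],
    "ecology": ["scores"],
    "diff": ["simulate"],
    "classify": ["simulate"],
}


def _sim_config(config: RunConfig) -> SimulationConfig:
    return SimulationConfig(
        n_subjects={
            "normal_pouch": config.simulate.n_normal_pouch,
            "pouchitis": config.simulate.n_pouchitis,
        },
        mean_samples_per_subject=config.simulate.mean_samples_per_subject,
        depth=config.simulate.depth,
        separability=config.simulate.separability,
        seed=config.seed,
    )


def _done(stage_dir: Path, payload: dict | None = None) -> None:
    (stage_dir / "_done.json").write_text(json.dumps(payload or {}, indent=2))


def _is_done(stage_dir: Path) -> bool:
    return (stage_dir / "_done.json").exists()


def run_pipeline(config: RunConfig, outdir: str | Path, force: bool = False) -> Path:
    """Run all stages into ``outdir``; returns the run directory path."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    sim = _sim_config(config)

    manifest = {
        "config": config.model_dump(),
        "config_hash": config.hash(),
        "seed": config.seed,
        "version": __version__,
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))

    reran: set[str] = set()
    for stage in STAGES:
        stage_dir = outdir / stage
        needs = force or not _is_done(stage_dir) or any(d in reran for d in _DEPS[stage])
        if not needs:
            log.info("stage %s: up to date, skipping", stage)
            continue
        if stage_dir.exists():
            shutil.rmtree(stage_dir)
        stage_dir.mkdir(parents=True)
        log.info("stage %s: running", stage)
        _RUNNERS[stage](config, sim, outdir, stage_dir)
        reran.add(stage)
    return outdir


# --- stage runners ----------------------------------------------------------

def _run_simulate(config: RunConfig, sim: SimulationConfig, outdir: Path, d: Path) -> None:
    db = make_toy_database(seed=config.seed)
    write_database(db, d / "reference.faa", d / "reference_annotation.tsv")
    truths, metadata = simulate_cohort(sim)
    metadata.to_csv(d / "metadata.tsv", sep="\t")
    hits_dir = d / "hits"
    hits_dir.mkdir()
    for t in truths:
        hits, _ = simulate_hits(t, db, sim)
        write_hit_table(hits, hits_dir / f"{t.sample_id}.tsv")
    tables = simulate_feature_tables(truths, sim)
    for kind, tab in tables.items():
        tab.to_tsv(d / f"{kind}.tsv")
    truth_rows = pd.DataFrame([
        {"sample_id": t.sample_id, "phenotype": t.phenotype,
         "latent_dysbiosis": t.latent_dysbiosis,
         **{f"carrier_{g}": f for g, f in t.gh_carrier_fraction.items()}}
        for t in truths
    ])
    truth_rows.to_csv(d / "truth.tsv", sep="\t", index=False)
    _done(d, {"n_samples": len(truths)})


def _load_sim(outdir: Path):
    from .reference_db import load_database
    from .synthetic import read_hit_table

    d = outdir / "simulate"
    db = load_database(d / "reference.faa", d / "reference_annotation.tsv")
    metadata = pd.read_csv(d / "metadata.tsv", sep="\t", index_col="sample_id")
    hits = {
        p.stem: read_hit_table(p) for p in sorted((d / "hits").glob("*.tsv"))
    }
    return db, metadata, hits


def _run_quant(config: RunConfig, sim: SimulationConfig, outdir: Path, d: Path) -> None:
    db, metadata, hits = _load_sim(outdir)
    th = config.thresholds
    but_rows, bai_rows, taxa_rows = [], [], []
    for sid, h in hits.items():
        n = int(metadata.loc[sid, "total_reads"])
        but = butyrate_profile(h, db, n, sample_id=sid,
                               min_identity=th.butyrate_identity,
                               min_aln_len=th.aln_len, max_evalue=th.evalue)
        bai = bai_profile(h, db, n, sample_id=sid,
                          min_identity=th.bai_identity,
                          min_aln_len=th.aln_len, max_evalue=th.evalue)
        but_rows.append(but.to_frame())
        bai_rows.append(bai.to_frame())
        taxa_rows.append(but.taxa_frame())
    pd.concat(but_rows).to_csv(d / "butyrate_rpkm.tsv", sep="\t", index=False)
    pd.concat(bai_rows).to_csv(d / "bai_rpkm.tsv", sep="\t", index=False)
    taxa_rows = [t for t in taxa_rows if not t.empty] or taxa_rows[:1]
    pd.concat(taxa_rows).to_csv(d / "butyrate_taxa_rpkm.tsv", sep="\t", index=False)
    _done(d)


def _run_strainfrac(config: RunConfig, sim: SimulationConfig, outdir: Path, d: Path) -> None:
    db, metadata, hits = _load_sim(outdir)
    th = config.thresholds
    results = []
    for sid, h in hits.items():
        for gh in GH_FAMILIES:
            results.append(estimate_fraction(
                h, db, gh, sample_id=sid,
                min_identity_hk=th.hk_identity,
                min_gyrA_reads=th.min_gyrA,
                min_aln_len=th.aln_len, max_evalue=th.evalue,
            ))
    strain_fraction_table(results).to_csv(d / "strain_fractions.tsv", sep="\t", index=False)
    _done(d)


def _run_scores(config: RunConfig, sim: SimulationConfig, outdir: Path, d: Path) -> None:
    from .scores import AbundanceTable

    sim_dir = outdir / "simulate"
    species = AbundanceTable.from_tsv(sim_dir / "species.tsv")
    enzymes = AbundanceTable.from_tsv(sim_dir / "enzymes.tsv")
    nb = config.normalization
    filtered = filter_species_table(species, nb.prevalence, nb.abundance)
    filtered.to_tsv(d / "species_filtered.tsv")
    enzymes_cpm = cpm_normalize(enzymes)
    scores = pd.DataFrame({
        "mucin_degradation": mucin_degradation_score(enzymes_cpm),
        "oxidative_stress": oxidative_stress_score(enzymes_cpm),
    })
    scores.to_csv(d / "community_scores.tsv", sep="\t", index_label="sample_id")
    _done(d)


def _run_ecology(config: RunConfig, sim: SimulationConfig, outdir: Path, d: Path) -> None:
    from .scores import AbundanceTable

    species = AbundanceTable.from_tsv(outdir / "scores" / "species_filtered.tsv")
    metadata = pd.read_csv(outdir / "simulate" / "metadata.tsv", sep="\t",
                           index_col="sample_id")
    alpha = pd.Series(
        {s: shannon(species.data[s]) for s in species.samples}, name="shannon"
    )
    alpha.to_csv(d / "shannon.tsv", sep="\t", index_label="sample_id")
    dm = bray_curtis(species.data)
    ordi = pcoa(dm)
    ordi.coordinates.to_csv(d / "pcoa_coordinates.tsv", sep="\t",
                            index_label="sample_id")
    pd.DataFrame({"eigenvalue": ordi.eigenvalues}).to_csv(
        d / "pcoa_eigenvalues.tsv", sep="\t", index_label="axis")
    perm_rows = []
    for var in ["phenotype", "age", "calprotectin"]:
        res = permanova(dm, metadata, var,
                        n_permutations=config.statistics.permutations,
                        seed=config.seed)
        perm_rows.append({"variable": var, "r2": res.r2, "pseudo_f": res.pseudo_f,
                          "p": res.p_value, "permutations": res.n_permutations})
    pd.DataFrame(perm_rows).to_csv(d / "permanova.tsv", sep="\t", index=False)
    axis1 = ordi.coordinates["PC1"].loc[metadata.index]
    sp = spearman(axis1.to_numpy(), metadata["calprotectin"].to_numpy())
    (d / "spearman_axis1_calprotectin.json").write_text(json.dumps(sp, indent=2))
    _done(d)


def _run_diff(config: RunConfig, sim: SimulationConfig, outdir: Path, d: Path) -> None:
    from .scores import AbundanceTable

    species = AbundanceTable.from_tsv(outdir / "simulate" / "species.tsv")
    metadata = pd.read_csv(outdir / "simulate" / "metadata.tsv", sep="\t",
                           index_col="sample_id")
    # the demo cohort has no healthy arm; use normal pouch as reference
    ref = "healthy" if "healthy" in set(metadata["phenotype"]) else "normal_pouch"
    transformed = transform_abundance(species.data)
    res = fit_feature_models(transformed, metadata, reference=ref)
    res.to_csv(d / "differential_abundance.tsv", sep="\t", index=False)
    _done(d)


def _run_classify(config: RunConfig, sim: SimulationConfig, outdir: Path, d: Path) -> None:
    from .scores import AbundanceTable

    species = AbundanceTable.from_tsv(outdir / "simulate" / "species.tsv")
    metadata = pd.read_csv(outdir / "simulate" / "metadata.tsv", sep="\t",
                           index_col="sample_id")
    cb = config.classifier
    X, y = average_by_subject(species.data, metadata,
                              with_calprotectin=cb.with_calprotectin)
    params = GBTParams(colsample_bytree=cb.colsample_bytree)
    report = cross_validate(X, y, params, k=cb.k, repeats=cb.repeats,
                            seed=config.seed)
    selected = rank_and_select(report, min(cb.top_k, X.shape[1]))
    report.fold_metrics.to_csv(d / "cv_metrics.tsv", sep="\t", index=False)
    report.importances.to_csv(d / "feature_importances.tsv", sep="\t",
                              index_label="feature", header=["importance"])
    summary = {
        "mean_auc": report.mean_auc,
        "sd_auc": report.sd_auc,
        "selected_features": selected,
        "params": report.params.__dict__,
        "seed": config.seed,
    }
    (d / "cv_report.json").write_text(json.dumps(summary, indent=2))
    _done(d)


_RUNNERS = {
    "simulate": _run_simulate,
    "quant": _run_quant,
    "strainfrac": _run_strainfrac,
    "scores": _run_scores,
    "ecology": _run_ecology,
    "diff": _run_diff,
    "classify": _run_classify,
}
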