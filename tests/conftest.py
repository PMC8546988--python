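import numpy as np
import pandas as pd
import pytest

from pouchflow.reference_db import GeneDatabase, ReferenceGene
from pouchflow.synthetic import HIT_COLUMNS, SimulationConfig, make_toy_database


@pytest.fixture(scope="session")
def toy_db():
    return make_toy_database(seed=1)


@pytest.fixture()
def small_config():
    """A small cohort for fast generator tests."""
    return SimulationConfig(
        n_subjects={"normal_pouch": 6, "pouchitis": 6},
        depth=200_000,
        seed=42,
    )


@pytest.fixture()
def hand_db():
    """Tiny database with chosen lengths for hand-computed examples."""
    rng = np.random.default_rng(0)
    aas = np.array(list("ACDEFGHIKLMNPQRSTVWY"))

    def seq(n):
        return "".join(rng.choice(aas, size=n))

    genes = [
        ReferenceGene("but_a", seq(440), "but", "Faecalibacterium_prausnitzii"),
        ReferenceGene("but_b", seq(450), "but", "Roseburia_intestinalis"),
        ReferenceGene("but_c", seq(460), "but", "Eubacterium_rectale"),
        ReferenceGene("buk_a", seq(400), "buk", "Coprococcus_comes"),
        ReferenceGene("ato_a", seq(420), "ato", "Anaerostipes_hadrus"),
        ReferenceGene("hbt_a", seq(430), "4hbt", "Clostridium_scindens"),
        ReferenceGene("baiA_a", seq(500), "baiA", "Clostridium_scindens"),
        ReferenceGene("baiB_a", seq(500), "baiB", "Clostridium_scindens"),
        ReferenceGene("baiCD_a", seq(500), "baiCD", "Clostridium_scindens"),
        ReferenceGene("baiE_a", seq(500), "baiE", "Clostridium_scindens"),
        ReferenceGene("baiF_a", seq(500), "baiF", "Clostridium_scindens"),
        ReferenceGene("baiG_a", seq(500), "baiG", "Clostridium_scindens"),
        ReferenceGene("baiH_a", seq(500), "baiH", "Clostridium_scindens"),
        ReferenceGene("baiI_a", seq(500), "baiI", "Clostridium_scindens"),
        ReferenceGene("GH29_rg", seq(450), "GH29", "Ruminococcus_gnavus"),
        ReferenceGene("GH95_rg", seq(600), "GH95", "Ruminococcus_gnavus"),
        ReferenceGene("GH33_rg", seq(550), "GH33", "Ruminococcus_gnavus"),
        ReferenceGene("gyrA_rg", seq(900), "gyrA", "Ruminococcus_gnavus"),
        ReferenceGene("recA_rg", seq(350), "recA", "Ruminococcus_gnavus"),
        ReferenceGene("rplB_rg", seq(280), "rplB", "Ruminococcus_gnavus"),
    ]
    return GeneDatabase.from_genes(genes)


def make_hits(rows):
    """Build a hit table from (read, gene, pident, length, evalue, bitscore)."""
    out = []
    for read, gene, pident, length, evalue, bitscore in rows:
        out.append(dict(zip(HIT_COLUMNS, [
            read, gene, pident, length, 0, 0, 1, length * 3, 1, length,
            evalue, bitscore,
        ])))
    return pd.DataFrame(out, columns=HIT_COLUMNS)


@pytest.fixture()
def hits_factory():
    return make_hits
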