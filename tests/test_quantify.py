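import numpy as np
import pandas as pd
import pytest

from pouchflow.quantify import (
    bai_profile,
    butyrate_profile,
    filter_hits,
    quantify_family_rpkm,
    select_top_hit,
)
from pouchflow.reference_db import GeneDatabase, ReferenceGene


class TestFilterHits:
    def test_boundaries_inclusive(self, hits_factory):
        hits = hits_factory([
            ("r1", "g", 90.0, 25, 1e-5, 50.0),   # exactly at all thresholds
            ("r2", "g", 89.9, 25, 1e-5, 50.0),   # identity just below
            ("r3", "g", 90.0, 24, 1e-5, 50.0),   # length just below
            ("r4", "g", 90.0, 25, 1.1e-5, 50.0),  # E-value just above
        ])
        kept = filter_hits(hits, 90.0, 25, 1e-5)
        assert list(kept["qseqid"]) == ["r1"]

    def test_negative_threshold_rejected(self, hits_factory):
        hits = hits_factory([("r1", "g", 95.0, 30, 1e-9, 50.0)])
        with pytest.raises(ValueError):
            filter_hits(hits, -1.0, 25, 1e-5)

    def test_simulated_decoys_all_rejected(self, toy_db, small_config):
        """Decoy hits (identity < 90, or high E) never pass the butyrate gate."""
        from pouchflow.synthetic import simulate_cohort, simulate_hits

        truths, _ = simulate_cohort(small_config)
        hits, _ = simulate_hits(truths[0], toy_db, small_config)
        decoys = hits[hits["pident"] < 89.0]
        assert len(decoys) > 0
        assert len(filter_hits(decoys, 90.0, 25, 1e-5)) == 0


class TestSelectTopHit:
    def test_keeps_max_bitscore(self, hits_factory):
        hits = hits_factory([
            ("r1", "g1", 95.0, 30, 1e-9, 50.0),
            ("r1", "g2", 95.0, 30, 1e-9, 80.0),
        ])
        top = select_top_hit(hits)
        assert list(top["sseqid"]) == ["g2"]

    def test_tie_broken_by_evalue_then_gene_id(self, hits_factory):
        hits = hits_factory([
            ("r1", "b1", 95.0, 30, 1e-9, 50.0),
            ("r1", "a1", 95.0, 30, 1e-9, 50.0),
            ("r2", "z1", 95.0, 30, 1e-12, 50.0),
            ("r2", "a9", 95.0, 30, 1e-9, 50.0),
        ])
        top = select_top_hit(hits).set_index("qseqid")["sseqid"]
        assert top["r1"] == "a1"   # full tie: lexicographic gene id
        assert top["r2"] == "z1"   # lower E-value wins
    def test_idempotent_on_unique_reads(self, hits_factory):
        hits = hits_factory([
            ("r1", "g1", 95.0, 30, 1e-9, 50.0),
            ("r2", "g2", 95.0, 30, 1e-9, 60.0),
        ])
        pd.testing.assert_frame_equal(
            select_top_hit(hits).reset_index(drop=True), hits
        )


class TestRpkm:
    def _db_median_500(self):
        return GeneDatabase.from_genes([
            ReferenceGene("g1", "M" * 500, "but", "TaxA"),
        ])

    def test_closed_form(self, hits_factory):
        """30 reads, 500 aa median (1.5 kb), N = 2e6 -> RPKM = 30/(1.5*2) = 10."""
        db = self._db_median_500()
        hits = hits_factory([
            (f"r{i}", "g1", 95.0, 30, 1e-9, 60.0) for i in range(30)
        ])
        res = quantify_family_rpkm(hits, db, 2_000_000, ["but"])
        assert res.rpkm["but"] == pytest.approx(10.0)
        assert res.read_count["but"] == 30

    def test_zero_reads_reported_as_zero(self, hits_factory):
        db = self._db_median_500()
        res = quantify_family_rpkm(hits_factory([]), db, 1_000_000, ["but"])
        assert res.rpkm["but"] == 0.0
        assert res.read_count["but"] == 0

    def test_doubling_n_halves_rpkm(self, hits_factory):
        db = self._db_median_500()
        hits = hits_factory([(f"r{i}", "g1", 95.0, 30, 1e-9, 60.0)
                             for i in range(10)])
        a = quantify_family_rpkm(hits, db, 1_000_000, ["but"]).rpkm["but"]
        b = quantify_family_rpkm(hits, db, 2_000_000, ["but"]).rpkm["but"]
        assert b == pytest.approx(a / 2)

    def test_duplicating_reads_and_n_preserves_rpkm(self, hits_factory):
        db = self._db_median_500()
        rows = [(f"r{i}", "g1", 95.0, 30, 1e-9, 60.0) for i in range(10)]
        dup = rows + [(f"d{i}", "g1", 95.0, 30, 1e-9, 60.0) for i in range(10)]
        a = quantify_family_rpkm(hits_factory(rows), db, 1_000_000, ["but"])
        b = quantify_family_rpkm(hits_factory(dup), db, 2_000_000, ["but"])
        assert a.rpkm["but"] == pytest.approx(b.rpkm["but"])

    def test_invalid_inputs(self, hits_factory):
        db = self._db_median_500()
        hits = hits_factory([("r1", "g1", 95.0, 30, 1e-9, 60.0)])
        with pytest.raises(ValueError):
            quantify_family_rpkm(hits, db, 0, ["but"])
        with pytest.raises(KeyError):
            quantify_family_rpkm(hits, db, 1000, ["baiA"])
        with pytest.raises(KeyError):
            quantify_family_rpkm(
                hits_factory([("r1", "nope", 95.0, 30, 1e-9, 60.0)]),
                db, 1000, ["but"],
            )


class TestAttributeTaxa:
    def _two_taxon_db(self):
        return GeneDatabase.from_genes([
            ReferenceGene("g1", "M" * 500, "but", "TaxA"),
            ReferenceGene("g2", "M" * 500, "but", "TaxB"),
        ])

    def test_single_taxon_gets_all_mass(self, hits_factory):
        db = self._two_taxon_db()
        hits = hits_factory([(f"r{i}", "g1", 95.0, 30, 1e-9, 60.0)
                             for i in range(6)])
        res = quantify_family_rpkm(hits, db, 1_000_000, ["but"])
        assert res.taxon_breakdown[("but", "TaxA")] == pytest.approx(res.rpkm["but"])

    def test_even_split_gives_equal_shares_summing_to_total(self, hits_factory):
        db = self._two_taxon_db()
        rows = [(f"r{i}", "g1", 95.0, 30, 1e-9, 60.0) for i in range(5)]
        rows += [(f"s{i}", "g2", 95.0, 30, 1e-9, 60.0) for i in range(5)]
        res = quantify_family_rpkm(hits_factory(rows), db, 1_000_000, ["but"])
        a = res.taxon_breakdown[("but", "TaxA")]
        b = res.taxon_breakdown[("but", "TaxB")]
        assert a == pytest.approx(b)
        assert a + b == pytest.approx(res.rpkm["but"], abs=1e-9)

    def test_simulated_mixture_shares_recovered(self, hits_factory):
        """A 0.6/0.3/0.1 read mixture over three equal-length taxa."""
        rng = np.random.default_rng(5)
        db = GeneDatabase.from_genes([
            ReferenceGene(f"g{k}", "M" * 500, "but", f"Tax{k}") for k in range(3)
        ])
        probs = [0.6, 0.3, 0.1]
        picks = rng.choice(3, size=5000, p=probs)
        rows = [(f"r{i}", f"g{k}", 95.0, 30, 1e-9, 60.0)
                for i, k in enumerate(picks)]
        res = quantify_family_rpkm(hits_factory(rows), db, 100_000, ["but"])
        total = res.rpkm["but"]
        for k, p in enumerate(probs):
            share = res.taxon_breakdown[("but", f"Tax{k}")] / total
            assert share == pytest.approx(p, abs=0.05)


class TestProfiles:
    def test_bai_threshold_lower_than_butyrate(self, hand_db, hits_factory):
        hits = hits_factory([
            ("r1", "baiA_a", 75.0, 30, 1e-9, 60.0),
            ("r2", "but_a", 75.0, 30, 1e-9, 60.0),
        ])
        bai = bai_profile(hits, hand_db, 1_000_000)
        but = butyrate_profile(hits, hand_db, 1_000_000)
        assert bai.read_count["baiA"] == 1
        assert bai.read_count["bai"] == 1
        assert but.read_count["but"] == 0

    def test_decoy_only_table_gives_all_zero(self, hand_db, hits_factory):
        hits = hits_factory([
            ("r1", "but_a", 60.0, 20, 1e-3, 20.0),
            ("r2", "baiA_a", 55.0, 18, 1e-2, 15.0),
        ])
        assert all(v == 0 for v in butyrate_profile(hits, hand_db, 1e6).rpkm.values())
        assert all(v == 0 for v in bai_profile(hits, hand_db, 1e6).rpkm.values())

    def test_planted_rate_ratio_preserved(self, toy_db):
        """bai planted at ~2x the but rate shows up as ~2x the RPKM."""
        from pouchflow.reference_db import BAI_FAMILIES
        from pouchflow.synthetic import SimulationConfig, simulate_cohort, simulate_hits

        rates = {"pouchitis": {"but": 50.0, "gyrA": 10.0,
                               **{f: 100.0 / 8 for f in BAI_FAMILIES}}}
        cfg = SimulationConfig(
            n_subjects={"pouchitis": 12}, depth=1_000_000, seed=13,
            rates=rates, gh_carrier={"pouchitis": {}},
        )
        truths, _ = simulate_cohort(cfg)
        ratios = []
        for t in truths[:15]:
            hits, n = simulate_hits(t, toy_db, cfg)
            but = butyrate_profile(hits, toy_db, n).rpkm["but"]
            bai = bai_profile(hits, toy_db, n).rpkm["bai"]
            planted = sum(t.gene_copy_rate[f] for f in BAI_FAMILIES) / t.gene_copy_rate["but"]
            if but > 0:
                ratios.append((bai / but) / planted)
        assert np.mean(ratios) == pytest.approx(1.0, abs=0.25)


def _brute_force_pipeline(hits, db, total_reads, families,
                          min_identity, min_aln, max_e):
    """Independent read-by-read oracle for the filter/top-hit/RPKM chain."""
    best = {}
    for _, row in hits.iterrows():
        if row["evalue"] > max_e:
            continue
        key = row["qseqid"]
        cand = best.get(key)
        rank = (-row["bitscore"], row["evalue"], row["sseqid"])
        if cand is None or rank < cand[0]:
            best[key] = (rank, row)
    counts = {f: 0 for f in families}
    for _, row in best.values():
        if row["pident"] >= min_identity and row["length"] >= min_aln:
            fam = db.gene_family(row["sseqid"])
            if fam in counts:
                counts[fam] += 1
    import statistics
    out = {}
    for f in families:
        med = statistics.median(g.length_aa for g in db.members(f))
        out[f] = counts[f] / (3 * med / 1000 * total_reads / 1e6)
    return out


def test_oracle_equivalence_on_simulated_hits(toy_db, small_config):
    """The vectorized pipeline equals a read-by-read enumeration oracle."""
    from pouchflow.synthetic import simulate_cohort, simulate_hits

    truths, _ = simulate_cohort(small_config)
    hits, n = simulate_hits(truths[0], toy_db, small_config)
    hits = hits.head(100)
    res = butyrate_profile(hits, toy_db, n)
    expect = _brute_force_pipeline(hits, toy_db, n, ["but", "buk", "ato", "4hbt"],
                                   90.0, 25, 1e-5)
    for fam, v in expect.items():
        assert res.rpkm[fam] == pytest.approx(v, abs=1e-12)
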