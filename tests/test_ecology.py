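import itertools
import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps
from skbio import DistanceMatrix

from pouchflow.ecology import (
    bray_curtis,
    kruskal_dunn,
    pcoa,
    permanova,
    shannon,
    spearman,
)


class TestShannon:
    @pytest.mark.parametrize(
        "vec,expected",
        [
            ([1, 1, 1, 1], math.log(4)),
            ([5, 0, 0], 0.0),
            ([0.5, 0.25, 0.25], 1.0397207708399179),
        ],
    )
    def test_known_values(self, vec, expected):
        assert shannon(vec) == pytest.approx(expected, abs=1e-10)

    def test_all_zero_rejected(self):
        with pytest.raises(ValueError):
            shannon([0, 0, 0])

    def test_matches_entropy_oracle(self):
        rng = np.random.default_rng(0)
        for _ in range(10):
            x = rng.uniform(0, 5, size=8)
            p = x / x.sum()
            assert shannon(x) == pytest.approx(sps.entropy(p), abs=1e-12)


class TestBrayCurtis:
    def test_known_values(self):
        df = pd.DataFrame({"a": [2.0, 2.0], "b": [1.0, 3.0]})
        assert bray_curtis(df)["a", "b"] == pytest.approx(0.25)

    def test_identical_samples_zero(self):
        df = pd.DataFrame({"a": [1.0, 2.0], "b": [1.0, 2.0]})
        assert bray_curtis(df)["a", "b"] == 0.0

    def test_disjoint_supports_one(self):
        df = pd.DataFrame({"a": [1.0, 0.0], "b": [0.0, 3.0]})
        assert bray_curtis(df)["a", "b"] == 1.0

    def test_symmetric_bounded_and_scale_dependent(self):
        rng = np.random.default_rng(1)
        df = pd.DataFrame(rng.uniform(0, 10, size=(6, 5)),
                          columns=list("abcde"))
        dm = bray_curtis(df)
        m = np.asarray(dm.data)
        assert np.allclose(m, m.T)
        assert (m >= 0).all() and (m <= 1).all()
        assert np.allclose(np.diag(m), 0)
        # doubling one sample changes its distances (not scale-invariant)
        df2 = df.copy()
        df2["a"] = 2 * df2["a"]
        assert bray_curtis(df2)["a", "b"] != pytest.approx(dm["a", "b"])

    def test_matches_scipy_oracle(self):
        from scipy.spatial.distance import braycurtis

        rng = np.random.default_rng(2)
        df = pd.DataFrame(rng.uniform(0, 10, size=(7, 4)), columns=list("wxyz"))
        dm = bray_curtis(df)
        for a, b in itertools.combinations(df.columns, 2):
            assert dm[a, b] == pytest.approx(braycurtis(df[a], df[b]), abs=1e-12)


class TestPcoa:
    def test_collinear_configuration(self):
        d = DistanceMatrix(np.array([[0, 1, 2], [1, 0, 1], [2, 1, 0]], float),
                           ids=list("ABC"))
        o = pcoa(d)
        assert (o.eigenvalues > 1e-10).sum() == 1
        np.testing.assert_allclose(
            o.coordinates["PC1"].to_numpy(), [1.0, 0.0, -1.0], atol=1e-10
        )

    def test_euclidean_round_trip(self):
        """Distances of a 2D point grid are reproduced by the embedding."""
        pts = np.array([(i, j) for i in range(3) for j in range(3)], float)
        from scipy.spatial.distance import pdist, squareform

        d = DistanceMatrix(squareform(pdist(pts)),
                           ids=[f"p{i}" for i in range(len(pts))])
        o = pcoa(d)
        emb = o.coordinates.to_numpy()
        recon = squareform(pdist(emb))
        np.testing.assert_allclose(recon, d.data, atol=1e-8)

    def test_equilateral_has_two_equal_eigenvalues(self):
        d = DistanceMatrix(np.ones((3, 3)) - np.eye(3), ids=list("abc"))
        o = pcoa(d)
        pos = o.eigenvalues[o.eigenvalues > 1e-10]
        assert len(pos) == 2
        assert pos[0] == pytest.approx(pos[1])

    def test_matches_skbio(self):
        """Cross-check coordinates against the scikit-bio implementation."""
        from skbio.stats.ordination import pcoa as skbio_pcoa

        rng = np.random.default_rng(3)
        df = pd.DataFrame(rng.uniform(0, 10, size=(10, 8)),
                          columns=[f"s{i}" for i in range(8)])
        dm = bray_curtis(df)
        ours = pcoa(dm)
        theirs = skbio_pcoa(dm, number_of_dimensions=3)
        for k in range(3):
            a = ours.coordinates.iloc[:, k].to_numpy()
            b = theirs.samples.iloc[:, k].to_numpy()
            assert np.allclose(a, b, atol=1e-8) or np.allclose(a, -b, atol=1e-8)

    def test_too_few_samples_rejected(self):
        d = DistanceMatrix(np.array([[0, 1], [1, 0]], float), ids=list("ab"))
        with pytest.raises(ValueError):
            pcoa(d)


class TestPermanova:
    def _perfect_2plus2(self):
        m = np.ones((4, 4))
        m[np.ix_([0, 1], [0, 1])] = 0
        m[np.ix_([2, 3], [2, 3])] = 0
        np.fill_diagonal(m, 0)
        dm = DistanceMatrix(m, ids=list("abcd"))
        meta = pd.DataFrame({"grp": ["x", "x", "y", "y"]}, index=list("abcd"))
        return dm, meta

    def test_perfect_separation_exact(self):
        dm, meta = self._perfect_2plus2()
        res = permanova(dm, meta, "grp", n_permutations="exact")
        assert res.r2 == pytest.approx(1.0)
        assert res.p_value == pytest.approx(1 / 3)

    def test_matches_skbio_pseudo_f(self):
        from skbio.stats.distance import permanova as skbio_permanova

        rng = np.random.default_rng(4)
        df = pd.DataFrame(rng.uniform(0, 10, size=(12, 10)),
                          columns=[f"s{i}" for i in range(10)])
        dm = bray_curtis(df)
        grouping = pd.Series((["x"] * 5 + ["y"] * 5), index=dm.ids)
        meta = pd.DataFrame({"grp": grouping})
        ours = permanova(dm, meta, "grp", n_permutations=99, seed=1)
        theirs = skbio_permanova(dm, grouping.loc[list(dm.ids)].tolist(),
                                 permutations=99)
        assert ours.pseudo_f == pytest.approx(theirs["test statistic"], rel=1e-9)

    def test_seed_reproducible(self):
        rng = np.random.default_rng(5)
        df = pd.DataFrame(rng.uniform(0, 10, size=(8, 8)),
                          columns=[f"s{i}" for i in range(8)])
        dm = bray_curtis(df)
        meta = pd.DataFrame({"grp": ["x"] * 4 + ["y"] * 4}, index=dm.ids)
        a = permanova(dm, meta, "grp", n_permutations=199, seed=7)
        b = permanova(dm, meta, "grp", n_permutations=199, seed=7)
        assert a.p_value == b.p_value

    def test_numeric_variable_supported(self):
        rng = np.random.default_rng(6)
        df = pd.DataFrame(rng.uniform(0, 10, size=(8, 10)),
                          columns=[f"s{i}" for i in range(10)])
        dm = bray_curtis(df)
        meta = pd.DataFrame({"cal": rng.lognormal(5, 1, size=10)}, index=dm.ids)
        res = permanova(dm, meta, "cal", n_permutations=99, seed=1)
        assert 0 <= res.r2 <= 1

    def test_constant_variable_rejected(self):
        dm, meta = self._perfect_2plus2()
        meta["const"] = 1
        with pytest.raises(ValueError, match="constant"):
            permanova(dm, meta, "const")

    def test_missing_values_listed(self):
        dm, meta = self._perfect_2plus2()
        meta.loc["b", "grp"] = np.nan
        with pytest.raises(ValueError, match="b"):
            permanova(dm, meta, "grp")


def _brute_force_kw(groups_values):
    """Independent tie-corrected Kruskal-Wallis from the rank definition."""
    pooled = np.concatenate(groups_values)
    ranks = sps.rankdata(pooled)
    n = len(pooled)
    h, start = 0.0, 0
    for gv in groups_values:
        r = ranks[start:start + len(gv)]
        start += len(gv)
        h += len(gv) * (r.mean() - (n + 1) / 2) ** 2
    h *= 12.0 / (n * (n + 1))
    _, counts = np.unique(pooled, return_counts=True)
    denom = 1 - ((counts**3 - counts).sum()) / (n**3 - n)
    return h / denom if denom > 0 else 0.0


def _brute_force_dunn_z(groups_values, i, j):
    pooled = np.concatenate(groups_values)
    ranks = sps.rankdata(pooled)
    n = len(pooled)
    bounds = np.cumsum([0] + [len(g) for g in groups_values])
    ri = ranks[bounds[i]:bounds[i + 1]].mean()
    rj = ranks[bounds[j]:bounds[j + 1]].mean()
    _, counts = np.unique(pooled, return_counts=True)
    ties = (counts**3 - counts).sum()
    var = (n * (n + 1) / 12 - ties / (12 * (n - 1))) * (
        1 / len(groups_values[i]) + 1 / len(groups_values[j])
    )
    return (ri - rj) / math.sqrt(var)


class TestKruskalDunn:
    def test_matches_brute_force_and_scipy(self):
        g = [np.array([1.0, 2, 3]), np.array([101.0, 102, 103]),
             np.array([201.0, 202, 203])]
        vals = np.concatenate(g)
        labels = np.repeat(["a", "b", "c"], 3)
        res = kruskal_dunn(vals, labels)
        assert res["H"] == pytest.approx(_brute_force_kw(g))
        assert res["H"] == pytest.approx(sps.kruskal(*g).statistic)

    def test_randomized_against_oracles(self):
        rng = np.random.default_rng(7)
        for _ in range(50):
            sizes = rng.integers(2, 5, size=3)
            g = [np.round(rng.uniform(0, 5, size=s), 1) for s in sizes]
            labels = np.concatenate([[f"g{i}"] * len(gv) for i, gv in enumerate(g)])
            res = kruskal_dunn(np.concatenate(g), labels, adjust="none")
            assert res["H"] == pytest.approx(_brute_force_kw(g), abs=1e-10)
            for (i, j) in [(0, 1), (0, 2), (1, 2)]:
                z = _brute_force_dunn_z(g, i, j)
                assert res["z"][(f"g{i}", f"g{j}")] == pytest.approx(z, abs=1e-10)

    def test_all_tied_gives_h_zero_p_one(self):
        res = kruskal_dunn([5.0] * 6, ["a", "a", "b", "b", "c", "c"])
        assert res["H"] == 0.0
        assert res["p_global"] == 1.0

    def test_null_p_roughly_uniform(self):
        """Under identical group distributions the global p is ~ uniform."""
        rng = np.random.default_rng(8)
        ps = []
        for _ in range(300):
            vals = rng.normal(size=15)
            labels = np.repeat(["a", "b", "c"], 5)
            ps.append(kruskal_dunn(vals, labels)["p_global"])
        assert sps.kstest(ps, "uniform").pvalue > 0.01

    def test_single_group_rejected(self):
        with pytest.raises(ValueError):
            kruskal_dunn([1, 2, 3], ["a", "a", "a"])


class TestSpearman:
    def test_monotone_extremes(self):
        x = [1, 2, 3, 4, 5]
        assert spearman(x, [2, 4, 8, 16, 32])["rho"] == pytest.approx(1.0)
        assert spearman(x, x[::-1])["rho"] == pytest.approx(-1.0)

    def test_hand_ranked_example(self):
        r = spearman([1, 2, 3, 4, 5], [1, 3, 2, 5, 4])
        assert r["rho"] == pytest.approx(0.8)

    def test_matches_scipy_with_ties_and_nans(self):
        rng = np.random.default_rng(9)
        x = np.round(rng.uniform(0, 3, size=30), 1)
        y = np.round(x + rng.normal(0, 1, size=30), 1)
        x[3] = np.nan
        y[7] = np.nan
        ours = spearman(x, y)
        ok = ~(np.isnan(x) | np.isnan(y))
        theirs = sps.spearmanr(x[ok], y[ok])
        assert ours["rho"] == pytest.approx(theirs.statistic, abs=1e-12)
        assert ours["p"] == pytest.approx(theirs.pvalue, rel=1e-6)

    def test_too_few_pairs_rejected(self):
        with pytest.raises(ValueError):
            spearman([1, np.nan, 3], [1, 2, np.nan])
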