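"""Diversity, ordination, variance partitioning and group comparisons.

First-principles implementations of the community-ecology statistics used
to describe the dysbiosis gradient: Shannon diversity (natural log),
Bray-Curtis dissimilarity, principal-coordinate analysis (classical
multidimensional scaling), marginal single-variable PERMANOVA with free
permutations, tie-corrected Kruskal-Wallis with Dunn's pairwise z-tests,
and Spearman rank correlation with pairwise deletion of missing values.

Distance matrices travel in :class:`skbio.DistanceMatrix`; all values are
computed here, not delegated.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from skbio import DistanceMatrix


def shannon(abundances: np.ndarray | pd.Series | list) -> float:
    """Shannon diversity H = -Σ p ln p in nats; 0·ln 0 := 0."""
    x = np.asarray(abundances, dtype=float)
    if (x < 0).any():
        raise ValueError("abundances must be non-negative")
    total = x.sum()
    if total <= 0:
        raise ValueError("all-zero abundance vector")
    p = x[x > 0] / total
    return float(-(p * np.log(p)).sum())


def bray_curtis(table: pd.DataFrame) -> DistanceMatrix:
    """Bray-Curtis dissimilarity between sample columns.

    BC(j,k) = Σ_i |x_ij − x_ik| / Σ_i (x_ij + x_ik), in [0,1]. A pair of
    all-zero samples gets distance 0 with a warning.
    """
    x = table.values.astype(float)
    if (x < 0).any():
        raise ValueError("abundances must be non-negative")
    n = x.shape[1]
    if n < 2:
        raise ValueError("need >=2 samples")
    d = np.zeros((n, n))
    for j in range(n):
        diff = np.abs(x[:, j:j + 1] - x[:, j + 1:]).sum(axis=0)
        tot = (x[:, j:j + 1] + x[:, j + 1:]).sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            row = np.where(tot > 0, diff / np.where(tot > 0, tot, 1.0), 0.0)
        if (tot == 0).any():
            warnings.warn("pair(s) of all-zero samples assigned distance 0")
        d[j, j + 1:] = row
        d[j + 1:, j] = row
    return DistanceMatrix(d, ids=[str(c) for c in table.columns])


@dataclass
class OrdinationResult:
    """PCoA embedding: coordinates, eigenvalues, proportion explained."""

    coordinates: pd.DataFrame  # samples × retained axes
    eigenvalues: np.ndarray    # all eigenvalues, descending (negatives kept)
    proportion_explained: np.ndarray  # over positive eigenvalues only


def pcoa(dm: DistanceMatrix) -> OrdinationResult:
    """Classical multidimensional scaling of a distance matrix.

    Eigendecomposition of the Gower-centered matrix −½ J D² J. Axes with
    negative eigenvalues are dropped from the coordinates but retained in
    the eigenvalue report; proportions explained are over positive
    eigenvalues only (no Cailliez/Lingoes correction). Axis signs are fixed
    so the lexicographically smallest sample id has non-negative
    coordinates, making runs reproducible.
    """
    ids = list(dm.ids)
    n = len(ids)
    if n < 3:
        raise ValueError("need >=3 samples for ordination")
    d2 = np.asarray(dm.data, dtype=float) ** 2
    j = np.eye(n) - np.ones((n, n)) / n
    g = -0.5 * j @ d2 @ j
    evals, evecs = np.linalg.eigh((g + g.T) / 2)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    pos = evals > 1e-10
    coords = evecs[:, pos] * np.sqrt(evals[pos])
    anchor = int(np.argmin(ids))
    for a in range(coords.shape[1]):
        if coords[anchor, a] < 0:
            coords[:, a] = -coords[:, a]
    prop = evals[pos] / evals[pos].sum() if pos.any() else np.array([])
    cols = [f"PC{i + 1}" for i in range(coords.shape[1])]
    return OrdinationResult(
        coordinates=pd.DataFrame(coords, index=ids, columns=cols),
        eigenvalues=evals,
        proportion_explained=prop,
    )


@dataclass
class PermanovaResult:
    variable: str
    r2: float
    pseudo_f: float
    p_value: float
    n_permutations: int | str
    seed: int | None


def _hat_matrix(values: pd.Series) -> tuple[np.ndarray, int]:
    """Projection matrix of [1 | X] and the model degrees of freedom."""
    n = len(values)
    if values.nunique() < 2:
        raise ValueError(f"variable {values.name!r} is constant")
    if pd.api.types.is_numeric_dtype(values) and values.nunique() > 6:
        x = np.column_stack([np.ones(n), values.to_numpy(dtype=float)])
    else:
        dummies = pd.get_dummies(values.astype(str), drop_first=True)
        x = np.column_stack([np.ones(n), dummies.to_numpy(dtype=float)])
    df_model = x.shape[1] - 1
    h = x @ np.linalg.pinv(x)
    return h, df_model


def permanova(
    dm: DistanceMatrix,
    metadata: pd.DataFrame,
    variable: str,
    n_permutations: int | str = 999,
    seed: int | None = 0,
) -> PermanovaResult:
    """Marginal (single-variable) PERMANOVA on a distance matrix.

    R² = tr(H G H)/tr(G) with G the Gower-centered matrix and H the
    variable's hat matrix; pseudo-F uses (df_model, n − df_model − 1).
    Permutations shuffle whole samples. ``n_permutations="exact"``
    enumerates all n! relabelings and reports p = #{F_perm >= F_obs}/n!
    (the identity included); the random scheme reports
    (1 + #{F_perm >= F_obs}) / (1 + B).
    """
    ids = list(dm.ids)
    n = len(ids)
    if n < 4:
        raise ValueError("need >=4 samples")
    missing = [i for i in ids if i not in metadata.index]
    if missing:
        raise ValueError(f"samples missing from metadata: {missing}")
    values = metadata.loc[ids, variable]
    if values.isna().any():
        bad = values.index[values.isna()].tolist()
        raise ValueError(f"missing {variable!r} values for samples: {bad}")

    d2 = np.asarray(dm.data, dtype=float) ** 2
    jc = np.eye(n) - np.ones((n, n)) / n
    g = -0.5 * jc @ d2 @ jc
    h, df_model = _hat_matrix(values)
    tr_g = float(np.trace(g))

    def _f_and_r2(hm: np.ndarray) -> tuple[float, float]:
        ss_model = float(np.sum(hm * g))  # tr(HG), H idempotent symmetric
        ss_resid = tr_g - ss_model
        r2 = ss_model / tr_g if tr_g > 0 else 0.0
        df_resid = n - df_model - 1
        if ss_resid <= 1e-12 * max(tr_g, 1.0):
            return math.inf, r2
        return (ss_model / df_model) / (ss_resid / df_resid), r2

    f_obs, r2 = _f_and_r2(h)

    if n_permutations == "exact":
        count, total = 0, 0
        for perm in itertools.permutations(range(n)):
            p = np.array(perm)
            f_p, _ = _f_and_r2(h[np.ix_(p, p)])
            count += f_p >= f_obs
            total += 1
        p_value = count / total
    else:
        rng = np.random.default_rng(seed)
        count = 0
        for _ in range(int(n_permutations)):
            p = rng.permutation(n)
            f_p, _ = _f_and_r2(h[np.ix_(p, p)])
            count += f_p >= f_obs
        p_value = (1 + count) / (1 + int(n_permutations))

    return PermanovaResult(
        variable=variable, r2=float(r2), pseudo_f=float(f_obs),
        p_value=float(p_value), n_permutations=n_permutations, seed=seed,
    )


def _tie_term(ranks_all: np.ndarray) -> float:
    """Σ (t³ − t) over tie groups of the pooled ranks."""
    _, counts = np.unique(ranks_all, return_counts=True)
    return float((counts.astype(float) ** 3 - counts).sum())


def kruskal_dunn(
    values: np.ndarray | list,
    groups: np.ndarray | list,
    adjust: str = "bh",
) -> dict:
    """Tie-corrected Kruskal-Wallis H with Dunn's pairwise z-tests.

    Returns ``{"H", "p_global", "pairwise"}`` where ``pairwise`` maps
    (group_a, group_b) to the adjusted two-sided p. Pairwise adjustment
    defaults to Benjamini-Hochberg; ``"bonferroni"`` and ``"none"`` are
    available. If every observation is tied, H = 0 and p = 1.
    """
    from .differential import bh_adjust

    v = np.asarray(values, dtype=float)
    g = np.asarray(groups)
    labels = sorted(pd.unique(g).tolist())
    if len(labels) < 2:
        raise ValueError("need >=2 groups")
    n = len(v)
    ranks = sps.rankdata(v)
    tie = _tie_term(ranks)

    r_mean, sizes = {}, {}
    for lab in labels:
        mask = g == lab
        sizes[lab] = int(mask.sum())
        r_mean[lab] = float(ranks[mask].mean())

    h = 12.0 / (n * (n + 1)) * sum(
        sizes[lab] * (r_mean[lab] - (n + 1) / 2) ** 2 for lab in labels
    )
    denom = 1.0 - tie / (n**3 - n) if n**3 - n > 0 else 1.0
    if denom <= 0:  # every observation tied
        h, p_global = 0.0, 1.0
    else:
        h = h / denom
        p_global = float(sps.chi2.sf(h, df=len(labels) - 1))

    pairs = list(itertools.combinations(labels, 2))
    zs, ps = [], []
    var_base = n * (n + 1) / 12.0 - tie / (12.0 * (n - 1))
    for a, b in pairs:
        se = math.sqrt(var_base * (1.0 / sizes[a] + 1.0 / sizes[b]))
        z = (r_mean[a] - r_mean[b]) / se if se > 0 else 0.0
        zs.append(z)
        ps.append(2.0 * sps.norm.sf(abs(z)))
    if adjust == "bh":
        adj = bh_adjust(np.array(ps)) if ps else np.array([])
    elif adjust == "bonferroni":
        adj = np.minimum(np.array(ps) * len(ps), 1.0)
    elif adjust == "none":
        adj = np.array(ps)
    else:
        raise ValueError(f"unknown adjustment {adjust!r}")
    return {
        "H": float(h),
        "p_global": p_global,
        "pairwise": {pair: float(q) for pair, q in zip(pairs, adj)},
        "z": {pair: float(z) for pair, z in zip(pairs, zs)},
    }


def spearman(x, y) -> dict:
    """Spearman rho with a t-approximation p; NaN pairs dropped pairwise."""
    xa = np.asarray(x, dtype=float)
    ya = np.asarray(y, dtype=float)
    if len(xa) != len(ya):
        raise ValueError("x and y must have equal length")
    ok = ~(np.isnan(xa) | np.isnan(ya))
    xa, ya = xa[ok], ya[ok]
    n = len(xa)
    if n < 3:
        raise ValueError("need >=3 complete pairs")
    rx = sps.rankdata(xa)
    ry = sps.rankdata(ya)
    rx = rx - rx.mean()
    ry = ry - ry.mean()
    denom = math.sqrt(float((rx**2).sum() * (ry**2).sum()))
    if denom == 0:
        raise ValueError("constant input after ranking")
    rho = float((rx * ry).sum() / denom)
    if abs(rho) >= 1.0:
        p = 0.0
    else:
        t = rho * math.sqrt((n - 2) / (1.0 - rho**2))
        p = float(2.0 * sps.t.sf(abs(t), df=n - 2))
    return {"rho": rho, "p": p, "n": n}
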