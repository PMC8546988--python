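"""Per-feature mixed-model differential abundance with BH FDR.

Abundances are log2-transformed after per-sample smoothing of zeros (each
zero is replaced by that sample's minimum nonzero value). Each feature is
then modeled as phenotype (healthy as the reference level) plus age and
antibiotic-use fixed effects, with random intercepts for subject and
cohort — subjects are nested within cohorts, so the model uses cohort
groups with a subject variance component (REML, statsmodels MixedLM).
Features whose full model fails to converge are refitted without the
cohort intercept (subject-only random effect) and flagged if still
failing. Benjamini-Hochberg is applied across all feature × phenotype
tests.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.formula.api as smf

REFERENCE_PHENOTYPE = "healthy"


def transform_abundance(
    table: pd.DataFrame, base: float = 2.0, mode: str = "min"
) -> pd.DataFrame:
    """Per-sample zero smoothing followed by log transform.

    Within each sample (column), zeros are replaced by the sample's minimum
    nonzero value (``mode="min"``) or half of it (``mode="half_min"``),
    then log base 2 (configurable) is applied elementwise.
    """
    if (table.values < 0).any():
        raise ValueError("abundances must be non-negative")
    out = table.copy().astype(float)
    for col in out.columns:
        x = out[col].values
        nz = x[x > 0]
        if len(nz) == 0:
            raise ValueError(f"sample {col!r} is all zero")
        fill = nz.min() if mode == "min" else nz.min() / 2.0
        if mode not in ("min", "half_min"):
            raise ValueError(f"unknown smoothing mode {mode!r}")
        x = np.where(x == 0, fill, x)
        out[col] = np.log(x) / np.log(base)
    return out


def bh_adjust(pvalues: np.ndarray | list) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values.

    q_(i) = min_{j>=i} p_(j) · m / j, capped at 1, mapped back to the input
    order.
    """
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q_sorted = np.minimum(q_sorted, 1.0)
    q = np.empty(m)
    q[order] = q_sorted
    return q


@dataclass
class DifferentialResult:
    feature: str
    phenotype: str
    coefficient: float
    stderr: float
    p_value: float
    q_value: float
    n_samples: int
    converged: bool


def _fit_one(
    y: np.ndarray, meta: pd.DataFrame, phenotypes: list[str], reference: str
) -> tuple[dict[str, tuple[float, float, float]], bool]:
    """Fit the mixed model for one feature; returns per-phenotype
    (coef, se, p) and a convergence flag."""
    df = meta.copy()
    df["y"] = y
    df["phenotype"] = pd.Categorical(
        df["phenotype"],
        categories=[reference] + [p for p in phenotypes if p != reference],
    )
    fixed = "y ~ C(phenotype) + age + C(antibiotics)"

    def _extract(res) -> dict[str, tuple[float, float, float]]:
        out = {}
        for pheno in phenotypes:
            if pheno == reference:
                continue
            name = f"C(phenotype)[T.{pheno}]"
            out[pheno] = (
                float(res.params[name]),
                float(res.bse[name]),
                float(res.pvalues[name]),
            )
        return out

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            if df["cohort_id"].nunique() > 1:
                model = smf.mixedlm(
                    fixed, df, groups="cohort_id",
                    re_formula="1",
                    vc_formula={"subject": "0 + C(subject_id)"},
                )
            else:
                model = smf.mixedlm(fixed, df, groups="subject_id")
            res = model.fit(reml=True)
            if res.converged and np.all(np.isfinite(res.bse.to_numpy())):
                return _extract(res), True
        except Exception:
            pass
        # fallback: drop the cohort intercept, subject-only random effect
        try:
            model = smf.mixedlm(fixed, df, groups="subject_id")
            res = model.fit(reml=True)
            return _extract(res), bool(res.converged)
        except Exception:
            return {}, False


def fit_feature_models(
    transformed: pd.DataFrame,
    metadata: pd.DataFrame,
    reference: str = REFERENCE_PHENOTYPE,
) -> pd.DataFrame:
    """Mixed-model association of every feature with phenotype.

    ``transformed`` is features × samples (already log-transformed);
    ``metadata`` must carry phenotype, age, antibiotics, subject_id and
    cohort_id per sample, with the healthy reference level present.
    Returns a tidy frame (feature, phenotype, coefficient, stderr, p, q,
    n, converged) with BH FDR across all feature × phenotype tests.
    """
    required = {"phenotype", "age", "antibiotics", "subject_id", "cohort_id"}
    missing = required - set(metadata.columns)
    if missing:
        raise ValueError(f"metadata missing columns: {sorted(missing)}")
    samples = [s for s in transformed.columns if s in metadata.index]
    if len(samples) < len(transformed.columns):
        raise ValueError("metadata missing rows for some samples")
    meta = metadata.loc[samples]
    phenotypes = sorted(meta["phenotype"].unique())
    if len(phenotypes) < 2:
        raise ValueError("need >=2 phenotype levels")
    if reference not in phenotypes:
        raise ValueError(f"reference level {reference!r} absent")

    results: list[DifferentialResult] = []
    for feature in transformed.index:
        y = transformed.loc[feature, samples].to_numpy(dtype=float)
        if np.allclose(y, y[0]):
            for pheno in phenotypes:
                if pheno == reference:
                    continue
                results.append(DifferentialResult(
                    feature, pheno, np.nan, np.nan, np.nan, np.nan,
                    len(samples), False,
                ))
            continue
        coefs, converged = _fit_one(y, meta, phenotypes, reference)
        for pheno in phenotypes:
            if pheno == reference:
                continue
            if pheno in coefs:
                c, se, p = coefs[pheno]
            else:
                c = se = p = np.nan
                converged = False
            results.append(DifferentialResult(
                feature, pheno, c, se, p, np.nan, len(samples), converged,
            ))

    out = pd.DataFrame([r.__dict__ for r in results])
    ok = out["p_value"].notna()
    q = np.full(len(out), np.nan)
    if ok.any():
        q[ok.to_numpy()] = bh_adjust(out.loc[ok, "p_value"].to_numpy())
    out["q_value"] = q
    return out.rename(columns={
        "coefficient": "coefficient", "p_value": "p", "q_value": "q",
        "n_samples": "n",
    })
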