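"""Normal-pouch vs pouchitis gradient-boosted-tree classification protocol.

Longitudinal samples are averaged per subject, then an XGBoost classifier
(fixed hyperparameters: learning rate 0.1, 250 trees, depth 3, subsample
0.5, colsample 0.5 for species/pathways or 0.1 for enzymes, gamma 0.1,
L1 0.01, L2 0.5) is evaluated by stratified 5-fold cross-validation
repeated 100 times. Feature importances ("gain") are averaged over every
repeat × fold; the top-k features feed a final model that is validated on
an external cohort with AUC, sensitivity, specificity, accuracy and a
confusion matrix.

Selection from pooled CV importances reuses held-out folds and can inflate
null performance; a nested mode (selection recomputed inside each training
fold) is provided as the statistically safer alternative for new data.
"""

from __future__ import annotations

import warnings
from dataclasses import asdict, dataclass, field

import numpy as np
import pandas as pd
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import StratifiedKFold
from xgboost import XGBClassifier

POSITIVE_CLASS = "pouchitis"
PREDICTION_THRESHOLD = 0.5


@dataclass
class GBTParams:
    """Fixed gradient-boosted-tree hyperparameters of the protocol."""

    learning_rate: float = 0.1
    n_estimators: int = 250
    colsample_bytree: float = 0.5  # 0.1 for the enzyme model
    subsample: float = 0.5
    max_depth: int = 3
    gamma: float = 0.1
    reg_alpha: float = 0.01
    reg_lambda: float = 0.5
    importance_type: str = "gain"

    def to_xgb_kwargs(self, seed: int) -> dict:
        kw = asdict(self)
        kw.pop("importance_type")
        return dict(
            **kw,
            importance_type=self.importance_type,
            random_state=seed,
            n_jobs=1,
            eval_metric="logloss",
            verbosity=0,
        )

    @classmethod
    def for_feature_kind(cls, kind: str) -> "GBTParams":
        if kind == "enzymes":
            return cls(colsample_bytree=0.1)
        return cls()


@dataclass
class CVReport:
    """Per-fold metrics plus averaged importances of a repeated-CV run."""

    fold_metrics: pd.DataFrame  # repeat, fold, auc, sensitivity, specificity, accuracy
    mean_auc: float
    sd_auc: float
    importances: pd.Series  # mean importance per feature, descending
    params: GBTParams
    seed: int
    k_folds: int
    repeats: int
    selected_features: list[str] = field(default_factory=list)


def average_by_subject(
    table: pd.DataFrame, metadata: pd.DataFrame, with_calprotectin: bool = False
) -> tuple[pd.DataFrame, pd.Series]:
    """Average longitudinal samples per subject.

    ``table`` is features × samples. Returns (subjects × features matrix,
    subject phenotype labels). Optionally appends each subject's mean
    calprotectin (over its non-missing measurements) as a feature column.
    """
    samples = [s for s in table.columns if s in metadata.index]
    if len(samples) < len(table.columns):
        missing = set(table.columns) - set(samples)
        raise ValueError(f"samples missing from metadata: {sorted(missing)[:5]}")
    meta = metadata.loc[samples]
    label_sets = meta.groupby("subject_id")["phenotype"].nunique()
    conflicted = label_sets[label_sets > 1].index.tolist()
    if conflicted:
        raise ValueError(f"subjects with conflicting phenotype labels: {conflicted}")
    x = table[samples].T  # samples × features
    x = x.join(meta[["subject_id"]])
    averaged = x.groupby("subject_id").mean()
    labels = meta.groupby("subject_id")["phenotype"].first().loc[averaged.index]
    if with_calprotectin:
        cal = meta.groupby("subject_id")["calprotectin"].mean()
        averaged["calprotectin"] = cal.loc[averaged.index]
    return averaged, labels


def _binary_metrics(y_true: np.ndarray, prob: np.ndarray) -> dict:
    pred = (prob >= PREDICTION_THRESHOLD).astype(int)
    tp = int(((pred == 1) & (y_true == 1)).sum())
    tn = int(((pred == 0) & (y_true == 0)).sum())
    fp = int(((pred == 1) & (y_true == 0)).sum())
    fn = int(((pred == 0) & (y_true == 1)).sum())
    n = len(y_true)
    if len(np.unique(y_true)) < 2:
        auc = np.nan
    else:
        auc = float(roc_auc_score(y_true, prob))
    return {
        "auc": auc,
        "accuracy": (tp + tn) / n,
        "sensitivity": tp / (tp + fn) if tp + fn else np.nan,
        "specificity": tn / (tn + fp) if tn + fp else np.nan,
        "confusion": {"tp": tp, "tn": tn, "fp": fp, "fn": fn},
    }


def _encode_labels(y: pd.Series | np.ndarray) -> np.ndarray:
    y = pd.Series(y)
    classes = sorted(y.unique())
    if len(classes) != 2:
        raise ValueError(f"need exactly 2 classes, got {classes}")
    positive = POSITIVE_CLASS if POSITIVE_CLASS in classes else classes[1]
    return (y == positive).to_numpy(dtype=int)


def cross_validate(
    X: pd.DataFrame,
    y: pd.Series | np.ndarray,
    params: GBTParams | None = None,
    k: int = 5,
    repeats: int = 100,
    seed: int = 0,
    nested_top_k: int | None = None,
) -> CVReport:
    """Repeated stratified k-fold CV of the GBT classifier.

    Each repeat draws a fresh stratified split from a repeat-specific seed
    derived from the master seed, so the full report is deterministic.
    With ``nested_top_k``, feature selection is recomputed inside every
    training fold (no leakage); default is no within-fold selection —
    selection from pooled importances happens afterwards via
    :func:`rank_and_select`.
    """
    params = params or GBTParams()
    yb = _encode_labels(y)
    counts = np.bincount(yb)
    if (counts < k).any():
        raise ValueError(
            f"every class needs >= k={k} subjects (have {counts.tolist()}); "
            "use a smaller k"
        )
    rng = np.random.default_rng(seed)
    repeat_seeds = rng.integers(0, 2**31 - 1, size=repeats)
    rows = []
    importance_sum = np.zeros(X.shape[1])
    n_fits = 0
    for r, rseed in enumerate(repeat_seeds):
        skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=int(rseed))
        for fold, (tr, te) in enumerate(skf.split(X, yb)):
            X_tr, X_te = X.iloc[tr], X.iloc[te]
            if nested_top_k is not None:
                ranker = XGBClassifier(**params.to_xgb_kwargs(int(rseed)))
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    ranker.fit(X_tr, yb[tr])
                order = np.argsort(ranker.feature_importances_)[::-1]
                keep = X.columns[np.sort(order[:nested_top_k])]
                X_tr, X_te = X_tr[keep], X_te[keep]
            model = XGBClassifier(**params.to_xgb_kwargs(int(rseed)))
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                model.fit(X_tr, yb[tr])
            prob = model.predict_proba(X_te)[:, 1]
            m = _binary_metrics(yb[te], prob)
            rows.append({"repeat": r, "fold": fold, "auc": m["auc"],
                         "sensitivity": m["sensitivity"],
                         "specificity": m["specificity"],
                         "accuracy": m["accuracy"]})
            if nested_top_k is None:
                importance_sum += model.feature_importances_
            n_fits += 1
    fold_metrics = pd.DataFrame(rows)
    aucs = fold_metrics["auc"].dropna()
    importances = pd.Series(
        importance_sum / max(n_fits, 1), index=X.columns
    ).sort_values(ascending=False)
    return CVReport(
        fold_metrics=fold_metrics,
        mean_auc=float(aucs.mean()),
        sd_auc=float(aucs.std(ddof=1)),
        importances=importances,
        params=params,
        seed=seed,
        k_folds=k,
        repeats=repeats,
    )


def rank_and_select(report: CVReport, top_k: int) -> list[str]:
    """Top-k features by mean CV importance; ties broken lexicographically."""
    imp = report.importances
    if top_k > len(imp):
        raise ValueError(f"top_k={top_k} exceeds feature count {len(imp)}")
    order = sorted(imp.index, key=lambda f: (-imp[f], str(f)))
    selected = order[:top_k]
    report.selected_features = selected
    return selected


def validate_external(
    X_train: pd.DataFrame,
    y_train: pd.Series | np.ndarray,
    X_val: pd.DataFrame,
    y_val: pd.Series | np.ndarray,
    params: GBTParams | None = None,
    features: list[str] | None = None,
    seed: int = 0,
) -> dict:
    """Refit once on the full discovery set and score an external cohort.

    Validation columns are subset/reordered to the training feature list;
    features absent from the validation table are imputed as 0 with a
    warning. Returns AUC, accuracy, sensitivity, specificity and the
    confusion matrix (probability >= 0.5 → pouchitis).
    """
    params = params or GBTParams()
    features = list(features) if features is not None else list(X_train.columns)
    overlap = [f for f in features if f in X_val.columns]
    if not overlap:
        raise ValueError("no overlap between trained features and validation columns")
    missing = [f for f in features if f not in X_val.columns]
    if missing:
        warnings.warn(f"{len(missing)} trained feature(s) absent from validation "
                      f"table, imputed as 0: {missing[:5]}")
    Xv = X_val.reindex(columns=features, fill_value=0.0)
    yb_tr = _encode_labels(y_train)
    yb_va = _encode_labels(y_val)
    model = XGBClassifier(**params.to_xgb_kwargs(seed))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model.fit(X_train[features], yb_tr)
    prob = model.predict_proba(Xv)[:, 1]
    return _binary_metrics(yb_va, prob)
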