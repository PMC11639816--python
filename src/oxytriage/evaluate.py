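"""Multi-class evaluation, importance reporting, ablation, and light EDA.

Metrics are computed for the 4-class severity problem: per-class precision,
sensitivity (= recall), specificity and F1; macro and support-weighted
aggregates; accuracy; the generalized multi-class Matthews correlation
coefficient (covariance form over the confusion matrix, 0 when the
denominator vanishes); and one-vs-rest AUROC/AUPRC per class with unweighted
averages.  AUPRC uses trapezoidal integration of the PR curve.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA
from sklearn.metrics import confusion_matrix as _sk_confusion
from sklearn.metrics import precision_recall_curve, roc_auc_score
from sklearn.preprocessing import StandardScaler

from .datasets import build_tree_dataset, class_weights
from .models.trees import FittedTreeModel, TreeModelConfig, train_tree
from .preprocess import FEATURE_COLUMNS

logger = logging.getLogger(__name__)

__all__ = [
    "MetricReport",
    "compute_metrics",
    "multiclass_mcc",
    "importance_report",
    "ablate",
    "correlation_matrix",
    "pca_variance",
]

N_CLASSES = 4


@dataclass
class MetricReport:
    """Evaluation summary for one model on one sample set."""

    confusion: np.ndarray
    accuracy: float
    per_class: pd.DataFrame  # precision, sensitivity, specificity, f1, support
    macro: dict[str, float]
    weighted: dict[str, float]
    mcc: float
    auroc: dict[int, float | None]
    auprc: dict[int, float | None]
    avg_auroc: float | None
    avg_auprc: float | None
    sample_unit: str = "minute-rows"

    def to_dict(self) -> dict:
        return {
            "sample_unit": self.sample_unit,
            "confusion": self.confusion.tolist(),
            "accuracy": self.accuracy,
            "per_class": self.per_class.to_dict(orient="index"),
            "macro": self.macro,
            "weighted": self.weighted,
            "mcc": self.mcc,
            "auroc": {str(k): v for k, v in self.auroc.items()},
            "auprc": {str(k): v for k, v in self.auprc.items()},
            "avg_auroc": self.avg_auroc,
            "avg_auprc": self.avg_auprc,
        }


def multiclass_mcc(confusion: np.ndarray) -> float:
    """Generalized (covariance-form) Matthews correlation coefficient.

    Returns 0 when either marginal term of the denominator vanishes (e.g. a
    single-class constant predictor).
    """
    cm = np.asarray(confusion, dtype=float)
    s = cm.sum()
    c = np.trace(cm)
    t = cm.sum(axis=1)  # true-class totals
    p = cm.sum(axis=0)  # predicted-class totals
    num = c * s - float(t @ p)
    den = np.sqrt(s**2 - float(p @ p)) * np.sqrt(s**2 - float(t @ t))
    return float(num / den) if den > 0 else 0.0


def _trapezoid_auprc(y_bin: np.ndarray, scores: np.ndarray) -> float:
    # integrate along the threshold-ordered curve (recall is non-increasing);
    # sorting by recall would average duplicate-recall points incorrectly
    precision, recall, _ = precision_recall_curve(y_bin, scores)
    return float(-np.trapezoid(precision, recall))


def compute_metrics(
    y_true: np.ndarray,
    y_pred: np.ndarray,
    proba: np.ndarray | None = None,
    n_classes: int = N_CLASSES,
    sample_unit: str = "minute-rows",
) -> MetricReport:
    """Full multi-class metric report.

    ``proba`` rows must sum to 1 (within 1e-6); classes absent from
    ``y_true`` get no OvR AUROC/AUPRC and are excluded from the averages.
    """
    y_true = np.asarray(y_true, dtype=int)
    y_pred = np.asarray(y_pred, dtype=int)
    labels = list(range(n_classes))
    if proba is not None:
        proba = np.asarray(proba, dtype=float)
        if proba.shape != (y_true.size, n_classes):
            raise ValueError(f"probability matrix must be (n, {n_classes})")
        if np.abs(proba.sum(axis=1) - 1.0).max() > 1e-6:
            raise ValueError("probability rows must sum to 1 within 1e-6")
    cm = _sk_confusion(y_true, y_pred, labels=labels)
    total = cm.sum()
    accuracy = float(np.trace(cm) / total) if total else 0.0

    rows = {}
    for c in labels:
        tp = cm[c, c]
        fn = cm[c].sum() - tp
        fp = cm[:, c].sum() - tp
        tn = total - tp - fn - fp
        precision = tp / (tp + fp) if tp + fp else 0.0
        sensitivity = tp / (tp + fn) if tp + fn else 0.0
        specificity = tn / (tn + fp) if tn + fp else 0.0
        f1 = 2 * tp / (2 * tp + fp + fn) if 2 * tp + fp + fn else 0.0
        rows[c] = {
            "precision": precision,
            "sensitivity": sensitivity,
            "specificity": specificity,
            "f1": f1,
            "support": int(tp + fn),
        }
    per_class = pd.DataFrame.from_dict(rows, orient="index")
    support = per_class["support"].to_numpy(dtype=float)
    metric_cols = ["precision", "sensitivity", "specificity", "f1"]
    macro = {m: float(per_class[m].mean()) for m in metric_cols}
    weighted = {
        m: float(np.average(per_class[m], weights=support)) if support.sum() else 0.0
        for m in metric_cols
    }

    auroc: dict[int, float | None] = {}
    auprc: dict[int, float | None] = {}
    if proba is not None:
        for c in labels:
            y_bin = (y_true == c).astype(int)
            if y_bin.min() == y_bin.max():
                logger.warning("class %d absent from y_true; OvR curves undefined", c)
                auroc[c] = auprc[c] = None
                continue
            auroc[c] = float(roc_auc_score(y_bin, proba[:, c]))
            auprc[c] = _trapezoid_auprc(y_bin, proba[:, c])
    else:
        auroc = {c: None for c in labels}
        auprc = {c: None for c in labels}
    defined_roc = [v for v in auroc.values() if v is not None]
    defined_pr = [v for v in auprc.values() if v is not None]
    return MetricReport(
        confusion=cm,
        accuracy=accuracy,
        per_class=per_class,
        macro=macro,
        weighted=weighted,
        mcc=multiclass_mcc(cm),
        auroc=auroc,
        auprc=auprc,
        avg_auroc=float(np.mean(defined_roc)) if defined_roc else None,
        avg_auprc=float(np.mean(defined_pr)) if defined_pr else None,
        sample_unit=sample_unit,
    )


def importance_report(
    models: Mapping[str, FittedTreeModel],
    feature_names: Sequence[str] = FEATURE_COLUMNS,
    top: int | None = None,
) -> pd.DataFrame:
    """Per-model importance and rank table over the shared feature schema."""
    frames = {}
    for name, model in models.items():
        imp = model.feature_importances()
        total = imp.sum()
        frames[f"{name}_importance"] = imp / total if total > 0 else imp
    table = pd.DataFrame(frames, index=list(feature_names))
    for name in models:
        table[f"{name}_rank"] = (
            table[f"{name}_importance"].rank(ascending=False, method="min").astype(int)
        )
    mean_imp = table[[f"{n}_importance" for n in models]].mean(axis=1)
    table = table.loc[mean_imp.sort_values(ascending=False).index]
    return table.head(top) if top else table


def _drop_columns(features_to_drop: Iterable[str], drop_tags: bool) -> list[str]:
    dropped = []
    for feat in features_to_drop:
        dropped.append(feat)
        mask_col = f"mask_{feat}"
        if mask_col in FEATURE_COLUMNS:
            dropped.append(mask_col)
        if drop_tags:
            for col in (f"tag_{feat}", f"mask_tag_{feat}"):
                if col in FEATURE_COLUMNS:
                    dropped.append(col)
    unknown = [c for c in dropped if c not in FEATURE_COLUMNS]
    if unknown:
        raise KeyError(f"unknown feature columns: {unknown}")
    return dropped


def ablate(
    config: TreeModelConfig,
    train_frame: pd.DataFrame,
    test_frame: pd.DataFrame,
    features_to_drop: Iterable[str],
    drop_tags: bool = False,
    lag_minutes: int = 5,
) -> dict[str, MetricReport]:
    """Retrain without the named raw columns (and their masks) and compare.

    TAG columns derived from dropped vitals are kept unless ``drop_tags`` -
    note that they leak a coarse version of the dropped signal.
    Returns {"full": report, "ablated": report}.
    """
    dropped = _drop_columns(features_to_drop, drop_tags)
    keep = [c for c in FEATURE_COLUMNS if c not in dropped]
    if not keep:
        raise ValueError("cannot drop every feature")

    X_tr, y_tr, _ = build_tree_dataset(train_frame, lag_minutes)
    X_te, y_te, _ = build_tree_dataset(test_frame, lag_minutes)
    counts = {c: int((y_tr == c).sum()) for c in np.unique(y_tr)}
    cw = class_weights(counts)
    sw = np.array([cw[c] for c in y_tr])

    col_idx = {c: i for i, c in enumerate(FEATURE_COLUMNS)}
    keep_idx = [col_idx[c] for c in keep]

    reports = {}
    for name, idx in (("full", list(range(len(FEATURE_COLUMNS)))), ("ablated", keep_idx)):
        model = train_tree(config, X_tr[:, idx], y_tr, sample_weight=sw)
        proba_cols = model.classes_.astype(int)
        proba = np.zeros((len(y_te), N_CLASSES))
        proba[:, proba_cols] = model.predict_proba(X_te[:, idx])
        pred = model.predict(X_te[:, idx])
        reports[name] = compute_metrics(y_te, pred, proba)
    logger.info(
        "ablate: dropped %s -> MCC %.3f vs full %.3f",
        dropped,
        reports["ablated"].mcc,
        reports["full"].mcc,
    )
    return reports


def correlation_matrix(table: pd.DataFrame, columns: Sequence[str] | None = None) -> pd.DataFrame:
    """Pearson correlations; zero-variance columns are excluded with a warning."""
    cols = list(columns) if columns else [
        c for c in table.columns if pd.api.types.is_numeric_dtype(table[c])
    ]
    sub = table[cols]
    variances = sub.var()
    degenerate = variances[variances == 0].index.tolist()
    if degenerate:
        logger.warning("correlation_matrix: dropping zero-variance columns %s", degenerate)
        sub = sub.drop(columns=degenerate)
    if sub.shape[1] < 2 or len(sub) < 3:
        raise ValueError("need >= 2 varying numeric columns and >= 3 rows")
    return sub.corr(method="pearson")


def pca_variance(
    table: pd.DataFrame, columns: Sequence[str] | None = None
) -> pd.DataFrame:
    """Standardized PCA: per-component variance ratio and cumulative curve."""
    cols = list(columns) if columns else [
        c for c in table.columns if pd.api.types.is_numeric_dtype(table[c])
    ]
    sub = table[cols]
    variances = sub.var()
    degenerate = variances[variances == 0].index.tolist()
    if degenerate:
        logger.warning("pca_variance: dropping zero-variance columns %s", degenerate)
        sub = sub.drop(columns=degenerate)
    if sub.shape[1] < 2 or len(sub) < 3:
        raise ValueError("need >= 2 varying numeric columns and >= 3 rows")
    scaled = StandardScaler().fit_transform(sub.to_numpy(dtype=float))
    pca = PCA().fit(scaled)
    ratios = pca.explained_variance_ratio_
    return pd.DataFrame(
        {
            "component": np.arange(1, ratios.size + 1),
            "variance_ratio": ratios,
            "cumulative": np.cumsum(ratios),
        }
    )
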