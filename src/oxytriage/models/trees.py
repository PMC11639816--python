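"""Declarative tree-model harness.

Four configurations mirror the study's table of default and tuned
hyperparameters: three boosted-tree rows and a random forest.  Concrete
engines are pluggable behind the ``ENGINES`` registry; any estimator exposing
per-class probabilities and gain-based feature importance may back a row.  In
this build the boosted rows are backed by scikit-learn's histogram gradient
boosting (the same algorithm family); parameters that the backing engine
cannot express (e.g. row subsampling) are recorded as dropped on the fitted
handle rather than silently ignored.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Callable, Mapping

import numpy as np
from sklearn.ensemble import HistGradientBoostingClassifier, RandomForestClassifier
from sklearn.metrics import log_loss, roc_auc_score

logger = logging.getLogger(__name__)

__all__ = [
    "TreeModelConfig",
    "FittedTreeModel",
    "DEFAULT_TREE_CONFIGS",
    "ENGINES",
    "train_tree",
    "make_tpe_objective",
]


@dataclass(frozen=True)
class TreeModelConfig:
    """Declarative description of one tree-model row."""

    family: str  # "random_forest" | "boosted_trees"
    engine_key: str
    fixed_params: Mapping[str, object]
    search_space: Mapping[str, object]  # param -> (lower, upper) or categorical tuple

    def with_params(self, params: Mapping[str, object]) -> "TreeModelConfig":
        merged = dict(self.fixed_params) | dict(params)
        return TreeModelConfig(self.family, self.engine_key, merged, self.search_space)


#: Search bounds exactly as printed in the study's hyperparameter table.
DEFAULT_TREE_CONFIGS: dict[str, TreeModelConfig] = {
    "xgboost": TreeModelConfig(
        family="boosted_trees",
        engine_key="xgboost",
        fixed_params={"n_rounds": 300, "early_stopping_rounds": 5, "seed": 42},
        search_space={
            "max_depth": (4, 8),
            "eta": (0.005, 0.3),
            "subsample": (0.5, 1.0),
            "gamma": (0.0, 22.0),
            "min_child_weight": (0.0, 15.0),
        },
    ),
    "catboost": TreeModelConfig(
        family="boosted_trees",
        engine_key="catboost",
        fixed_params={"n_rounds": 400, "early_stopping_rounds": 5, "seed": 42},
        search_space={
            "depth": (4, 10),
            "learning_rate": (0.005, 0.3),
            "l2_leaf_reg": (1.0, 10.0),
            "min_data_in_leaf": (1.0, 15.0),
        },
    ),
    "lightgbm": TreeModelConfig(
        family="boosted_trees",
        engine_key="lightgbm",
        fixed_params={"n_rounds": 300, "seed": 42},
        search_space={
            "max_depth": (4, 8),
            "learning_rate": (0.005, 0.3),
            "bagging_fraction": (0.5, 1.0),
            "min_split_gain": (0.0, 22.0),
            "min_child_weight": (0.0, 15.0),
        },
    ),
    "random_forest": TreeModelConfig(
        family="random_forest",
        engine_key="random_forest",
        fixed_params={"n_estimators": 100, "seed": 42, "n_jobs": -1},
        search_space={
            "max_depth": (4, 20),
            "min_samples_split": (2, 10),
            "min_samples_leaf": (1, 5),
            "max_features": ("sqrt", "log2", 12),
            "criterion": ("gini", "entropy"),
        },
    ),
}


def _as_leaf(value: object) -> int:
    """Integer-valued engine parameter from a (possibly fractional) sample."""
    return max(1, int(round(float(value))))


def _build_hgb(params: Mapping[str, object]) -> tuple[HistGradientBoostingClassifier, list[str]]:
    """Translate a boosted-row parameterization onto histogram GBM."""
    dropped: list[str] = []
    kwargs: dict = {
        "max_iter": int(params.get("n_rounds", 300)),
        "random_state": int(params.get("seed", 42)),
    }
    esr = params.get("early_stopping_rounds")
    if esr:
        kwargs |= {
            "early_stopping": True,
            "n_iter_no_change": int(esr),
            "validation_fraction": 0.1,
        }
    else:
        kwargs["early_stopping"] = False
    renames = {
        "eta": "learning_rate",
        "learning_rate": "learning_rate",
        "max_depth": "max_depth",
        "depth": "max_depth",
        "l2_leaf_reg": "l2_regularization",
        "min_child_weight": "min_samples_leaf",
        "min_data_in_leaf": "min_samples_leaf",
    }
    unsupported = {"subsample", "gamma", "bagging_fraction", "min_split_gain"}
    for name, value in params.items():
        if name in ("n_rounds", "early_stopping_rounds", "seed"):
            continue
        if name in unsupported:
            dropped.append(name)
            continue
        target = renames.get(name)
        if target is None:
            raise ValueError(f"unknown boosted-tree parameter {name!r}")
        if target in ("max_depth", "min_samples_leaf"):
            kwargs[target] = _as_leaf(value)
        else:
            kwargs[target] = float(value)
    return HistGradientBoostingClassifier(**kwargs), dropped


def _build_rf(params: Mapping[str, object]) -> tuple[RandomForestClassifier, list[str]]:
    kwargs: dict = {
        "n_estimators": int(params.get("n_estimators", 100)),
        "random_state": int(params.get("seed", 42)),
        "n_jobs": int(params.get("n_jobs", -1)),
    }
    for name, value in params.items():
        if name in ("n_estimators", "seed", "n_jobs"):
            continue
        if name in ("max_depth", "min_samples_split", "min_samples_leaf"):
            kwargs[name] = _as_leaf(value) if name != "min_samples_split" else max(2, int(round(float(value))))
        elif name == "max_features":
            kwargs[name] = int(value) if isinstance(value, (int, float)) else str(value)
        elif name == "criterion":
            kwargs[name] = str(value)
        else:
            raise ValueError(f"unknown random-forest parameter {name!r}")
    return RandomForestClassifier(**kwargs), []


ENGINES: dict[str, Callable] = {
    "xgboost": _build_hgb,
    "catboost": _build_hgb,
    "lightgbm": _build_hgb,
    "random_forest": _build_rf,
}


@dataclass
class FittedTreeModel:
    """A fitted engine with the probability/importance contract."""

    config: TreeModelConfig
    estimator: object
    dropped_params: list[str] = field(default_factory=list)
    train_curve: np.ndarray = field(default_factory=lambda: np.empty(0))
    val_curve: np.ndarray = field(default_factory=lambda: np.empty(0))

    @property
    def classes_(self) -> np.ndarray:
        return self.estimator.classes_

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        return self.estimator.predict_proba(np.asarray(X, dtype=float))

    def predict(self, X: np.ndarray) -> np.ndarray:
        return self.estimator.predict(np.asarray(X, dtype=float))

    @property
    def n_iterations(self) -> int:
        est = self.estimator
        return int(getattr(est, "n_iter_", getattr(est, "n_estimators", 0)))

    def feature_importances(self) -> np.ndarray:
        """Gain-based importance per input feature (unnormalized)."""
        est = self.estimator
        if hasattr(est, "feature_importances_"):  # random forest: impurity decrease
            return np.asarray(est.feature_importances_, dtype=float)
        imp = np.zeros(est.n_features_in_, dtype=float)
        for iteration in est._predictors:
            for predictor in iteration:
                nodes = predictor.nodes
                split = ~nodes["is_leaf"].astype(bool)
                np.add.at(imp, nodes["feature_idx"][split], nodes["gain"][split])
        return imp


def train_tree(
    config: TreeModelConfig,
    X_train: np.ndarray,
    y_train: np.ndarray,
    sample_weight: np.ndarray | None = None,
) -> FittedTreeModel:
    """Fit one configured tree model; deterministic for a fixed seed.

    Exposes per-class probabilities, gain-based importance, and the engine's
    training/validation score curves where available.
    """
    X_train = np.asarray(X_train, dtype=float)
    if not np.isfinite(X_train).all():
        raise ValueError("non-finite feature values; the pipeline guarantees none")
    builder = ENGINES[config.engine_key]
    estimator, dropped = builder(config.fixed_params)
    if dropped:
        logger.info(
            "train_tree[%s]: engine cannot express %s; recorded as dropped",
            config.engine_key,
            dropped,
        )
    estimator.fit(X_train, np.asarray(y_train), sample_weight=sample_weight)
    return FittedTreeModel(
        config=config,
        estimator=estimator,
        dropped_params=dropped,
        train_curve=np.asarray(getattr(estimator, "train_score_", []), dtype=float),
        val_curve=np.asarray(getattr(estimator, "validation_score_", []), dtype=float),
    )


def make_tpe_objective(
    config: TreeModelConfig,
    X_train: np.ndarray,
    y_train: np.ndarray,
    X_val: np.ndarray,
    y_val: np.ndarray,
    objective: str = "one_minus_auc",
    sample_weight: np.ndarray | None = None,
) -> Callable[[Mapping[str, object]], float]:
    """Validation-split objective for TPE: ``1 - macro OvR AUROC`` or log loss."""
    if objective not in ("one_minus_auc", "logloss"):
        raise ValueError(f"unknown objective {objective!r}")

    def _evaluate(params: Mapping[str, object]) -> float:
        model = train_tree(config.with_params(params), X_train, y_train, sample_weight)
        proba = model.predict_proba(X_val)
        if objective == "logloss":
            return float(log_loss(y_val, proba, labels=model.classes_))
        auc = roc_auc_score(y_val, proba, multi_class="ovr", average="macro",
                            labels=model.classes_)
        return float(1.0 - auc)

    return _evaluate
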