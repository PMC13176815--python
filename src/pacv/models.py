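"""Classifier adapters: ten standard families plus a built-in linear model.

Every family is exposed through one :class:`ModelAdapter` contract
(fit -> predict -> serialized_size) at a fixed default configuration with a
pinned seed, plus a small capacity-ordered hyperparameter grid for the
nested scheme's inner search. The gradient-boosted families backed by
optional libraries (xgboost, lightgbm) are skipped with a logged notice when
the library is absent; :class:`BuiltinLinearClassifier` — L2-regularized
logistic regression fit by plain gradient descent — is always available so
the toolkit runs with no optional backend.
"""

from __future__ import annotations

import logging
import pickle
from dataclasses import dataclass, field
from itertools import product

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.discriminant_analysis import (
    LinearDiscriminantAnalysis,
    QuadraticDiscriminantAnalysis,
)
from sklearn.ensemble import (
    AdaBoostClassifier,
    ExtraTreesClassifier,
    GradientBoostingClassifier,
    RandomForestClassifier,
)
from sklearn.linear_model import LogisticRegression
from sklearn.neighbors import KNeighborsClassifier
from sklearn.utils.validation import check_is_fitted, check_X_y

logger = logging.getLogger(__name__)

FAMILY_NAMES = (
    "knn",
    "logistic_regression",
    "adaboost",
    "lda",
    "qda",
    "gradient_boosting",
    "extra_trees",
    "random_forest",
    "xgboost",
    "lightgbm",
    "builtin_linear",
)


class BuiltinLinearClassifier(BaseEstimator, ClassifierMixin):
    """Logistic regression with L2 penalty, fit by full-batch gradient descent.

    Deterministic (zero initialization, fixed step schedule), dependency-free
    beyond numpy, and convex — so its decision boundary is checkable against
    any generic convex optimizer.

    Parameters
    ----------
    l2 : float
        Ridge penalty on the weights (not the intercept).
    lr : float
        Gradient step size.
    n_iter : int
        Number of full-batch gradient steps.
    """

    def __init__(self, l2: float = 1.0, lr: float = 0.5, n_iter: int = 300):
        self.l2 = l2
        self.lr = lr
        self.n_iter = n_iter

    def fit(self, X, y):
        X, y = check_X_y(X, y)
        self.classes_ = np.unique(y)
        yy = (y == self.classes_[-1]).astype(float)
        n, d = X.shape
        w = np.zeros(d)
        b = 0.0
        for _ in range(self.n_iter):
            z = X @ w + b
            p = 1.0 / (1.0 + np.exp(-np.clip(z, -35, 35)))
            g = p - yy
            w -= self.lr * ((X.T @ g) / n + self.l2 * w / n)
            b -= self.lr * g.mean()
        self.coef_ = w
        self.intercept_ = b
        self.n_features_in_ = d
        return self

    def decision_function(self, X):
        check_is_fitted(self, "coef_")
        return np.asarray(X, dtype=float) @ self.coef_ + self.intercept_

    def predict(self, X):
        score = self.decision_function(X)
        out = np.where(score >= 0, self.classes_[-1], self.classes_[0])
        return out


def _available_backends() -> dict[str, type]:
    backends: dict[str, type] = {}
    try:
        from xgboost import XGBClassifier

        backends["xgboost"] = XGBClassifier
    except ImportError:  # pragma: no cover - environment dependent
        logger.info("xgboost not installed; skipping the xgboost family")
    try:
        from lightgbm import LGBMClassifier

        backends["lightgbm"] = LGBMClassifier
    except ImportError:  # pragma: no cover
        logger.info("lightgbm not installed; skipping the lightgbm family")
    return backends


def _make_estimator(family: str, seed: int, config: dict):
    cfg = dict(config)
    if family == "knn":
        return KNeighborsClassifier(**cfg)
    if family == "logistic_regression":
        return LogisticRegression(random_state=seed, max_iter=1000, **cfg)
    if family == "adaboost":
        return AdaBoostClassifier(random_state=seed, **cfg)
    if family == "lda":
        return LinearDiscriminantAnalysis(**cfg)
    if family == "qda":
        return QuadraticDiscriminantAnalysis(**cfg)
    if family == "gradient_boosting":
        return GradientBoostingClassifier(random_state=seed, **cfg)
    if family == "extra_trees":
        return ExtraTreesClassifier(random_state=seed, **cfg)
    if family == "random_forest":
        return RandomForestClassifier(random_state=seed, **cfg)
    if family == "builtin_linear":
        return BuiltinLinearClassifier(**cfg)
    backends = _available_backends()
    if family == "xgboost":
        if "xgboost" not in backends:
            raise ImportError("xgboost is not installed")
        return backends["xgboost"](random_state=seed, eval_metric="logloss",
                                   verbosity=0, **cfg)
    if family == "lightgbm":
        if "lightgbm" not in backends:
            raise ImportError("lightgbm is not installed")
        return backends["lightgbm"](random_state=seed, verbose=-1, **cfg)
    raise ValueError(f"unknown model family '{family}'")


@dataclass
class ModelAdapter:
    """Uniform fit/predict wrapper around one classifier family.

    ``config`` holds the hyperparameters overriding the family's documented
    defaults; ``seed`` pins every randomized component.
    """

    family_name: str
    config: dict = field(default_factory=dict)
    seed: int = 42

    def __post_init__(self) -> None:
        if self.family_name not in FAMILY_NAMES:
            raise ValueError(f"unknown model family '{self.family_name}'")
        self.estimator_ = None

    def clone(self, config: dict | None = None) -> "ModelAdapter":
        return ModelAdapter(
            family_name=self.family_name,
            config=dict(self.config if config is None else config),
            seed=self.seed,
        )

    def fit(self, X, y) -> "ModelAdapter":
        est = _make_estimator(self.family_name, self.seed, self.config)
        est.fit(np.asarray(X, dtype=float), np.asarray(y, dtype=int))
        self.estimator_ = est
        return self

    def predict(self, X) -> np.ndarray:
        if self.estimator_ is None:
            raise RuntimeError("adapter is not fitted; call fit() first")
        return np.asarray(self.estimator_.predict(np.asarray(X, dtype=float)), dtype=int)

    @property
    def is_fitted(self) -> bool:
        return self.estimator_ is not None


def build_adapter(family_name: str, seed: int = 42, config: dict | None = None) -> ModelAdapter:
    """One adapter at its fixed configuration."""
    return ModelAdapter(family_name=family_name, config=dict(config or {}), seed=seed)


def build_default_models(seed: int = 42) -> list[ModelAdapter]:
    """One adapter per available family at its fixed default configuration.

    Families backed by an absent optional library are skipped with a logged
    notice; ``builtin_linear`` is always present.
    """
    backends = _available_backends()
    adapters = []
    for fam in FAMILY_NAMES:
        if fam in ("xgboost", "lightgbm") and fam not in backends:
            continue
        adapters.append(build_adapter(fam, seed=seed))
    return adapters


# Capacity-ordered grids for the nested inner search: index 0 is always the
# simplest (most regularized / shallowest / most-neighbors) configuration.
# They are deliberately small — the comparison hinges on the validation
# design, not grid breadth — and overridable per run.
def default_grid(family_name: str) -> "HyperParamGrid":
    if family_name == "knn":
        configs = [{"n_neighbors": k} for k in (25, 15, 9, 5, 3, 1)]
    elif family_name in ("logistic_regression",):
        configs = [{"C": c} for c in (0.01, 0.1, 1.0, 10.0)]
    elif family_name == "builtin_linear":
        configs = [{"l2": l2} for l2 in (10.0, 1.0, 0.1, 0.01)]
    elif family_name == "lda":
        configs = [{"solver": "lsqr", "shrinkage": s} for s in (0.9, 0.5, 0.1, 0.0)]
    elif family_name == "qda":
        configs = [{"reg_param": r} for r in (0.9, 0.5, 0.1, 0.0)]
    elif family_name == "adaboost":
        configs = [{"n_estimators": n} for n in (10, 25, 50, 100)]
    elif family_name in ("gradient_boosting", "xgboost", "lightgbm"):
        configs = [
            {"n_estimators": n, "max_depth": d}
            for n, d in product((50, 100), (1, 2, 3))
        ]
        configs.sort(key=lambda c: (c["max_depth"], c["n_estimators"]))
    elif family_name in ("extra_trees", "random_forest"):
        configs = [
            {"n_estimators": n, "max_depth": d}
            for n, d in product((50, 100), (2, 5, None))
        ]
        configs.sort(key=lambda c: (np.inf if c["max_depth"] is None else c["max_depth"],
                                    c["n_estimators"]))
    else:
        raise ValueError(f"unknown model family '{family_name}'")
    return HyperParamGrid(family_name=family_name, configs=configs)


@dataclass
class HyperParamGrid:
    """Ordered configurations for one family; position = capacity index."""

    family_name: str
    configs: list[dict]

    def __post_init__(self) -> None:
        if not self.configs:
            raise ValueError("grid must contain at least one configuration")
        self.capacity_index = list(range(len(self.configs)))

    def __len__(self) -> int:
        return len(self.configs)


def serialized_size(adapter: ModelAdapter) -> int:
    """Byte length of the canonical binary serialization of a fitted model."""
    if not adapter.is_fitted:
        raise RuntimeError("adapter must be fitted before measuring its size")
    return len(pickle.dumps(adapter.estimator_))
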