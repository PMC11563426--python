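"""Stacked-generalisation classifier for peptide feature matrices.

The default configuration trains five base learners — random forest, decision
tree, support-vector machine, k-nearest neighbours, and a gradient-boosting
machine (LightGBM) — and a logistic-regression meta-learner. Meta-features
are **out-of-fold** base-learner positive-class probabilities: the training
data is split into ``internal_folds`` stratified folds and each base learner
predicts each fold while trained on the others, so the meta-learner never
sees a base prediction made on data the base learner was fitted on (naive
same-data stacking overfits). For final prediction the base learners are
refitted on the full training data.

All stochastic components draw seeds from one master seed through a fixed
splitting rule (``numpy`` SeedSequence spawning in learner order), so a refit
with the same seed reproduces predictions exactly.

An extreme-gradient-boosting learner (XGBoost) can be enabled as an optional
sixth base learner when the ``xgboost`` package is installed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Any

import joblib
import numpy as np
from sklearn.base import clone
from sklearn.calibration import CalibratedClassifierCV
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedKFold
from sklearn.neighbors import KNeighborsClassifier
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier

from pepstack.encoders import FeatureMatrix

# lightgbm's sklearn wrapper warns about feature names on ndarray input;
# all pepstack matrices carry names externally (FeatureMatrix.col_names)
warnings.filterwarnings(
    "ignore", message="X does not have valid feature names", category=UserWarning
)

_FORMAT_VERSION = 1

KINDS = (
    "random-forest",
    "decision-tree",
    "support-vector-machine",
    "k-nearest-neighbors",
    "gradient-boosting-machine",
    "extreme-gradient-boosting",
    "logistic-regression",
)

#: the five-learner default ensemble
DEFAULT_BASE_KINDS = (
    "random-forest",
    "decision-tree",
    "support-vector-machine",
    "k-nearest-neighbors",
    "gradient-boosting-machine",
)

_SEEDED_KINDS = {
    "random-forest",
    "decision-tree",
    "support-vector-machine",  # probability calibration shuffles internally
    "gradient-boosting-machine",
    "extreme-gradient-boosting",
    "logistic-regression",
}


def default_hyperparameters(kind: str) -> dict[str, Any]:
    """Tuned defaults per learner kind.

    Random forest: max_depth 30, min_samples_split 5, 300 trees. Decision
    tree: entropy criterion, min_samples_split 5, random splitter. SVM and
    the gradient-boosting machine run library defaults, with probability
    outputs enabled for the SVM (internal cross-validated Platt calibration).
    k-NN and logistic regression use documented library defaults
    (n_neighbors 5; L2-regularised logistic regression, C=1).
    """
    if kind == "random-forest":
        return {"max_depth": 30, "min_samples_split": 5, "n_estimators": 300}
    if kind == "decision-tree":
        return {"criterion": "entropy", "min_samples_split": 5, "splitter": "random"}
    if kind == "support-vector-machine":
        return {}
    if kind == "k-nearest-neighbors":
        return {"n_neighbors": 5}
    if kind == "gradient-boosting-machine":
        return {"verbose": -1}
    if kind == "extreme-gradient-boosting":
        return {"eval_metric": "logloss"}
    if kind == "logistic-regression":
        return {"max_iter": 1000}
    raise ValueError(f"unknown learner kind: {kind!r}")


def _estimator(kind: str, hyper: dict[str, Any], seed: int | None):
    params = {**default_hyperparameters(kind), **hyper}
    if kind in _SEEDED_KINDS and seed is not None:
        params.setdefault("random_state", seed)
    if kind == "random-forest":
        return RandomForestClassifier(**params)
    if kind == "decision-tree":
        return DecisionTreeClassifier(**params)
    if kind == "support-vector-machine":
        # probability outputs via internal cross-validated Platt calibration
        return CalibratedClassifierCV(SVC(**params), ensemble=False)
    if kind == "k-nearest-neighbors":
        return KNeighborsClassifier(**params)
    if kind == "gradient-boosting-machine":
        from lightgbm import LGBMClassifier

        return LGBMClassifier(**params)
    if kind == "extreme-gradient-boosting":
        from xgboost import XGBClassifier

        return XGBClassifier(**params)
    if kind == "logistic-regression":
        return LogisticRegression(**params)
    raise ValueError(f"unknown learner kind: {kind!r}")


@dataclass(frozen=True)
class BaseLearnerConfig:
    """One base learner: kind, hyperparameter overrides, enabled flag."""

    kind: str
    hyperparameters: dict[str, Any] = field(default_factory=dict)
    enabled: bool = True

    def __post_init__(self) -> None:
        if self.kind not in KINDS:
            raise ValueError(f"unknown learner kind: {self.kind!r}; known: {KINDS}")
        # validate hyperparameter names against the learner's estimator
        if self.kind == "support-vector-machine":
            valid = set(SVC().get_params())  # overrides target the inner SVC
        else:
            valid = set(_estimator(self.kind, {}, None).get_params())
        unknown = set(self.hyperparameters) - valid
        if unknown:
            raise ValueError(
                f"{self.kind}: unknown hyperparameter(s) {sorted(unknown)}"
            )


def default_base_configs() -> list[BaseLearnerConfig]:
    return [BaseLearnerConfig(kind) for kind in DEFAULT_BASE_KINDS]


@dataclass
class StackingModel:
    """Configuration plus (after fitting) persistable fitted state."""

    base_configs: list[BaseLearnerConfig] = field(default_factory=default_base_configs)
    meta_hyperparameters: dict[str, Any] = field(default_factory=dict)
    internal_folds: int = 5
    meta_feature_mode: str = "probability"  # or "hard-label"
    seed: int = 0
    # fitted state
    fitted_base: list[Any] | None = None
    fitted_meta: Any | None = None
    feature_names: list[str] | None = None

    def __post_init__(self) -> None:
        if self.meta_feature_mode not in ("probability", "hard-label"):
            raise ValueError("meta_feature_mode must be 'probability' or 'hard-label'")
        if self.internal_folds < 2:
            raise ValueError("internal_folds must be >= 2")

    @property
    def enabled_configs(self) -> list[BaseLearnerConfig]:
        return [c for c in self.base_configs if c.enabled]

    @property
    def is_fitted(self) -> bool:
        return self.fitted_meta is not None


def _learner_seeds(master_seed: int, n: int) -> list[int]:
    """Deterministic per-learner seeds spawned from the master seed."""
    ss = np.random.SeedSequence(master_seed)
    return [int(child.generate_state(1)[0] % (2**31 - 1)) for child in ss.spawn(n)]


def _check_fit_inputs(m: FeatureMatrix, labels: np.ndarray) -> np.ndarray:
    labels = np.asarray(labels, dtype=int)
    if labels.shape[0] != m.shape[0]:
        raise ValueError("labels length must match matrix rows")
    if np.isnan(m.values).any():
        raise ValueError("feature matrix contains NaN")
    classes, counts = np.unique(labels, return_counts=True)
    if len(classes) < 2:
        raise ValueError("training data contains a single class")
    if counts.min() < 2:
        raise ValueError("each class needs >= 2 rows")
    return labels


def _positive_scores(est, X: np.ndarray) -> np.ndarray:
    proba = est.predict_proba(X)
    pos_col = list(est.classes_).index(1)
    return proba[:, pos_col]


def _meta_features(
    model: StackingModel, ests: list[Any], X: np.ndarray
) -> np.ndarray:
    cols = []
    for est in ests:
        if model.meta_feature_mode == "probability":
            cols.append(_positive_scores(est, X))
        else:
            cols.append(est.predict(X).astype(float))
    return np.column_stack(cols)


def fit_stacking(
    m: FeatureMatrix, labels: np.ndarray, model: StackingModel | None = None
) -> StackingModel:
    """Fit the stacking ensemble; returns a new fitted model.

    Base learners are cross-fitted (stratified ``internal_folds``-fold) to
    produce the out-of-fold meta-feature matrix — one column per enabled base
    learner — on which the logistic-regression meta-learner is trained. The
    base learners are then refitted on all training rows for use at predict
    time.
    """
    if model is None:
        model = StackingModel()
    labels = _check_fit_inputs(m, labels)
    configs = model.enabled_configs
    if not configs:
        raise ValueError("no enabled base learners")
    seeds = _learner_seeds(model.seed, len(configs) + 2)
    X = m.values
    n = X.shape[0]
    skf = StratifiedKFold(
        n_splits=model.internal_folds, shuffle=True, random_state=seeds[-2]
    )
    oof = np.zeros((n, len(configs)))
    templates = [
        _estimator(c.kind, c.hyperparameters, seeds[j]) for j, c in enumerate(configs)
    ]
    for tr, te in skf.split(X, labels):
        for j, tmpl in enumerate(templates):
            est = clone(tmpl)
            est.fit(X[tr], labels[tr])
            if model.meta_feature_mode == "probability":
                oof[te, j] = _positive_scores(est, X[te])
            else:
                oof[te, j] = est.predict(X[te]).astype(float)
    meta = LogisticRegression(
        **{**default_hyperparameters("logistic-regression"),
           **model.meta_hyperparameters, "random_state": seeds[-1]}
    )
    meta.fit(oof, labels)
    fitted_base = []
    for tmpl in templates:
        est = clone(tmpl)
        est.fit(X, labels)
        fitted_base.append(est)
    return replace(
        model,
        fitted_base=fitted_base,
        fitted_meta=meta,
        feature_names=list(m.col_names),
    )


def predict_stacking(
    model: StackingModel, m: FeatureMatrix
) -> tuple[np.ndarray, np.ndarray]:
    """Predict labels and positive-class scores for a fitted stacking model.

    Input columns are realigned to the training columns by name; a mismatch
    raises with the missing/extra names. Label = score >= 0.5.
    """
    if not model.is_fitted:
        raise ValueError("model is not fitted")
    m = m.reorder_columns(model.feature_names)
    Z = _meta_features(model, model.fitted_base, m.values)
    scores = _positive_scores(model.fitted_meta, Z)
    return (scores >= 0.5).astype(int), scores


def fit_single(
    m: FeatureMatrix, labels: np.ndarray, config: BaseLearnerConfig, seed: int = 0
):
    """Fit one base learner on the full training data (no meta layer)."""
    labels = _check_fit_inputs(m, labels)
    est = _estimator(config.kind, config.hyperparameters, _learner_seeds(seed, 1)[0])
    est.fit(m.values, labels)
    return _SingleModel(est, list(m.col_names), config, seed)


@dataclass
class _SingleModel:
    """A fitted single learner with the same predict surface as the stack."""

    estimator: Any
    feature_names: list[str]
    config: BaseLearnerConfig
    seed: int

    def predict(self, m: FeatureMatrix) -> tuple[np.ndarray, np.ndarray]:
        m = m.reorder_columns(self.feature_names)
        scores = _positive_scores(self.estimator, m.values)
        return (scores >= 0.5).astype(int), scores


def save_model(model: StackingModel | _SingleModel, path: str | Path,
               metadata: dict | None = None) -> None:
    """Persist a fitted model (config, columns, seeds, fitted state) to one file."""
    payload = {
        "format_version": _FORMAT_VERSION,
        "model": model,
        "metadata": metadata or {},
    }
    joblib.dump(payload, path)


def load_model(path: str | Path):
    """Load a model persisted by :func:`save_model`."""
    payload = joblib.load(path)
    if payload.get("format_version") != _FORMAT_VERSION:
        raise ValueError(f"unsupported model file version: {payload.get('format_version')}")
    return payload["model"]
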