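"""Evaluation harness: confusion metrics, ROC/AUC, CV and split protocols.

Metrics are the standard confusion-matrix closed forms, with the positive
class being the minority of interest (e.g. IL-10-inducing):

    Sn  = TP / (TP + FN)                     (sensitivity, true-positive rate)
    Sp  = TN / (TN + FP)                     (specificity, true-negative rate)
    ACC = (TP + TN) / (TP + FP + TN + FN)
    MCC = (TP*TN - FP*FN) / sqrt((TP+FP)(TP+FN)(TN+FP)(TN+FN))

All metrics are computed and reported as fractions in [0, 1] (MCC in
[-1, 1]); a percent presentation is a display option only. AUC is the
rank-statistic (Mann–Whitney) formulation: the probability that a random
positive outscores a random negative, ties counted half.

Two protocols are provided: stratified k-fold cross-validation (default
k = 10) and a stratified 80/20 train/test split. Oversampling is applied
inside each training portion only by default (``scope="fold-internal"``), so
synthetic points never leak into evaluation folds; a ``scope="global"`` mode
that balances before splitting exists for comparison with studies that did
so, and inflates metrics accordingly.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Any

import numpy as np
from sklearn.metrics import roc_auc_score, roc_curve
from sklearn.model_selection import StratifiedKFold, train_test_split

from pepstack.balancing import oversample
from pepstack.encoders import EncoderSpec, FeatureMatrix, encode_dataset
from pepstack.ensemble import (
    BaseLearnerConfig,
    StackingModel,
    fit_single,
    fit_stacking,
    predict_stacking,
)
from pepstack.peptide_io import LabeledDataset


@dataclass(frozen=True)
class ConfusionCounts:
    TP: int
    FP: int
    TN: int
    FN: int

    def __post_init__(self) -> None:
        for name in ("TP", "FP", "TN", "FN"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative")

    @property
    def total(self) -> int:
        return self.TP + self.FP + self.TN + self.FN


def confusion(labels_true: np.ndarray, labels_pred: np.ndarray) -> ConfusionCounts:
    """2x2 cross-tabulation with positive = 1."""
    t = np.asarray(labels_true)
    p = np.asarray(labels_pred)
    if t.shape != p.shape:
        raise ValueError(f"length mismatch: {t.shape} vs {p.shape}")
    if t.size == 0:
        raise ValueError("empty label vectors")
    for v, name in ((t, "labels_true"), (p, "labels_pred")):
        if not np.isin(v, (0, 1)).all():
            raise ValueError(f"{name} must be binary")
    return ConfusionCounts(
        TP=int(((t == 1) & (p == 1)).sum()),
        FP=int(((t == 0) & (p == 1)).sum()),
        TN=int(((t == 0) & (p == 0)).sum()),
        FN=int(((t == 1) & (p == 0)).sum()),
    )


def metrics_from_confusion(c: ConfusionCounts) -> dict[str, float]:
    """Sensitivity, specificity, accuracy and MCC as fractions.

    A zero denominator in Sn or Sp yields NaN (undefined); a zero MCC
    denominator yields MCC = 0 by convention.
    """
    if c.total == 0:
        raise ValueError("empty confusion table")
    tp, fp, tn, fn = float(c.TP), float(c.FP), float(c.TN), float(c.FN)
    sn = tp / (tp + fn) if (tp + fn) > 0 else math.nan
    sp = tn / (tn + fp) if (tn + fp) > 0 else math.nan
    acc = (tp + tn) / c.total
    denom = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    mcc = (tp * tn - fp * fn) / math.sqrt(denom) if denom > 0 else 0.0
    return {"sensitivity": sn, "specificity": sp, "accuracy": acc, "mcc": mcc}


def roc_auc(labels_true: np.ndarray, scores: np.ndarray) -> float:
    """Area under the ROC curve (Mann–Whitney formulation, ties half)."""
    t = np.asarray(labels_true)
    if len(np.unique(t)) < 2:
        raise ValueError("both classes must be present to compute AUC")
    return float(roc_auc_score(t, np.asarray(scores, dtype=float)))


def roc_points(labels_true: np.ndarray, scores: np.ndarray) -> np.ndarray:
    """ROC curve as an array of (false-positive rate, true-positive rate, threshold)."""
    fpr, tpr, thr = roc_curve(np.asarray(labels_true), np.asarray(scores, dtype=float))
    return np.column_stack([fpr, tpr, thr])


def stratified_kfold(
    labels: np.ndarray, k: int = 10, seed: int = 0
) -> list[np.ndarray]:
    """Disjoint stratified fold index sets covering all rows.

    Per-fold class counts are within one instance of the proportional share.
    """
    labels = np.asarray(labels, dtype=int)
    if k < 2:
        raise ValueError("k must be >= 2")
    _, counts = np.unique(labels, return_counts=True)
    if counts.min() < k:
        raise ValueError(f"smallest class has {counts.min()} members; needs >= k = {k}")
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    return [te for _, te in skf.split(np.zeros(len(labels)), labels)]


@dataclass
class BalanceConfig:
    """Oversampling configuration for a protocol run."""

    method: str = "none"  # {"ADASYN", "SMOTE", "none"}
    k: int = 5
    target_ratio: float = 1.0
    scope: str = "fold-internal"  # or "global"
    scale: bool = False

    def __post_init__(self) -> None:
        if self.scope not in ("fold-internal", "global"):
            raise ValueError("scope must be 'fold-internal' or 'global'")


@dataclass
class EvalReport:
    """Per-fold and aggregate evaluation results plus the protocol descriptor."""

    protocol: dict[str, Any]
    fold_metrics: list[dict[str, float]]
    confusions: list[dict[str, int]]
    aggregate: dict[str, float]
    aggregate_mode: str = "fold-mean"  # or "pooled"

    @property
    def n_folds(self) -> int:
        return len(self.fold_metrics)

    def to_json(self, path: str | Path | None = None) -> str:
        s = json.dumps(asdict(self), indent=2, allow_nan=True)
        if path is not None:
            Path(path).write_text(s)
        return s

    @classmethod
    def from_json(cls, source: str | Path) -> "EvalReport":
        p = Path(str(source))
        text = p.read_text() if p.exists() else str(source)
        d = json.loads(text)
        return cls(**d)


def _fold_eval(
    X_tr: FeatureMatrix,
    y_tr: np.ndarray,
    X_te: FeatureMatrix,
    y_te: np.ndarray,
    balance: BalanceConfig,
    model: StackingModel | BaseLearnerConfig,
    seed: int,
) -> tuple[dict[str, float], ConfusionCounts]:
    if balance.method != "none" and balance.scope == "fold-internal":
        rs = oversample(
            X_tr, y_tr, method=balance.method, k=balance.k,
            target_ratio=balance.target_ratio, seed=seed, scale=balance.scale,
        )
        X_tr, y_tr = rs.matrix, rs.labels
    if isinstance(model, BaseLearnerConfig):
        fitted = fit_single(X_tr, y_tr, model, seed=seed)
        pred, scores = fitted.predict(X_te)
    else:
        template = StackingModel(
            base_configs=model.base_configs,
            meta_hyperparameters=model.meta_hyperparameters,
            internal_folds=model.internal_folds,
            meta_feature_mode=model.meta_feature_mode,
            seed=seed,
        )
        fitted = fit_stacking(X_tr, y_tr, template)
        pred, scores = predict_stacking(fitted, X_te)
    c = confusion(y_te, pred)
    met = metrics_from_confusion(c)
    met["auc"] = roc_auc(y_te, scores) if len(np.unique(y_te)) == 2 else math.nan
    return met, c


_METRIC_KEYS = ("accuracy", "mcc", "auc", "sensitivity", "specificity")


def run_protocol(
    dataset: LabeledDataset,
    specs: list[EncoderSpec],
    balance: BalanceConfig | None = None,
    model: StackingModel | BaseLearnerConfig | None = None,
    protocol: str = "cv10",
    seed: int = 0,
    aggregate_mode: str = "fold-mean",
) -> EvalReport:
    """Run the full evaluation pipeline: encode, split, balance, fit, score.

    ``protocol`` is ``"cv10"`` (stratified 10-fold; ``"cv<k>"`` for other k)
    or ``"split80_20"`` (stratified hold-out). With fold-internal balancing
    (the default scope) oversampling sees only each fold's training portion.
    With ``scope="global"`` the whole encoded dataset is balanced before
    splitting. ``aggregate_mode`` is the unweighted mean of per-fold metrics
    or ``"pooled"`` (metrics of the summed confusion table; pooled AUC
    concatenates scores across folds).
    """
    balance = balance or BalanceConfig()
    model = model or StackingModel()
    matrix = encode_dataset(dataset, specs)
    labels = dataset.labels.copy()
    if balance.method != "none" and balance.scope == "global":
        rs = oversample(
            matrix, labels, method=balance.method, k=balance.k,
            target_ratio=balance.target_ratio, seed=seed, scale=balance.scale,
        )
        matrix, labels = rs.matrix, rs.labels

    def sub(idx: np.ndarray) -> FeatureMatrix:
        return FeatureMatrix(
            [matrix.row_ids[i] for i in idx], list(matrix.col_names), matrix.values[idx]
        )

    splits: list[tuple[np.ndarray, np.ndarray]] = []
    if protocol.startswith("cv"):
        k = int(protocol[2:] or 10)
        folds = stratified_kfold(labels, k=k, seed=seed)
        all_idx = np.arange(len(labels))
        for te in folds:
            tr = np.setdiff1d(all_idx, te)
            splits.append((tr, te))
    elif protocol == "split80_20":
        tr, te = train_test_split(
            np.arange(len(labels)), test_size=0.2, stratify=labels, random_state=seed
        )
        splits.append((np.sort(tr), np.sort(te)))
    else:
        raise ValueError(f"unknown protocol: {protocol!r}")

    fold_metrics, confusions, all_scores, all_true = [], [], [], []
    for fold_i, (tr, te) in enumerate(splits):
        met, c = _fold_eval(
            sub(tr), labels[tr], sub(te), labels[te], balance, model,
            seed=seed + fold_i,
        )
        fold_metrics.append(met)
        confusions.append({"TP": c.TP, "FP": c.FP, "TN": c.TN, "FN": c.FN})

    if aggregate_mode == "fold-mean":
        aggregate = {
            k: float(np.mean([m[k] for m in fold_metrics])) for k in _METRIC_KEYS
        }
    elif aggregate_mode == "pooled":
        pooled = ConfusionCounts(
            TP=sum(c["TP"] for c in confusions),
            FP=sum(c["FP"] for c in confusions),
            TN=sum(c["TN"] for c in confusions),
            FN=sum(c["FN"] for c in confusions),
        )
        aggregate = metrics_from_confusion(pooled)
        aggregate["auc"] = float(np.mean([m["auc"] for m in fold_metrics]))
    else:
        raise ValueError(f"unknown aggregate_mode: {aggregate_mode!r}")

    model_desc = (
        {"type": "single", "kind": model.kind}
        if isinstance(model, BaseLearnerConfig)
        else {
            "type": "stacking",
            "base": [c.kind for c in model.enabled_configs],
            "internal_folds": model.internal_folds,
            "meta_feature_mode": model.meta_feature_mode,
        }
    )
    report = EvalReport(
        protocol={
            "protocol": protocol,
            "n_folds": len(splits),
            "seed": seed,
            "balance": asdict(balance),
            "model": model_desc,
            "encoders": [s.to_dict() for s in specs],
        },
        fold_metrics=fold_metrics,
        confusions=confusions,
        aggregate=aggregate,
        aggregate_mode=aggregate_mode,
    )
    return report


def percent(metrics: dict[str, float]) -> dict[str, float]:
    """Presentation helper: fractions scaled to percentages (MCC left as-is)."""
    return {
        k: (v * 100.0 if k != "mcc" and not math.isnan(v) else v)
        for k, v in metrics.items()
    }
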