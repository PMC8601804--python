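"""Evaluation: confusion matrices, per-class/mean accuracy, stratified
k-fold cross-validation of the whole committee, per-group reporting and
one-vs-rest ROC/AUC.

Mean accuracy is the *unweighted* mean of per-class (row-wise) accuracies,
not pooled accuracy — the convention used in the reference results this
module reproduces.  Formatted accuracies are truncated (not rounded) to
four decimals, matching the same convention; full precision is kept
internally.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.metrics import auc as _auc
from sklearn.metrics import roc_curve
from sklearn.model_selection import StratifiedKFold

from .features import FeatureMatrix
from .gsvn import GsvnConfig, GsvnModel, StratificationError, grid_search, predict, train_gsvn


def truncate4(x: float) -> float:
    """Truncate toward zero to 4 decimals (178/186 -> 0.9569, not 0.9570)."""
    return math.trunc(x * 10000.0) / 10000.0


@dataclass
class ConfusionMatrix:
    """K x K counts; rows are actual classes, columns predicted."""

    counts: np.ndarray
    classes: list[str]

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        k = len(self.classes)
        if self.counts.shape != (k, k):
            raise ValueError(f"counts must be {k}x{k}, got {self.counts.shape}")
        if (self.counts < 0).any():
            raise ValueError("counts must be non-negative")

    def row_sums(self) -> np.ndarray:
        return self.counts.sum(axis=1)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=self.classes, columns=self.classes)


class UndefinedClassError(ValueError):
    """Raised when a class has no actual samples in the confusion matrix."""


def confusion(actual, predicted, classes: list[str]) -> ConfusionMatrix:
    """Count matrix with counts[a][p] = #{i : actual_i = a and predicted_i = p}."""
    actual = list(actual)
    predicted = list(predicted)
    if len(actual) != len(predicted):
        raise ValueError(f"length mismatch: {len(actual)} actual vs {len(predicted)} predicted")
    idx = {c: i for i, c in enumerate(classes)}
    counts = np.zeros((len(classes), len(classes)), dtype=np.int64)
    for a, p in zip(actual, predicted):
        counts[idx[a], idx[p]] += 1
    return ConfusionMatrix(counts, list(classes))


def accuracies(cm: ConfusionMatrix) -> tuple[dict[str, float], float]:
    """Per-class (row-wise) accuracies and their unweighted mean."""
    sums = cm.row_sums()
    for c, s in zip(cm.classes, sums):
        if s == 0:
            raise UndefinedClassError(f"class {c!r} has no actual samples")
    per_class = {
        c: float(cm.counts[i, i] / sums[i]) for i, c in enumerate(cm.classes)
    }
    mean = float(np.mean(list(per_class.values())))
    return per_class, mean


def grouped_report(actual, predicted, groups) -> pd.DataFrame:
    """Correct / incorrect / total / accuracy per group (e.g. per sex)."""
    df = pd.DataFrame({"actual": list(actual), "predicted": list(predicted),
                       "group": list(groups)})
    rows = []
    for g, grp in df.groupby("group", sort=True):
        correct = int((grp["actual"] == grp["predicted"]).sum())
        total = len(grp)
        rows.append(
            {
                "group": g,
                "correct": correct,
                "incorrect": total - correct,
                "total": total,
                "accuracy": correct / total,
                "accuracy_display": truncate4(correct / total),
            }
        )
    return pd.DataFrame(rows)


def roc_ovr(actual, vote_scores: np.ndarray, classes: list[str]) -> dict:
    """One-vs-rest ROC curves and AUCs from normalized vote scores."""
    actual = np.asarray(list(actual))
    scores = np.asarray(vote_scores, dtype=np.float64)
    out: dict = {"per_class": {}, "macro_auc": None}
    aucs = []
    for k, c in enumerate(classes):
        y_bin = (actual == c).astype(int)
        fpr, tpr, _ = roc_curve(y_bin, scores[:, k])
        a = float(_auc(fpr, tpr))
        out["per_class"][c] = {"fpr": fpr.tolist(), "tpr": tpr.tolist(), "auc": a}
        aucs.append(a)
    out["macro_auc"] = float(np.mean(aucs))
    return out


@dataclass
class EvalReport:
    confusion: ConfusionMatrix
    per_class_accuracy: dict[str, float]
    mean_accuracy: float
    fold_results: list[dict] = field(default_factory=list)
    auc: dict = field(default_factory=dict)
    oof_predictions: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "classes": self.confusion.classes,
            "confusion": self.confusion.counts.tolist(),
            "per_class_accuracy": {
                c: self.per_class_accuracy[c] for c in self.confusion.classes
            },
            "per_class_accuracy_display": {
                c: truncate4(self.per_class_accuracy[c]) for c in self.confusion.classes
            },
            "mean_accuracy": self.mean_accuracy,
            "mean_accuracy_display": truncate4(self.mean_accuracy),
            "fold_results": self.fold_results,
            "oof_predictions": self.oof_predictions,
            "auc": {
                "macro": self.auc.get("macro_auc"),
                "per_class": {
                    c: v["auc"] for c, v in self.auc.get("per_class", {}).items()
                },
            },
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2, sort_keys=True)


def report_from_predictions(actual, predicted, classes, scores=None) -> EvalReport:
    cm = confusion(actual, predicted, classes)
    per_class, mean = accuracies(cm)
    roc = roc_ovr(actual, scores, classes) if scores is not None else {}
    return EvalReport(cm, per_class, mean, auc=roc)


def kfold_cv(
    features: FeatureMatrix,
    config: GsvnConfig | None = None,
    k: int = 10,
    seed: int = 0,
) -> EvalReport:
    """Stratified k-fold cross-validation of the whole committee.

    Each row is validated exactly once; a fresh committee is trained per
    fold and out-of-fold predictions are pooled into a single confusion
    matrix.  When (C, gamma) are unset, one grid search on the full data
    picks the shared pair before the folds run.
    """
    config = config or GsvnConfig()
    if features.labels is None:
        raise ValueError("feature matrix has no labels")
    y = features.labels.to_numpy().astype(str)
    classes = sorted(set(y))
    counts = pd.Series(y).value_counts()
    if counts.min() < k:
        raise StratificationError(
            f"class {counts.idxmin()!r} has {counts.min()} rows < k={k}"
        )
    C, gamma = config.C, config.gamma
    if C is None or gamma is None:
        C, gamma = grid_search(
            features, config.C_grid, config.gamma_grid, config.grid_folds, seed=seed
        )
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    n = len(features)
    oof_pred = np.empty(n, dtype=object)
    oof_scores = np.zeros((n, len(classes)))
    fold_results = []
    for fold, (tr, va) in enumerate(skf.split(features.X, y)):
        model = train_gsvn(
            features.take(tr),
            n_members=config.n_members,
            C=C,
            gamma=gamma,
            split=config.split,
            seed=seed + fold,
            mode=config.mode,
            unit=config.unit,
        )
        labels, scores = predict(model, features.take(va))
        oof_pred[va] = labels
        oof_scores[va] = scores
        fold_cm = confusion(y[va], labels, classes)
        _, fold_mean = accuracies(fold_cm)
        fold_results.append(
            {
                "fold": fold,
                "confusion": fold_cm.counts.tolist(),
                "mean_accuracy": fold_mean,
                "val_indices": [int(i) for i in va],
            }
        )
    cm = confusion(y, list(oof_pred), classes)
    per_class, mean = accuracies(cm)
    roc = roc_ovr(y, oof_scores, classes)
    report = EvalReport(
        cm, per_class, mean,
        fold_results=fold_results,
        auc=roc,
        oof_predictions=[str(p) for p in oof_pred],
    )
    report.grid = {"C": C, "gamma": gamma}  # type: ignore[attr-defined]
    return report
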