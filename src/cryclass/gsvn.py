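"""Grouped-support-vector network.

A committee of RBF-kernel support-vector classifiers combined by weighted
majority voting.  Members are trained on bootstrap resamples drawn
proportionally to boosting weights: after each member is fit, training rows
it misclassifies are upweighted, and the member's vote weight is the
multiclass boosting weight ln((1 - eps) / eps) + ln(K - 1) earned on its
held-out 20% split.  A plain-bagging mode (uniform resampling, vote weight
= validation accuracy) is available for ablation.

Features are z-scored with statistics from each member's fit split; RBF
kernels are scale-sensitive.
"""

from __future__ import annotations

import json
import math
import pickle
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.model_selection import StratifiedKFold, train_test_split
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .features import FeatureMatrix

DEFAULT_C_GRID = (1.0, 3.0, 33.0)
DEFAULT_GAMMA_GRID = tuple(round(0.1 * k, 1) for k in range(1, 51))

MAX_VOTE_WEIGHT = math.log(1e6)


class SchemaError(ValueError):
    """Raised when prediction rows do not match the model's feature schema."""


class StratificationError(ValueError):
    """Raised when a class is too small for the requested stratified split."""


@dataclass
class MemberModel:
    scaler: StandardScaler
    svm: SVC
    C: float
    gamma: float
    vote_weight: float
    val_accuracy: float

    def predict(self, X: np.ndarray) -> np.ndarray:
        return self.svm.predict(self.scaler.transform(X))


@dataclass
class GsvnModel:
    members: list[MemberModel]
    classes: list[str]
    schema: list[str]
    grid: dict
    unit: str
    seed: int

    def __post_init__(self) -> None:
        if not self.members:
            raise ValueError("GsvnModel requires at least one member")

    def save(self, path) -> None:
        with open(path, "wb") as fh:
            pickle.dump(self, fh)

    def save_metadata(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(
                {
                    "classes": self.classes,
                    "schema": self.schema,
                    "grid": self.grid,
                    "unit": self.unit,
                    "seed": self.seed,
                    "n_members": len(self.members),
                    "vote_weights": [m.vote_weight for m in self.members],
                    "val_accuracies": [m.val_accuracy for m in self.members],
                },
                fh,
                indent=2,
                sort_keys=True,
            )

    @classmethod
    def load(cls, path) -> "GsvnModel":
        with open(path, "rb") as fh:
            model = pickle.load(fh)
        if not isinstance(model, cls):
            raise TypeError(f"{path} does not contain a GsvnModel")
        return model


@dataclass
class GsvnConfig:
    """Training configuration for the committee."""

    n_members: int = 300
    C: float | None = None  # None -> grid search
    gamma: float | None = None
    C_grid: tuple[float, ...] = DEFAULT_C_GRID
    gamma_grid: tuple[float, ...] = DEFAULT_GAMMA_GRID
    split: float = 0.8
    mode: str = "boost"  # "boost" or "bag"
    grid_folds: int = 3
    unit: str = "clip"


def boosting_vote_weight(eps: float, n_classes: int) -> float:
    """Multiclass boosting vote weight ln((1 - eps)/eps) + ln(K - 1).

    Floored at 0; capped at ln(1e6) as eps -> 0; 0 for members no better
    than chance (eps >= (K-1)/K).
    """
    if eps >= (n_classes - 1) / n_classes:
        return 0.0
    if eps <= 0.0:
        return MAX_VOTE_WEIGHT
    w = math.log((1.0 - eps) / eps) + math.log(n_classes - 1)
    return float(np.clip(w, 0.0, MAX_VOTE_WEIGHT))


def _check_xy(features: FeatureMatrix) -> tuple[np.ndarray, np.ndarray, list[str]]:
    if features.labels is None:
        raise ValueError("feature matrix has no labels")
    X = features.X.to_numpy(dtype=np.float64)
    y = features.labels.to_numpy().astype(str)
    classes = sorted(set(y))
    if len(classes) < 2:
        raise StratificationError(f"need >= 2 classes, got {classes}")
    return X, y, classes


def grid_search(
    train: FeatureMatrix,
    C_grid: tuple[float, ...] = DEFAULT_C_GRID,
    gamma_grid: tuple[float, ...] = DEFAULT_GAMMA_GRID,
    folds: int = 3,
    seed: int = 0,
) -> tuple[float, float]:
    """Pick (C, gamma) maximizing mean stratified-CV accuracy.

    Ties are broken toward smaller C, then smaller gamma (the grids are
    scanned in ascending order and only strict improvements replace the
    incumbent).
    """
    X, y, classes = _check_xy(train)
    counts = pd.Series(y).value_counts()
    if counts.min() < folds:
        raise StratificationError(
            f"class {counts.idxmin()!r} has {counts.min()} rows < {folds} folds"
        )
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    splits = list(skf.split(X, y))
    best = (-1.0, None, None)
    for C in sorted(C_grid):
        for gamma in sorted(gamma_grid):
            accs = []
            for tr, va in splits:
                scaler = StandardScaler().fit(X[tr])
                svc = SVC(kernel="rbf", C=C, gamma=gamma).fit(scaler.transform(X[tr]), y[tr])
                accs.append(float(np.mean(svc.predict(scaler.transform(X[va])) == y[va])))
            score = float(np.mean(accs))
            if score > best[0]:
                best = (score, C, gamma)
    return best[1], best[2]


def _fit_member(
    X: np.ndarray, y: np.ndarray, C: float, gamma: float
) -> tuple[StandardScaler, SVC]:
    scaler = StandardScaler().fit(X)
    svc = SVC(kernel="rbf", C=C, gamma=gamma, decision_function_shape="ovo")
    svc.fit(scaler.transform(X), y)
    return scaler, svc


def _weighted_resample(
    rng: np.random.Generator, n: int, w: np.ndarray, y: np.ndarray, min_per_class: int
) -> np.ndarray:
    """Draw a bootstrap resample; redraw if a class gets too thin to split."""
    for _ in range(20):
        idx = rng.choice(n, size=n, p=w)
        counts = pd.Series(y[idx]).value_counts()
        if len(counts) == len(set(y)) and counts.min() >= min_per_class:
            return idx
    return rng.choice(n, size=n)  # fall back to uniform


def train_gsvn(
    train: FeatureMatrix,
    n_members: int = 300,
    C: float = 1.0,
    gamma: float = 0.1,
    split: float = 0.8,
    seed: int = 0,
    mode: str = "boost",
    unit: str = "clip",
) -> GsvnModel:
    """Train the boosted SVM committee.

    Each round draws a weight-proportional bootstrap resample of the
    training rows, splits it 80:20 stratified, fits an RBF SVM on the 80%
    and scores it on the 20%.  The validation error (weighted by the
    current boosting weights of the validation rows) sets the member's vote
    weight; misclassified training rows are upweighted for the next round.
    Members no better than chance get vote weight 0 and reset the weights.
    """
    X, y, classes = _check_xy(train)
    n = len(y)
    K = len(classes)
    counts = pd.Series(y).value_counts()
    min_needed = max(int(math.ceil(1.0 / (1.0 - split))), 2)
    if counts.min() < min_needed or n < 10:
        raise StratificationError(
            f"class {counts.idxmin()!r} has {counts.min()} rows; too few for a "
            f"stratified {split:.0%} split"
        )
    rng = np.random.default_rng(seed)
    w = np.full(n, 1.0 / n)
    members: list[MemberModel] = []
    for _ in range(n_members):
        idx = _weighted_resample(rng, n, w if mode == "boost" else np.full(n, 1.0 / n),
                                 y, min_per_class=min_needed)
        fit_idx, val_idx = train_test_split(
            idx,
            test_size=1.0 - split,
            stratify=y[idx],
            random_state=int(rng.integers(2**31)),
        )
        scaler, svc = _fit_member(X[fit_idx], y[fit_idx], C, gamma)
        val_pred = svc.predict(scaler.transform(X[val_idx]))
        mis_val = val_pred != y[val_idx]
        val_acc = float(np.mean(~mis_val))
        if mode == "bag":
            members.append(MemberModel(scaler, svc, C, gamma, val_acc, val_acc))
            continue
        wv = w[val_idx]
        eps = float(np.dot(wv, mis_val) / wv.sum()) if wv.sum() > 0 else float(np.mean(mis_val))
        vote = boosting_vote_weight(eps, K)
        if eps >= (K - 1) / K:
            w = np.full(n, 1.0 / n)
        else:
            mis_all = svc.predict(scaler.transform(X)) != y
            w = w * np.exp(vote * mis_all)
            w = w / w.sum()
        members.append(MemberModel(scaler, svc, C, gamma, vote, val_acc))
    if all(m.vote_weight == 0.0 for m in members):
        # keep the committee usable: fall back to accuracy-proportional votes
        for m in members:
            m.vote_weight = m.val_accuracy
    return GsvnModel(
        members=members,
        classes=classes,
        schema=train.schema,
        grid={"C": C, "gamma": gamma},
        unit=unit,
        seed=seed,
    )


def _check_schema(model: GsvnModel, X: pd.DataFrame) -> np.ndarray:
    missing = [c for c in model.schema if c not in X.columns]
    extra = [c for c in X.columns if c not in model.schema]
    if missing or extra:
        raise SchemaError(f"schema mismatch: missing={missing}, extra={extra}")
    return X[model.schema].to_numpy(dtype=np.float64)


def predict(
    model: GsvnModel, rows: FeatureMatrix | pd.DataFrame
) -> tuple[np.ndarray, np.ndarray]:
    """Weighted-majority-vote prediction.

    Returns (labels, scores) where scores[i, k] is the total vote weight
    for class k on row i, normalized to sum 1 per row; ties go to the
    earlier class in ``model.classes``.
    """
    X_df = rows.X if isinstance(rows, FeatureMatrix) else rows
    X = _check_schema(model, X_df)
    n = len(X)
    scores = np.zeros((n, len(model.classes)))
    for member in model.members:
        if member.vote_weight <= 0.0:
            continue
        pred = member.predict(X)
        for k, c in enumerate(model.classes):
            scores[pred == c, k] += member.vote_weight
    totals = scores.sum(axis=1, keepdims=True)
    zero = totals[:, 0] == 0
    scores[zero] = 1.0 / len(model.classes)
    totals[zero] = 1.0
    scores = scores / totals
    labels = np.array([model.classes[k] for k in scores.argmax(axis=1)])
    return labels, scores


def predict_clip(
    model: GsvnModel, frame_rows: FeatureMatrix
) -> pd.Series:
    """Clip labels from frame-level predictions by weighted plurality.

    Each frame votes for its predicted class with the ensemble score margin
    (top score minus runner-up); ties go to the earlier class in
    ``model.classes``.  Requires frame rows carrying a ``clip_id`` meta
    column.
    """
    if frame_rows.meta is None or "clip_id" not in frame_rows.meta.columns:
        raise ValueError("frame rows need a clip_id meta column")
    labels, scores = predict(model, frame_rows)
    sorted_scores = np.sort(scores, axis=1)
    margins = sorted_scores[:, -1] - sorted_scores[:, -2]
    df = pd.DataFrame(
        {
            "clip_id": frame_rows.meta["clip_id"].to_numpy(),
            "label": labels,
            "margin": margins,
        }
    )
    out: dict[str, str] = {}
    for clip_id, grp in df.groupby("clip_id", sort=False):
        tallies = np.zeros(len(model.classes))
        for k, c in enumerate(model.classes):
            mask = grp["label"] == c
            tallies[k] = grp.loc[mask, "margin"].sum() if mask.any() else 0.0
        if tallies.sum() == 0.0:  # all margins zero: plain frame counts
            for k, c in enumerate(model.classes):
                tallies[k] = (grp["label"] == c).sum()
        out[clip_id] = model.classes[int(tallies.argmax())]
    return pd.Series(out)
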