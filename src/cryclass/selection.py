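"""Random-forest variable selection.

Two steps, mirroring the elimination + interpretation phases of
forest-based variable selection:

1. **Threshold** — features are ranked by out-of-bag permutation importance
   (Breiman's mean decrease in accuracy: the drop in each tree's own
   out-of-bag accuracy when the feature is permuted, averaged over trees —
   the per-tree form does not saturate in the presence of redundant
   informative features the way ensemble-vote accuracy does); a
   data-driven threshold is obtained from decoy runs in which the class
   labels are permuted (the null distribution of importances), and
   features whose importance does not exceed the largest decoy importance
   are eliminated — a shadow-feature rule in the spirit of Boruta.
2. **Interpretation** — nested forests are fit on the top-1, top-2, ...
   surviving features; the smallest subset whose out-of-bag error is within
   one standard deviation of the minimum is kept.

Importance is computed per feature *family* by default (pitch, peak, MFCC,
... as whole blocks, permuted jointly), because selection for this task is
reported at the family level; per-dimension mode is available.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from sklearn.ensemble import RandomForestClassifier

from .features import FeatureMatrix, feature_family


class DegenerateLabelsError(ValueError):
    """Raised when the label vector has fewer than two classes."""


@dataclass
class SelectionResult:
    importances: dict[str, float]
    ranking: list[str]
    threshold_kept: list[str]
    interpretation_set: list[str]
    threshold: float
    ntree: int
    seed: int
    mode: str = "family"
    oob_errors: dict[int, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not set(self.interpretation_set) <= set(self.threshold_kept):
            raise ValueError("interpretation_set must be nested in threshold_kept")
        if not set(self.threshold_kept) <= set(self.ranking):
            raise ValueError("threshold_kept must be nested in ranking")

    def selected_columns(self, features: FeatureMatrix) -> list[str]:
        """Expand selected names back to feature-matrix columns."""
        if self.mode == "dimension":
            return [c for c in features.schema if c in self.interpretation_set]
        chosen = set(self.interpretation_set)
        return [c for c in features.schema if feature_family(c) in chosen]

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(
                {
                    "importances": self.importances,
                    "ranking": self.ranking,
                    "threshold_kept": self.threshold_kept,
                    "interpretation_set": self.interpretation_set,
                    "threshold": self.threshold,
                    "ntree": self.ntree,
                    "seed": self.seed,
                    "mode": self.mode,
                    "oob_errors": {str(k): v for k, v in self.oob_errors.items()},
                },
                fh,
                indent=2,
                sort_keys=True,
            )


# ---------------------------------------------------------------------------
# OOB machinery

def _check_input(features: FeatureMatrix) -> tuple[np.ndarray, np.ndarray, list[str]]:
    if features.labels is None:
        raise DegenerateLabelsError("feature matrix has no labels")
    y_raw = features.labels.to_numpy()
    classes = sorted(set(y_raw))
    if len(classes) < 2:
        raise DegenerateLabelsError(f"need >= 2 classes, got {classes}")
    if len(features) < 10:
        raise ValueError(f"need >= 10 rows for selection, got {len(features)}")
    code = {c: i for i, c in enumerate(classes)}
    y = np.array([code[v] for v in y_raw])
    return features.X.to_numpy(dtype=np.float64), y, classes


def _fit_forest(X: np.ndarray, y: np.ndarray, ntree: int, seed: int) -> RandomForestClassifier:
    forest = RandomForestClassifier(
        n_estimators=ntree, random_state=seed, n_jobs=1, bootstrap=True
    )
    forest.fit(X, y)
    return forest


def _oob_masks(forest: RandomForestClassifier, n: int) -> np.ndarray:
    """Boolean (n_trees, n) matrix, True where a sample is out of bag."""
    masks = np.ones((len(forest.estimators_), n), dtype=bool)
    for i, idx in enumerate(forest.estimators_samples_):
        masks[i, idx] = False
    return masks


def _oob_votes_accuracy(
    forest: RandomForestClassifier,
    masks: np.ndarray,
    X: np.ndarray,
    y: np.ndarray,
    n_classes: int,
) -> float:
    """Accuracy of per-sample majority votes over each sample's OOB trees."""
    n = len(y)
    counts = np.zeros((n, n_classes))
    for i, tree in enumerate(forest.estimators_):
        pred = tree.predict(X).astype(int)
        oob = masks[i]
        np.add.at(counts, (np.flatnonzero(oob), pred[oob]), 1.0)
    has_vote = counts.sum(axis=1) > 0
    if not has_vote.any():
        return 0.0
    vote = counts.argmax(axis=1)
    return float(np.mean(vote[has_vote] == y[has_vote]))


def _block_columns(schema: list[str], mode: str) -> dict[str, list[int]]:
    blocks: dict[str, list[int]] = {}
    for i, col in enumerate(schema):
        name = col if mode == "dimension" else feature_family(col)
        blocks.setdefault(name, []).append(i)
    return blocks


def _block_importances(
    forest: RandomForestClassifier,
    X: np.ndarray,
    y: np.ndarray,
    blocks: dict[str, list[int]],
    n_classes: int,
    n_repeats: int,
    rng: np.random.Generator,
) -> dict[str, float]:
    """Per-tree OOB permutation importance per block (columns permuted jointly).

    importance(block) = mean over trees of (tree's OOB accuracy) minus
    (tree's OOB accuracy with the block permuted), averaged over repeats.
    """
    n = len(y)
    masks = _oob_masks(forest, n)

    names = list(blocks)
    # stack all permuted variants so each tree predicts once
    variants = []
    for name in names:
        cols = blocks[name]
        for _ in range(n_repeats):
            perm = rng.permutation(n)
            Xp = X.copy()
            Xp[:, cols] = Xp[perm][:, cols]
            variants.append(Xp)
    X_stack = np.vstack(variants)
    n_var = len(variants)

    # drop[v] accumulates (baseline - permuted) per-tree accuracy deltas
    drop = np.zeros(n_var)
    n_trees_used = 0
    for i, tree in enumerate(forest.estimators_):
        oob = masks[i]
        if not oob.any():
            continue
        n_trees_used += 1
        base_pred = tree.predict(X).astype(int)
        base_acc = float(np.mean(base_pred[oob] == y[oob]))
        pred = tree.predict(X_stack).astype(int).reshape(n_var, n)
        perm_acc = (pred[:, oob] == y[oob]).mean(axis=1)
        drop += base_acc - perm_acc
    if n_trees_used == 0:
        return {name: 0.0 for name in names}
    drop /= n_trees_used

    importances: dict[str, float] = {}
    for k, name in enumerate(names):
        importances[name] = float(np.mean(drop[k * n_repeats : (k + 1) * n_repeats]))
    return importances


# ---------------------------------------------------------------------------
# Public API

def rank_importance(
    features: FeatureMatrix,
    ntree: int = 2000,
    n_repeats: int = 5,
    seed: int = 0,
    mode: str = "family",
) -> tuple[dict[str, float], list[str]]:
    """Rank features (or feature families) by OOB permutation importance."""
    X, y, classes = _check_input(features)
    rng = np.random.default_rng(seed)
    forest = _fit_forest(X, y, ntree, int(rng.integers(2**31)))
    blocks = _block_columns(features.schema, mode)
    imp = _block_importances(forest, X, y, blocks, len(classes), n_repeats, rng)
    ranking = sorted(imp, key=lambda k: (-imp[k], k))
    return imp, ranking


def select_variables(
    features: FeatureMatrix,
    ntree: int = 2000,
    n_repeats: int = 5,
    n_decoy: int = 3,
    seed: int = 0,
    mode: str = "family",
) -> SelectionResult:
    """Two-step variable selection: decoy threshold, then nested OOB search."""
    X, y, classes = _check_input(features)
    n_classes = len(classes)
    rng = np.random.default_rng(seed)
    blocks = _block_columns(features.schema, mode)

    forest = _fit_forest(X, y, ntree, int(rng.integers(2**31)))
    imp = _block_importances(forest, X, y, blocks, n_classes, n_repeats, rng)
    ranking = sorted(imp, key=lambda k: (-imp[k], k))

    # decoy runs: same importance computation under permuted labels gives the
    # null distribution of importances; threshold = largest decoy importance
    decoy_vals: list[float] = []
    for _ in range(n_decoy):
        y_perm = rng.permutation(y)
        d_forest = _fit_forest(X, y_perm, ntree, int(rng.integers(2**31)))
        d_imp = _block_importances(d_forest, X, y_perm, blocks, n_classes, n_repeats, rng)
        decoy_vals.extend(d_imp.values())
    threshold = float(max(decoy_vals))
    kept = [name for name in ranking if imp[name] > threshold]

    # nested interpretation search over the surviving ranking
    oob_errors: dict[int, float] = {}
    interpretation: list[str] = []
    if kept:
        errs, sds = [], []
        for k in range(1, len(kept) + 1):
            cols = sorted(i for name in kept[:k] for i in blocks[name])
            sub_forest = _fit_forest(X[:, cols], y, ntree, int(rng.integers(2**31)))
            masks = _oob_masks(sub_forest, len(y))
            acc = _oob_votes_accuracy(sub_forest, masks, X[:, cols], y, n_classes)
            e = 1.0 - acc
            errs.append(e)
            sds.append(float(np.sqrt(max(e * (1.0 - e), 0.0) / len(y))))
            oob_errors[k] = e
        best = int(np.argmin(errs))
        cutoff = errs[best] + sds[best]
        k_star = next(k for k in range(1, len(kept) + 1) if errs[k - 1] <= cutoff)
        interpretation = kept[:k_star]

    return SelectionResult(
        importances=imp,
        ranking=ranking,
        threshold_kept=kept,
        interpretation_set=interpretation,
        threshold=threshold,
        ntree=ntree,
        seed=seed,
        mode=mode,
        oob_errors=oob_errors,
    )
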