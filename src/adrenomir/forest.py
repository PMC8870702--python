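"""Random-forest marker ranking by mean decrease in accuracy.

The forest is used only to order the markers — to confirm which of the
literature-selected miRNAs carry the group signal — never as the diagnostic
classifier itself. Importance follows the classic out-of-bag permutation
definition: for each tree, the drop in out-of-bag accuracy after permuting
one feature's out-of-bag values, averaged over trees ("mean decrease in
accuracy"). Trees are CART-style: Gini impurity, exhaustive threshold search
over a random feature subset at every split, grown on a bootstrap resample.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Sequence

import numpy as np
import pandas as pd

from .seeding import child_seed

__all__ = [
    "ForestParams",
    "ImportanceResult",
    "RandomForestMDA",
    "fit_forest",
    "permutation_importance",
    "rank_markers",
]


@dataclass(frozen=True)
class ForestParams:
    n_trees: int = 500
    max_features_per_split: Optional[int] = None  # None -> floor(sqrt(p))
    min_leaf: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_trees < 1:
            raise ValueError("n_trees must be >= 1")
        if self.min_leaf < 1:
            raise ValueError("min_leaf must be >= 1")
        if self.max_features_per_split is not None and self.max_features_per_split < 1:
            raise ValueError("max_features_per_split must be >= 1")


@dataclass
class _Tree:
    """Flat-array binary tree; leaf nodes have feature == -1."""

    feature: np.ndarray
    threshold: np.ndarray
    left: np.ndarray
    right: np.ndarray
    leaf_class: np.ndarray

    def predict(self, X: np.ndarray) -> np.ndarray:
        n = X.shape[0]
        out = np.empty(n, dtype=int)
        for i in range(n):
            node = 0
            while self.feature[node] >= 0:
                if X[i, self.feature[node]] <= self.threshold[node]:
                    node = self.left[node]
                else:
                    node = self.right[node]
            out[i] = self.leaf_class[node]
        return out


def _gini(counts: np.ndarray) -> float:
    n = counts.sum()
    if n == 0:
        return 0.0
    p = counts / n
    return 1.0 - float(np.sum(p * p))


def _best_split(X: np.ndarray, y: np.ndarray, features: np.ndarray,
                n_classes: int, min_leaf: int):
    """Exhaustive threshold search over the candidate features.

    Returns (feature, threshold, gain) or None if no admissible split.
    """
    n = y.size
    parent_counts = np.bincount(y, minlength=n_classes)
    parent_gini = _gini(parent_counts)
    best = None
    best_gain = 1e-12  # require strictly positive impurity decrease
    for f in features:
        order = np.argsort(X[:, f], kind="stable")
        xs = X[order, f]
        ys = y[order]
        left_counts = np.zeros(n_classes, dtype=int)
        right_counts = parent_counts.copy()
        for i in range(n - 1):
            c = ys[i]
            left_counts[c] += 1
            right_counts[c] -= 1
            if xs[i] == xs[i + 1]:
                continue
            n_left = i + 1
            n_right = n - n_left
            if n_left < min_leaf or n_right < min_leaf:
                continue
            gain = parent_gini - (
                n_left / n * _gini(left_counts) + n_right / n * _gini(right_counts)
            )
            if gain > best_gain:
                best_gain = gain
                best = (int(f), float((xs[i] + xs[i + 1]) / 2.0), gain)
    return best


def _grow_tree(X: np.ndarray, y: np.ndarray, n_classes: int, mtry: int,
               min_leaf: int, rng: np.random.Generator) -> _Tree:
    feature: List[int] = []
    threshold: List[float] = []
    left: List[int] = []
    right: List[int] = []
    leaf_class: List[int] = []
    p = X.shape[1]

    def new_node() -> int:
        feature.append(-1)
        threshold.append(0.0)
        left.append(-1)
        right.append(-1)
        leaf_class.append(-1)
        return len(feature) - 1

    def majority(labels: np.ndarray) -> int:
        counts = np.bincount(labels, minlength=n_classes)
        return int(np.argmax(counts))  # ties -> lowest class index

    stack = [(new_node(), np.arange(y.size))]
    while stack:
        node, idx = stack.pop()
        labels = y[idx]
        if labels.size < 2 * min_leaf or np.all(labels == labels[0]):
            leaf_class[node] = majority(labels)
            continue
        candidates = rng.choice(p, size=min(mtry, p), replace=False)
        split = _best_split(X[idx], labels, candidates, n_classes, min_leaf)
        if split is None:
            leaf_class[node] = majority(labels)
            continue
        f, thr, _ = split
        feature[node] = f
        threshold[node] = thr
        mask = X[idx, f] <= thr
        left[node] = new_node()
        right[node] = new_node()
        stack.append((left[node], idx[mask]))
        stack.append((right[node], idx[~mask]))

    return _Tree(
        feature=np.asarray(feature, dtype=int),
        threshold=np.asarray(threshold, dtype=float),
        left=np.asarray(left, dtype=int),
        right=np.asarray(right, dtype=int),
        leaf_class=np.asarray(leaf_class, dtype=int),
    )


@dataclass
class ImportanceResult:
    """Per-marker mean decrease in accuracy and the implied ranking."""

    importance: pd.Series
    ranks: pd.Series

    def top(self, k: int) -> list:
        return list(self.ranks.sort_values().index[:k])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"mean_decrease_accuracy": self.importance, "rank": self.ranks}
        ).sort_values("rank")


class RandomForestMDA:
    """Bootstrap forest with out-of-bag permutation importance.

    sklearn-style estimator: ``fit(X, y)`` grows the trees and retains each
    tree's out-of-bag sample indices; ``permutation_importance`` computes the
    mean decrease in accuracy per feature. Ranking ties break by feature
    name.
    """

    def __init__(self, n_trees: int = 500, max_features_per_split: Optional[int] = None,
                 min_leaf: int = 1, seed: int = 0) -> None:
        self.n_trees = n_trees
        self.max_features_per_split = max_features_per_split
        self.min_leaf = min_leaf
        self.seed = seed

    def get_params(self, deep: bool = True) -> dict:
        return {
            "n_trees": self.n_trees,
            "max_features_per_split": self.max_features_per_split,
            "min_leaf": self.min_leaf,
            "seed": self.seed,
        }

    def set_params(self, **params) -> "RandomForestMDA":
        for k, v in params.items():
            if k not in self.get_params():
                raise ValueError(f"unknown parameter {k}")
            setattr(self, k, v)
        return self

    def fit(self, X, y, feature_names: Sequence[str] = None) -> "RandomForestMDA":
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        if X.ndim != 2 or X.shape[0] != y.shape[0]:
            raise ValueError("X must be (n_samples, n_features) aligned with y")
        if np.isnan(X).any():
            raise ValueError("X contains masked (NaN) values")
        self.classes_, y_enc = np.unique(y, return_inverse=True)
        if self.classes_.size < 2:
            raise ValueError("training labels contain a single class")
        n, p = X.shape
        self.feature_names_ = (
            list(feature_names) if feature_names is not None
            else [f"feature_{j}" for j in range(p)]
        )
        if len(self.feature_names_) != p:
            raise ValueError("feature_names length mismatch")
        mtry = self.max_features_per_split or max(1, int(np.sqrt(p)))

        self.trees_: List[_Tree] = []
        self.oob_indices_: List[np.ndarray] = []
        for t in range(self.n_trees):
            rng = np.random.default_rng(child_seed(self.seed, "tree", t))
            boot = rng.integers(0, n, size=n)
            oob = np.setdiff1d(np.arange(n), boot)
            tree = _grow_tree(X[boot], y_enc[boot], self.classes_.size,
                              mtry, self.min_leaf, rng)
            self.trees_.append(tree)
            self.oob_indices_.append(oob)

        self._X = X
        self._y = y_enc
        self.oob_score_ = self._oob_score()
        return self

    def _oob_score(self) -> float:
        """OOB accuracy with per-sample plurality vote over covering trees."""
        n = self._y.size
        votes = np.zeros((n, self.classes_.size), dtype=int)
        for tree, oob in zip(self.trees_, self.oob_indices_):
            if oob.size == 0:
                continue
            pred = tree.predict(self._X[oob])
            votes[oob, pred] += 1
        covered = votes.sum(axis=1) > 0
        if not covered.any():
            return float("nan")
        calls = np.argmax(votes[covered], axis=1)
        return float(np.mean(calls == self._y[covered]))

    def predict(self, X) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        votes = np.zeros((X.shape[0], self.classes_.size), dtype=int)
        for tree in self.trees_:
            votes[np.arange(X.shape[0]), tree.predict(X)] += 1
        return self.classes_[np.argmax(votes, axis=1)]

    def permutation_importance(self, permutation_seed: int = None) -> ImportanceResult:
        """Mean decrease in OOB accuracy per feature.

        Per tree and feature: permute the feature's values among the tree's
        out-of-bag samples (fixed permutation seed) and record the accuracy
        drop; average over trees with non-empty out-of-bag sets.
        """
        if not hasattr(self, "trees_"):
            raise ValueError("forest is not fitted")
        if permutation_seed is None:
            permutation_seed = child_seed(self.seed, "permutation")
        p = len(self.feature_names_)
        diffs = np.zeros(p)
        n_used = 0
        for t, (tree, oob) in enumerate(zip(self.trees_, self.oob_indices_)):
            if oob.size == 0:
                continue
            n_used += 1
            X_oob = self._X[oob]
            y_oob = self._y[oob]
            base_acc = np.mean(tree.predict(X_oob) == y_oob)
            rng = np.random.default_rng(child_seed(permutation_seed, "tree", t))
            for j in range(p):
                perm = rng.permutation(oob.size)
                X_perm = X_oob.copy()
                X_perm[:, j] = X_oob[perm, j]
                perm_acc = np.mean(tree.predict(X_perm) == y_oob)
                diffs[j] += base_acc - perm_acc
        if n_used == 0:
            raise ValueError("no tree has out-of-bag samples")
        importance = pd.Series(diffs / n_used, index=self.feature_names_,
                               name="mean_decrease_accuracy")
        order = sorted(
            self.feature_names_, key=lambda f: (-importance[f], f)
        )
        ranks = pd.Series(
            {f: i + 1 for i, f in enumerate(order)}, name="rank"
        ).loc[self.feature_names_]
        return ImportanceResult(importance=importance, ranks=ranks)


def fit_forest(X, y, params: ForestParams = None,
               feature_names: Sequence[str] = None) -> RandomForestMDA:
    params = params or ForestParams()
    model = RandomForestMDA(
        n_trees=params.n_trees,
        max_features_per_split=params.max_features_per_split,
        min_leaf=params.min_leaf,
        seed=params.seed,
    )
    return model.fit(X, y, feature_names=feature_names)


def permutation_importance(forest: RandomForestMDA, permutation_seed: int = None
                           ) -> ImportanceResult:
    return forest.permutation_importance(permutation_seed)


def rank_markers(matrix, groups: Sequence[str] = ("ACA", "ACC", "NAC"),
                 params: ForestParams = None) -> ImportanceResult:
    """Rank an expression matrix's markers on the labeled analysis set."""
    sub = matrix.restrict_groups(groups)
    X = sub.feature_array(sub.assay_ids)
    y = sub.groups.to_numpy()
    forest = fit_forest(X, y, params=params, feature_names=sub.assay_ids)
    return forest.permutation_importance()
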