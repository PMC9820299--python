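"""Regression forest with mean-decrease-impurity feature importance.

Trees are grown by exhaustive search over candidate thresholds (midpoints
between consecutive distinct sorted feature values), choosing the split
that minimizes the sample-weighted child impurity

    G(x_i, v) = (n_left/N_s) * H(X_left) + (n_right/N_s) * H(X_right)

with the mean-squared-error impurity H.  Node importance is the weighted
impurity decrease

    n_k = w_k * H_k - w_left * H_left - w_right * H_right

with all weights taken relative to the tree's total training-sample count,
summed per split feature and normalized so the importances add to one.
The forest importance is the mean of the per-tree normalized vectors.

Ties between equally scoring splits are broken deterministically: lowest
feature index first, then lowest threshold.  Scores within a tiny relative
tolerance are treated as tied so the rule is stable under floating-point
reordering.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = [
    "TreeNode",
    "TreeParams",
    "RegressionTree",
    "Forest",
    "ImportanceVector",
    "Metrics",
    "fit_tree",
    "fit_forest",
    "feature_importance",
    "regression_metrics",
    "split_indices",
    "SCORE_ATOL",
    "SCORE_RTOL",
]

# splits whose scores differ by less than this are considered tied
SCORE_ATOL = 1e-12
SCORE_RTOL = 1e-9


def _tied(score: float, best: float) -> bool:
    return score <= best + SCORE_ATOL + SCORE_RTOL * abs(best)


@dataclass
class TreeNode:
    n_samples: int
    impurity: float          # MSE impurity H of the node
    value: float             # mean response (leaf prediction)
    feature: int = -1        # -1 marks a leaf
    threshold: float = float("nan")
    left: "TreeNode | None" = None
    right: "TreeNode | None" = None

    @property
    def is_leaf(self) -> bool:
        return self.feature < 0


@dataclass(frozen=True)
class TreeParams:
    """Growth limits; defaults are the standard regression-forest choices."""

    max_depth: int | None = None
    min_samples_split: int = 2
    min_samples_leaf: int = 1
    #: features tried per split: explicit count, or None for max(1, m // 3)
    max_features: int | None = None

    def resolve_max_features(self, m: int) -> int:
        if self.max_features is None:
            return max(1, m // 3)
        if not (1 <= self.max_features <= m):
            raise ValueError(f"max_features must lie in [1, {m}]")
        return self.max_features


def _node_stats(y: np.ndarray) -> tuple[float, float]:
    mean = float(np.mean(y))
    imp = float(np.mean((y - mean) ** 2))
    return mean, imp


def _best_split(
    x_cols: Sequence[np.ndarray],
    features: np.ndarray,
    y: np.ndarray,
    min_leaf: int,
) -> tuple[int, float] | None:
    """Exhaustive best split over the given feature columns.

    Returns (feature, threshold) of the minimal weighted-child-impurity
    split under the tie rule, or None if no feature admits a valid split.
    """
    n = y.size
    best_score = np.inf
    best: tuple[int, float] | None = None
    for f, x in zip(features, x_cols):
        order = np.argsort(x, kind="stable")
        xs = x[order]
        ys = y[order]
        distinct = xs[:-1] < xs[1:]
        if not distinct.any():
            continue
        cum = np.cumsum(ys)
        cumsq = np.cumsum(ys * ys)
        i = np.arange(1, n)  # left child size
        valid = distinct & (i >= min_leaf) & (n - i >= min_leaf)
        if not valid.any():
            continue
        il = i[valid]
        sse_left = cumsq[il - 1] - cum[il - 1] ** 2 / il
        sse_right = (cumsq[-1] - cumsq[il - 1]) - (cum[-1] - cum[il - 1]) ** 2 / (n - il)
        scores = (sse_left + sse_right) / n
        k = int(np.argmin(scores))
        smin = float(scores[k])
        if smin < best_score and not _tied(best_score, smin):
            # strictly better than the incumbent: take the first tied
            # position within this feature (lowest threshold)
            first = int(np.nonzero(scores <= smin + SCORE_ATOL + SCORE_RTOL * abs(smin))[0][0])
            pos = il[first]
            best_score = smin
            best = (int(f), float((xs[pos - 1] + xs[pos]) / 2.0))
    return best


@dataclass
class RegressionTree:
    root: TreeNode
    n_train: int
    n_features: int

    def predict(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        out = np.empty(X.shape[0])
        idx = np.arange(X.shape[0])
        stack = [(self.root, idx)]
        while stack:
            node, ind = stack.pop()
            if node.is_leaf or ind.size == 0:
                out[ind] = node.value
                continue
            go_left = X[ind, node.feature] <= node.threshold
            stack.append((node.left, ind[go_left]))
            stack.append((node.right, ind[~go_left]))
        return out

    def internal_nodes(self) -> list[TreeNode]:
        nodes, stack = [], [self.root]
        while stack:
            node = stack.pop()
            if not node.is_leaf:
                nodes.append(node)
                stack.append(node.left)
                stack.append(node.right)
        return nodes

    def raw_importance(self) -> np.ndarray | None:
        """Per-feature sum of node importance shares; None if the tree never splits."""
        internal = self.internal_nodes()
        if not internal:
            return None
        contrib = np.zeros(self.n_features)
        for node in internal:
            nk = (
                node.n_samples * node.impurity
                - node.left.n_samples * node.left.impurity
                - node.right.n_samples * node.right.impurity
            ) / self.n_train
            contrib[node.feature] += nk
        total = contrib.sum()
        if total <= 0:
            return None
        fi = contrib / total            # share of total impurity decrease
        return fi / fi.sum()            # explicit final normalization


def fit_tree(
    X: np.ndarray,
    y: np.ndarray,
    params: TreeParams | None = None,
    seed: int | np.random.Generator = 0,
) -> RegressionTree:
    """Grow a regression tree by recursive exhaustive split search."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if X.ndim != 2 or y.ndim != 1 or X.shape[0] != y.size:
        raise ValueError("X must be (n, m) and y length n")
    if y.size < 1 or not np.all(np.isfinite(y)):
        raise ValueError("response must be non-empty and finite")
    params = params or TreeParams()
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    m = X.shape[1]
    k_features = params.resolve_max_features(m)

    def grow(idx: np.ndarray, depth: int) -> TreeNode:
        ys = y[idx]
        value, imp = _node_stats(ys)
        node = TreeNode(n_samples=idx.size, impurity=imp, value=value)
        if (
            idx.size < params.min_samples_split
            or imp <= 0.0
            or (params.max_depth is not None and depth >= params.max_depth)
        ):
            return node
        if k_features < m:
            features = np.sort(rng.choice(m, size=k_features, replace=False))
        else:
            features = np.arange(m)
        split = _best_split([X[idx, f] for f in features], features, ys, params.min_samples_leaf)
        if split is None:
            return node
        node.feature, node.threshold = split
        go_left = X[idx, node.feature] <= node.threshold
        node.left = grow(idx[go_left], depth + 1)
        node.right = grow(idx[~go_left], depth + 1)
        return node

    root = grow(np.arange(X.shape[0]), 0)
    return RegressionTree(root=root, n_train=X.shape[0], n_features=m)


@dataclass
class Forest:
    """Bagged ensemble of regression trees; prediction is the tree mean."""

    trees: list[RegressionTree]
    n_trees: int
    params: TreeParams
    bootstrap: bool
    seed: int
    feature_names: tuple[str, ...] = ()

    def predict(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        acc = np.zeros(X.shape[0])
        for tree in self.trees:
            acc += tree.predict(X)
        return acc / len(self.trees)


def fit_forest(
    X: np.ndarray,
    y: np.ndarray,
    n_trees: int = 500,
    params: TreeParams | None = None,
    seed: int = 0,
    bootstrap: bool = True,
    feature_names: Sequence[str] | None = None,
) -> Forest:
    """Fit a regression forest on bootstrap resamples with random feature subsets."""
    if n_trees < 1:
        raise ValueError("need at least one tree")
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    params = params or TreeParams()
    n = X.shape[0]
    trees = []
    for child in np.random.SeedSequence(seed).spawn(n_trees):
        rng = np.random.default_rng(child)
        idx = rng.integers(0, n, size=n) if bootstrap else np.arange(n)
        trees.append(fit_tree(X[idx], y[idx], params=params, seed=rng))
    names = tuple(feature_names) if feature_names is not None else tuple(
        f"x{i}" for i in range(X.shape[1])
    )
    return Forest(
        trees=trees, n_trees=n_trees, params=params, bootstrap=bootstrap, seed=seed,
        feature_names=names,
    )


@dataclass(frozen=True)
class ImportanceVector:
    """Normalized per-feature importances; sums to one when defined."""

    values: np.ndarray
    names: tuple[str, ...]
    defined: bool = True

    def as_dict(self) -> dict[str, float]:
        return {n: float(v) for n, v in zip(self.names, self.values)}


def feature_importance(forest: Forest) -> ImportanceVector:
    """Mean of per-tree normalized mean-decrease-impurity vectors."""
    m = forest.trees[0].n_features
    vectors = [v for v in (t.raw_importance() for t in forest.trees) if v is not None]
    if not vectors:
        return ImportanceVector(values=np.zeros(m), names=forest.feature_names, defined=False)
    mean = np.mean(vectors, axis=0)
    return ImportanceVector(values=mean, names=forest.feature_names, defined=True)


@dataclass(frozen=True)
class Metrics:
    r2: float
    mse: float
    mae: float
    mape: float  # percent; NaN when any true value is zero

    def as_dict(self) -> dict[str, float]:
        return {"r2": self.r2, "mse": self.mse, "mae": self.mae, "mape": self.mape}


def regression_metrics(y_true: np.ndarray, y_pred: np.ndarray) -> Metrics:
    """R^2, MSE, MAE and MAPE (percent) of a prediction."""
    y_true = np.asarray(y_true, dtype=float)
    y_pred = np.asarray(y_pred, dtype=float)
    if y_true.shape != y_pred.shape or y_true.size < 2:
        raise ValueError("need matching arrays of length >= 2")
    err = y_true - y_pred
    mse = float(np.mean(err**2))
    mae = float(np.mean(np.abs(err)))
    ss_tot = float(np.sum((y_true - y_true.mean()) ** 2))
    r2 = float("nan") if ss_tot == 0 else 1.0 - float(np.sum(err**2)) / ss_tot
    if np.any(y_true == 0):
        mape = float("nan")
    else:
        mape = 100.0 * float(np.mean(np.abs(err / y_true)))
    return Metrics(r2=r2, mse=mse, mae=mae, mape=mape)


def split_indices(n: int, test_fraction: float = 0.1, seed: int = 0) -> tuple[np.ndarray, np.ndarray]:
    """Uniform random train/test partition (default 9:1)."""
    if not (0.0 < test_fraction < 1.0):
        raise ValueError("test_fraction must lie in (0, 1)")
    perm = np.random.default_rng(seed).permutation(n)
    n_test = max(1, int(round(n * test_fraction)))
    return np.sort(perm[n_test:]), np.sort(perm[:n_test])
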