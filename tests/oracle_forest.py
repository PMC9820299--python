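"""Independent brute-force oracle for regression-tree splitting and importance.

Everything here is naive on purpose: candidate splits are enumerated one by
one, impurities are recomputed from scratch with plain Python loops over
means, and the tree is represented as nested dicts.  The only shared
contract with the implementation under test is the split-score tie rule
(lowest feature index, then lowest threshold, with near-equal scores
treated as ties).
"""

from __future__ import annotations

import numpy as np

ATOL = 1e-12
RTOL = 1e-9


def impurity(y) -> float:
    y = list(y)
    mean = sum(y) / len(y)
    return sum((v - mean) ** 2 for v in y) / len(y)


def enumerate_splits(X, y, min_leaf=1):
    """All (feature, threshold, score) candidates with Eq-style weighted child impurity."""
    n, m = X.shape
    out = []
    for f in range(m):
        xs = sorted(set(X[:, f]))
        for a, b in zip(xs, xs[1:]):
            thr = (a + b) / 2.0
            left = [y[i] for i in range(n) if X[i, f] <= thr]
            right = [y[i] for i in range(n) if X[i, f] > thr]
            if len(left) < min_leaf or len(right) < min_leaf:
                continue
            score = (len(left) * impurity(left) + len(right) * impurity(right)) / n
            out.append((f, thr, score))
    return out


def best_split(X, y, min_leaf=1):
    """First candidate (feature asc, threshold asc) within tolerance of the min score."""
    cands = enumerate_splits(X, y, min_leaf)
    if not cands:
        return None
    smin = min(s for _, _, s in cands)
    for f, thr, s in cands:  # already ordered by (feature, threshold)
        if s <= smin + ATOL + RTOL * abs(smin):
            return f, thr
    return None


def grow_tree(X, y, idx=None, min_split=2, min_leaf=1):
    """Nested-dict regression tree grown with the brute-force split search."""
    if idx is None:
        idx = list(range(len(y)))
    ys = [y[i] for i in idx]
    node = {
        "idx": list(idx),
        "n": len(idx),
        "impurity": impurity(ys),
        "value": sum(ys) / len(ys),
        "feature": None,
    }
    if len(idx) < min_split or node["impurity"] <= 0.0:
        return node
    sub_X = np.array([[X[i, f] for f in range(X.shape[1])] for i in idx])
    sub_y = [y[i] for i in idx]
    split = best_split(sub_X, np.array(sub_y), min_leaf)
    if split is None:
        return node
    f, thr = split
    node["feature"], node["threshold"] = f, thr
    left_idx = [i for i in idx if X[i, f] <= thr]
    right_idx = [i for i in idx if X[i, f] > thr]
    node["left"] = grow_tree(X, y, left_idx, min_split, min_leaf)
    node["right"] = grow_tree(X, y, right_idx, min_split, min_leaf)
    return node


def tree_importance(node, n_total, m):
    """Per-feature normalized importance computed by walking the dict tree."""
    contrib = [0.0] * m

    def walk(nd):
        if nd["feature"] is None:
            return
        nk = (
            nd["n"] / n_total * nd["impurity"]
            - nd["left"]["n"] / n_total * nd["left"]["impurity"]
            - nd["right"]["n"] / n_total * nd["right"]["impurity"]
        )
        contrib[nd["feature"]] += nk
        walk(nd["left"])
        walk(nd["right"])

    walk(node)
    total = sum(contrib)
    if total <= 0:
        return None
    f = [c / total for c in contrib]
    s = sum(f)
    return [v / s for v in f]


def collect_splits(node, out=None):
    """(feature, threshold) of every internal node, preorder."""
    if out is None:
        out = []
    if node["feature"] is not None:
        out.append((node["feature"], node["threshold"]))
        collect_splits(node["left"], out)
        collect_splits(node["right"], out)
    return out
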