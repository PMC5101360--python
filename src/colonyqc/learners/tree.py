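"""CART binary classification tree with Gini impurity.

Greedy top-down induction: each node tries every (feature, threshold)
pair with thresholds at the midpoints of consecutive distinct sorted
feature values and keeps the split with the largest weighted Gini
decrease.  Ties between equally good splits go to the lowest feature
index, then the lowest threshold, so induction is fully deterministic.
Growth stops at pure nodes, the depth limit, or when no admissible
split remains (every child would fall below ``min_leaf`` samples or all
feature values coincide); impure nodes accept zero-gain splits, which is
what lets the tree work through locally uninformative structure such as
an XOR pattern.  Leaves predict their
majority label; an exactly tied leaf predicts -1.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from ..errors import InsufficientDataError
from .base import TrainedBinaryLearner, TreeSpec


@dataclass
class _Node:
    prediction: int
    feature: int | None = None
    threshold: float | None = None
    left: "_Node | None" = None
    right: "_Node | None" = None

    @property
    def is_leaf(self) -> bool:
        return self.feature is None


def _gini(y: np.ndarray) -> float:
    if len(y) == 0:
        return 0.0
    p = (y == 1).mean()
    return 2.0 * p * (1.0 - p)


def _majority(y: np.ndarray) -> int:
    pos = (y == 1).sum()
    neg = len(y) - pos
    return 1 if pos > neg else -1


def _best_split(
    X: np.ndarray, y: np.ndarray, min_leaf: int
) -> tuple[int, float, float] | None:
    """Return (feature, threshold, gain) of the best admissible split."""
    n = len(y)
    parent = _gini(y)
    best: tuple[int, float, float] | None = None
    for f in range(X.shape[1]):
        order = np.argsort(X[:, f], kind="stable")
        xs, ys = X[order, f], y[order]
        distinct = np.flatnonzero(np.diff(xs) > 0)
        for idx in distinct:
            left_n = idx + 1
            right_n = n - left_n
            if left_n < min_leaf or right_n < min_leaf:
                continue
            thr = 0.5 * (xs[idx] + xs[idx + 1])
            gain = parent - (
                left_n * _gini(ys[:left_n]) + right_n * _gini(ys[left_n:])
            ) / n
            if best is None or gain > best[2] + 1e-15:
                best = (f, thr, gain)
            # equal gains: earlier feature / lower threshold already held
    # zero-gain splits are admissible on impure nodes (CART grows through
    # locally uninformative splits, e.g. the XOR root)
    return best


def _grow(
    X: np.ndarray, y: np.ndarray, spec: TreeSpec, depth: int
) -> _Node:
    node = _Node(prediction=_majority(y))
    if len(np.unique(y)) == 1:
        return node
    if spec.max_depth is not None and depth >= spec.max_depth:
        return node
    split = _best_split(X, y, spec.min_leaf)
    if split is None:
        return node
    f, thr, _ = split
    mask = X[:, f] <= thr
    node.feature, node.threshold = f, thr
    node.left = _grow(X[mask], y[mask], spec, depth + 1)
    node.right = _grow(X[~mask], y[~mask], spec, depth + 1)
    return node


@dataclass
class TreeLearner(TrainedBinaryLearner):
    root: _Node
    spec: TreeSpec
    n_features: int = 0

    def predict_many(self, Q: np.ndarray) -> np.ndarray:
        Q = np.atleast_2d(np.asarray(Q, dtype=float))
        out = np.empty(Q.shape[0], dtype=int)
        for i, row in enumerate(Q):
            node = self.root
            while not node.is_leaf:
                node = node.left if row[node.feature] <= node.threshold else node.right
            out[i] = node.prediction
        return out

    def depth(self) -> int:
        def _d(node: _Node) -> int:
            if node.is_leaf:
                return 0
            return 1 + max(_d(node.left), _d(node.right))

        return _d(self.root)


def tree_fit(X: np.ndarray, y: Sequence[int], spec: TreeSpec) -> TreeLearner:
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    if X.shape[0] < 2:
        raise InsufficientDataError("need at least 2 training rows")
    root = _grow(X, y, spec, depth=0)
    return TreeLearner(root=root, spec=spec, n_features=X.shape[1])
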