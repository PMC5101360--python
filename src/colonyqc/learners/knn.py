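"""Distance-weighted k-nearest-neighbour binary classifier.

Votes are weighted per the spec: ``equal`` (1), ``inverse`` (1/d) or
``squared_inverse`` (1/d^2).  Two deterministic conventions:

* zero-distance rule — under the inverse weightings, if any of the k
  nearest neighbours sits at distance exactly 0, the vote is taken over
  the zero-distance neighbours only, with equal weight;
* tie rule — if the two class scores are equal, predict the label of the
  single nearest neighbour; if the configuration still cannot decide,
  predict -1.

The standardized Euclidean distance is scaled by the per-feature sample
standard deviation (n-1 denominator) of the training matrix, frozen at
fit time.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from ..errors import DegenerateScaleError, InsufficientDataError
from .base import KNNSpec, TrainedBinaryLearner
from .distances import distance_matrix


@dataclass
class KNNLearner(TrainedBinaryLearner):
    X: np.ndarray
    y: np.ndarray
    spec: KNNSpec
    scale: np.ndarray | None = None

    def __post_init__(self):
        self.n_features = self.X.shape[1]

    def predict_many(self, Q: np.ndarray) -> np.ndarray:
        Q = np.atleast_2d(np.asarray(Q, dtype=float))
        D = distance_matrix(Q, self.X, self.spec.distance, self.scale)
        k = self.spec.k
        out = np.empty(Q.shape[0], dtype=int)
        for r in range(Q.shape[0]):
            out[r] = self._vote(D[r], k)
        return out

    def _vote(self, d: np.ndarray, k: int) -> int:
        # stable sort: distance ties broken by training-row order
        order = np.argsort(d, kind="stable")[:k]
        nd, ny = d[order], self.y[order]
        if self.spec.weighting == "equal":
            w = np.ones(k)
        else:
            zero = nd == 0.0
            if zero.any():
                w = zero.astype(float)  # exact matches take the vote
            elif self.spec.weighting == "inverse":
                w = 1.0 / nd
            else:
                w = 1.0 / nd**2
        score_pos = w[ny == 1].sum()
        score_neg = w[ny == -1].sum()
        if score_pos > score_neg:
            return 1
        if score_neg > score_pos:
            return -1
        return int(ny[0]) if k >= 1 else -1


def knn_fit(X: np.ndarray, y: Sequence[int], spec: KNNSpec) -> KNNLearner:
    """Store the training set and, for standardized Euclidean, its scale."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    n = X.shape[0]
    if spec.k > n:
        raise InsufficientDataError(f"k={spec.k} exceeds n={n} training rows")
    if not ((y == 1).any() and (y == -1).any()):
        raise InsufficientDataError("both labels -1 and +1 must be present")
    scale = None
    if spec.distance == "standardized_euclidean":
        scale = X.std(axis=0, ddof=1)
        dead = np.flatnonzero(scale == 0)
        if dead.size:
            raise DegenerateScaleError(
                "standardized_euclidean needs nonzero per-feature std; "
                f"feature(s) {dead.tolist()} are constant"
            )
    return KNNLearner(X=X, y=y, spec=spec, scale=scale)
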