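"""Distance-weighted k-NN against an exhaustive sort-and-vote oracle."""

import numpy as np
import pytest

from colonyqc.errors import DegenerateScaleError, InsufficientDataError
from colonyqc.learners import KNNSpec, knn_fit
from colonyqc.learners.distances import DISTANCES
from colonyqc.learners.base import WEIGHTINGS

from test_distances import brute_distance


# --- independent oracle mirroring the documented voting rules ---------------

def knn_oracle(X, y, q, k, distance, weighting):
    scale = np.std(X, axis=0, ddof=1) if distance == "standardized_euclidean" else None
    # clamp float artifacts: the similarity-based distances are >= 0 by
    # definition but the direct formula can return -eps for exact matches
    d = [
        max(0.0, brute_distance(
            q.tolist(), X[i].tolist(), distance,
            scale.tolist() if scale is not None else None,
        ))
        for i in range(len(X))
    ]
    order = sorted(range(len(X)), key=lambda i: (d[i], i))[:k]
    nd = [d[i] for i in order]
    ny = [y[i] for i in order]
    if weighting == "equal":
        w = [1.0] * k
    elif any(v == 0.0 for v in nd):
        w = [1.0 if v == 0.0 else 0.0 for v in nd]
    elif weighting == "inverse":
        w = [1.0 / v for v in nd]
    else:
        w = [1.0 / v**2 for v in nd]
    pos = sum(wi for wi, yi in zip(w, ny) if yi == 1)
    neg = sum(wi for wi, yi in zip(w, ny) if yi == -1)
    if pos > neg:
        return 1
    if neg > pos:
        return -1
    return ny[0]


@pytest.mark.parametrize("distance", DISTANCES)
@pytest.mark.parametrize("weighting", WEIGHTINGS)
def test_predictions_match_oracle(distance, weighting):
    """>= 500 random small problems across the full 7 x 3 grid."""
    import zlib

    rng = np.random.default_rng(zlib.crc32(f"{distance}|{weighting}".encode()))
    for trial in range(25):
        n = int(rng.integers(6, 30))
        d = int(rng.integers(3, 6))
        X = rng.normal(size=(n, d))
        y = np.where(rng.random(n) < 0.5, 1, -1)
        if len(np.unique(y)) < 2:
            y[0] = -y[0]
        k = int(rng.choice([1, 3, 5, 7]))
        k = min(k, n if n % 2 else n - 1)
        learner = knn_fit(X, y, KNNSpec(k=k, distance=distance, weighting=weighting))
        for _ in range(4):
            if rng.random() < 0.3:
                q = X[rng.integers(n)].copy()  # exercise zero-distance rule
            else:
                q = rng.normal(size=d)
            scale = (np.std(X, axis=0, ddof=1)
                     if distance == "standardized_euclidean" else None)
            d_all = sorted(
                max(0.0, brute_distance(
                    q.tolist(), X[i].tolist(), distance,
                    scale.tolist() if scale is not None else None))
                for i in range(n)
            )
            # skip knife-edge orderings where float noise between the two
            # distance implementations could legitimately flip a neighbour
            gaps = np.diff(d_all[: k + 1])
            if len(gaps) and (gaps < 1e-9).any() and min(d_all[:k + 1]) > 0:
                continue
            assert learner.predict(q) == knn_oracle(X, y, q, k, distance, weighting)


def test_nearest_neighbor_examples():
    X = np.array([[0.0], [10.0]])
    y = np.array([-1, 1])
    learner = knn_fit(X, y, KNNSpec(k=1))
    assert learner.predict([1.0]) == -1


def test_zero_distance_neighbor_takes_inverse_vote():
    X = np.array([[0.0], [2.0], [3.0]])
    y = np.array([-1, 1, 1])
    learner = knn_fit(X, y, KNNSpec(k=3, weighting="inverse"))
    assert learner.predict([0.0]) == -1


def test_all_points_equal_weight_gives_majority(rng):
    X = rng.normal(size=(9, 3))
    y = np.array([1, 1, 1, 1, 1, -1, -1, -1, -1])
    learner = knn_fit(X, y, KNNSpec(k=9, weighting="equal"))
    for _ in range(10):
        assert learner.predict(rng.normal(size=3)) == 1


def test_fit_errors():
    X = np.array([[0.0], [1.0]])
    y = np.array([-1, 1])
    with pytest.raises(InsufficientDataError):
        knn_fit(X, y, KNNSpec(k=3))
    with pytest.raises(InsufficientDataError):
        knn_fit(X, np.array([1, 1]), KNNSpec(k=1))
    Xc = np.array([[0.0, 5.0], [1.0, 5.0], [2.0, 5.0]])
    with pytest.raises(DegenerateScaleError):
        knn_fit(Xc, np.array([-1, 1, 1]),
                KNNSpec(k=1, distance="standardized_euclidean"))


def test_spec_rejects_even_k():
    with pytest.raises(ValueError):
        KNNSpec(k=2)


def test_refit_is_deterministic(binary_problem):
    X, y = binary_problem
    probes = np.random.default_rng(7).normal(size=(20, X.shape[1]))
    spec = KNNSpec(k=3, distance="cityblock", weighting="squared_inverse")
    p1 = knn_fit(X, y, spec).predict_many(probes)
    p2 = knn_fit(X, y, spec).predict_many(probes)
    assert np.array_equal(p1, p2)
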