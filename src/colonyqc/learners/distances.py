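"""The seven distance measures used by the k-NN binary learners.

All are standard: Chebyshev, cityblock, Euclidean and standardized
Euclidean metrics, plus the correlation, cosine and Spearman
dissimilarities (one minus the respective similarity).  Scalar evaluation
goes through :func:`pairwise_distance`; the k-NN learner uses the batch
:func:`distance_matrix` built on ``scipy.spatial.distance.cdist``.
"""

from __future__ import annotations

import numpy as np
from scipy.spatial import distance as ssd
from scipy.stats import rankdata

from ..errors import DegenerateVectorError, MissingParameterError

DISTANCES = (
    "chebyshev",
    "cityblock",
    "correlation",
    "cosine",
    "euclidean",
    "standardized_euclidean",
    "spearman",
)

_CORRELATION_TYPE = frozenset({"correlation", "spearman"})


def _check_degenerate(a: np.ndarray, b: np.ndarray, distance: str) -> None:
    if distance in _CORRELATION_TYPE:
        if np.std(a) == 0 or np.std(b) == 0:
            raise DegenerateVectorError(
                f"{distance} distance undefined for a constant vector"
            )
    elif distance == "cosine":
        if np.linalg.norm(a) == 0 or np.linalg.norm(b) == 0:
            raise DegenerateVectorError(
                "cosine distance undefined for a zero vector"
            )


def pairwise_distance(
    a, b, distance: str, scale: np.ndarray | None = None
) -> float:
    """Distance between two vectors under one of the seven measures.

    ``scale`` is the per-feature standard deviation vector required by
    ``standardized_euclidean`` (strictly positive).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if distance not in DISTANCES:
        raise ValueError(f"unknown distance {distance!r}")
    _check_degenerate(a, b, distance)
    if distance == "chebyshev":
        return float(ssd.chebyshev(a, b))
    if distance == "cityblock":
        return float(ssd.cityblock(a, b))
    if distance == "euclidean":
        return float(ssd.euclidean(a, b))
    if distance == "standardized_euclidean":
        if scale is None:
            raise MissingParameterError(
                "standardized_euclidean requires a per-feature scale vector"
            )
        scale = np.asarray(scale, dtype=float)
        if scale.shape != a.shape or np.any(scale <= 0):
            raise MissingParameterError(
                "scale must be strictly positive with the feature length"
            )
        return float(ssd.seuclidean(a, b, scale**2))
    if distance == "cosine":
        return float(max(ssd.cosine(a, b), 0.0))
    if distance == "correlation":
        return float(max(ssd.correlation(a, b), 0.0))
    # spearman: correlation distance on average ranks
    ra, rb = rankdata(a), rankdata(b)
    if np.std(ra) == 0 or np.std(rb) == 0:
        raise DegenerateVectorError(
            "spearman distance undefined for a constant-rank vector"
        )
    return float(max(ssd.correlation(ra, rb), 0.0))


def distance_matrix(
    Q: np.ndarray,
    X: np.ndarray,
    distance: str,
    scale: np.ndarray | None = None,
) -> np.ndarray:
    """All pairwise distances between query rows Q and training rows X."""
    Q = np.atleast_2d(np.asarray(Q, dtype=float))
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if distance == "standardized_euclidean":
        if scale is None:
            raise MissingParameterError(
                "standardized_euclidean requires a per-feature scale vector"
            )
        return ssd.cdist(Q, X, "seuclidean", V=np.asarray(scale, float) ** 2)
    if distance == "spearman":
        RQ = np.apply_along_axis(rankdata, 1, Q)
        RX = np.apply_along_axis(rankdata, 1, X)
        return np.maximum(ssd.cdist(RQ, RX, "correlation"), 0.0)
    if distance in ("correlation", "cosine"):
        return np.maximum(ssd.cdist(Q, X, distance), 0.0)
    return ssd.cdist(Q, X, distance)
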