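"""Learner specifications and the common binary-learner interface.

A *spec* is a small frozen dataclass describing one binary classifier
configuration; :func:`fit_binary` dispatches a (X, y) problem with labels
in {-1, +1} to the right family and returns a fitted learner exposing
``predict(x) -> int`` and ``predict_many(X) -> ndarray``.
"""

from __future__ import annotations

from abc import ABC, abstractmethod
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from .distances import DISTANCES

WEIGHTINGS = ("equal", "inverse", "squared_inverse")
DISCRIMINANT_VARIANTS = (
    "linear",
    "diag_linear",
    "pseudo_linear",
    "quadratic",
    "diag_quadratic",
    "pseudo_quadratic",
)
NB_KERNELS = ("gaussian", "box", "epanechnikov", "triangle")


@dataclass(frozen=True)
class KNNSpec:
    """k-nearest-neighbour configuration.

    ``k`` must be odd (prevents plain-vote ties in a binary dichotomy);
    the study grid uses odd k in 1..23 but any odd k is accepted.
    """

    k: int = 1
    distance: str = "euclidean"
    weighting: str = "equal"

    def __post_init__(self):
        if self.k < 1 or self.k % 2 == 0:
            raise ValueError(f"k must be a positive odd integer, got {self.k}")
        if self.distance not in DISTANCES:
            raise ValueError(f"unknown distance {self.distance!r}")
        if self.weighting not in WEIGHTINGS:
            raise ValueError(f"unknown weighting {self.weighting!r}")

    def with_k(self, k: int) -> "KNNSpec":
        return replace(self, k=k)


@dataclass(frozen=True)
class DiscriminantSpec:
    """Gaussian discriminant-analysis configuration.

    ``linear`` variants pool one covariance matrix across classes,
    ``quadratic`` variants estimate one per class; ``diag_*`` keep only the
    covariance diagonal and ``pseudo_*`` replace inverse/determinant by
    pseudoinverse/pseudo-determinant so singular covariances still fit.
    """

    variant: str = "linear"
    priors: tuple | None = None  # None -> empirical class frequencies

    def __post_init__(self):
        if self.variant not in DISCRIMINANT_VARIANTS:
            raise ValueError(f"unknown discriminant variant {self.variant!r}")
        if self.priors is not None:
            p = np.asarray(self.priors, dtype=float)
            if np.any(p < 0) or not np.isclose(p.sum(), 1.0):
                raise ValueError("priors must be nonnegative and sum to 1")


@dataclass(frozen=True)
class NaiveBayesSpec:
    """Naive Bayes with per-feature normal or kernel-smoothed densities.

    ``bandwidth`` of ``"normal_reference"`` selects the Silverman rule
    h = 1.06 * sigma_hat * n^(-1/5) per class and feature; a positive float
    fixes the bandwidth globally.
    """

    density: str = "normal"
    kernel: str | None = None
    bandwidth: float | str = "normal_reference"

    def __post_init__(self):
        if self.density not in ("normal", "kde"):
            raise ValueError(f"unknown density {self.density!r}")
        if self.density == "kde":
            if self.kernel not in NB_KERNELS:
                raise ValueError(
                    f"kde density needs a kernel in {NB_KERNELS}, "
                    f"got {self.kernel!r}"
                )
        elif self.kernel is not None:
            raise ValueError("kernel is only meaningful with density='kde'")
        if isinstance(self.bandwidth, str):
            if self.bandwidth != "normal_reference":
                raise ValueError(f"unknown bandwidth rule {self.bandwidth!r}")
        elif self.bandwidth <= 0:
            raise ValueError("explicit bandwidth must be positive")


@dataclass(frozen=True)
class TreeSpec:
    """CART classification tree with Gini impurity."""

    min_leaf: int = 1
    max_depth: int | None = None

    def __post_init__(self):
        if self.min_leaf < 1:
            raise ValueError("min_leaf must be >= 1")
        if self.max_depth is not None and self.max_depth < 1:
            raise ValueError("max_depth must be >= 1 when given")


LearnerSpec = KNNSpec | DiscriminantSpec | NaiveBayesSpec | TreeSpec


class TrainedBinaryLearner(ABC):
    """A fitted binary classifier predicting hard labels in {-1, +1}."""

    n_features: int

    @abstractmethod
    def predict_many(self, X: np.ndarray) -> np.ndarray:
        """Predict a label in {-1, +1} for each row of X."""

    def predict(self, x) -> int:
        return int(self.predict_many(np.atleast_2d(np.asarray(x, float)))[0])


def fit_binary(
    X: np.ndarray, y: Sequence[int], spec: LearnerSpec
) -> TrainedBinaryLearner:
    """Fit one binary learner of the family selected by ``spec``."""
    from .discriminant import discriminant_fit
    from .knn import knn_fit
    from .naive_bayes import naive_bayes_fit
    from .tree import tree_fit

    if isinstance(spec, KNNSpec):
        return knn_fit(X, y, spec)
    if isinstance(spec, DiscriminantSpec):
        return discriminant_fit(X, y, spec)
    if isinstance(spec, NaiveBayesSpec):
        return naive_bayes_fit(X, y, spec)
    if isinstance(spec, TreeSpec):
        return tree_fit(X, y, spec)
    raise TypeError(f"unknown learner spec {type(spec).__name__}")


def describe_spec(spec: LearnerSpec) -> str:
    """Short human-readable name, used in reports and logs."""
    if isinstance(spec, KNNSpec):
        return f"knn[{spec.distance},{spec.weighting},k={spec.k}]"
    if isinstance(spec, DiscriminantSpec):
        return f"discriminant[{spec.variant}]"
    if isinstance(spec, NaiveBayesSpec):
        if spec.density == "normal":
            return "naive_bayes[normal]"
        return f"naive_bayes[kde,{spec.kernel}]"
    if isinstance(spec, TreeSpec):
        return "tree[gini]"
    return repr(spec)
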