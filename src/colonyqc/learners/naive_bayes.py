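"""Naive Bayes binary classifiers: normal densities or kernel smoothing.

Prediction maximises  log pi_c + sum_f log p_cf(x_f)  over the two
classes, treating features as conditionally independent.  The normal
variant stores a per-class per-feature mean and variance; the kernel
variant stores the raw per-class feature values and evaluates

    p(x) = 1/(n h) * sum_i K((x - x_i) / h)

with h from the per-class, per-feature normal-reference (Silverman) rule
h = 1.06 * sigma_hat * n^(-1/5) unless an explicit bandwidth is given.
Supported kernels: gaussian, box, epanechnikov, triangle.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from ..errors import InsufficientDataError, ZeroVarianceError
from .base import NaiveBayesSpec, TrainedBinaryLearner

_CLASSES = (-1, 1)
_TINY = np.finfo(float).tiny


def kernel_function(kernel: str, u: np.ndarray) -> np.ndarray:
    """Evaluate a smoothing kernel at standardised offsets u."""
    u = np.asarray(u, dtype=float)
    if kernel == "gaussian":
        return np.exp(-0.5 * u**2) / np.sqrt(2 * np.pi)
    inside = (np.abs(u) <= 1).astype(float)
    if kernel == "box":
        return 0.5 * inside
    if kernel == "epanechnikov":
        return 0.75 * (1 - u**2) * inside
    if kernel == "triangle":
        return (1 - np.abs(u)) * inside
    raise ValueError(f"unknown kernel {kernel!r}")


def silverman_bandwidth(values: np.ndarray) -> float:
    """Normal-reference rule h = 1.06 * sigma_hat * n^(-1/5)."""
    n = len(values)
    return 1.06 * float(np.std(values, ddof=1)) * n ** (-0.2)


@dataclass
class NaiveBayesLearner(TrainedBinaryLearner):
    spec: NaiveBayesSpec
    log_priors: dict
    # normal density state
    means: dict | None = None
    variances: dict | None = None
    # kde state: class -> (n_c x d) values, (d,) bandwidths
    values: dict | None = None
    bandwidths: dict | None = None

    def __post_init__(self):
        ref = self.means if self.means is not None else self.values
        self.n_features = ref[_CLASSES[0]].shape[-1]

    def class_log_density(self, c: int, Q: np.ndarray) -> np.ndarray:
        """Sum of per-feature log densities for class c at each query row."""
        Q = np.atleast_2d(np.asarray(Q, dtype=float))
        if self.spec.density == "normal":
            mu, var = self.means[c], self.variances[c]
            ll = -0.5 * (np.log(2 * np.pi * var) + (Q - mu) ** 2 / var)
            return ll.sum(axis=1)
        V, h = self.values[c], self.bandwidths[c]
        n = V.shape[0]
        # (q, n, d) standardised offsets
        U = (Q[:, None, :] - V[None, :, :]) / h
        dens = kernel_function(self.spec.kernel, U).sum(axis=1) / (n * h)
        return np.log(np.maximum(dens, _TINY)).sum(axis=1)

    def predict_many(self, Q: np.ndarray) -> np.ndarray:
        Q = np.atleast_2d(np.asarray(Q, dtype=float))
        score = {
            c: self.log_priors[c] + self.class_log_density(c, Q)
            for c in _CLASSES
        }
        return np.where(score[1] > score[-1], 1, -1)


def naive_bayes_fit(
    X: np.ndarray, y: Sequence[int], spec: NaiveBayesSpec
) -> NaiveBayesLearner:
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    n = X.shape[0]
    for c in _CLASSES:
        if (y == c).sum() < 2:
            raise InsufficientDataError(
                f"class {c:+d} needs at least 2 examples"
            )
    log_priors = {c: float(np.log((y == c).sum() / n)) for c in _CLASSES}

    if spec.density == "normal":
        means, variances = {}, {}
        for c in _CLASSES:
            Xc = X[y == c]
            means[c] = Xc.mean(axis=0)
            var = Xc.var(axis=0, ddof=1)
            dead = np.flatnonzero(var == 0)
            if dead.size:
                raise ZeroVarianceError(
                    f"class {c:+d} has zero variance in feature(s) "
                    f"{dead.tolist()}"
                )
            variances[c] = var
        return NaiveBayesLearner(
            spec=spec, log_priors=log_priors, means=means, variances=variances
        )

    values, bandwidths = {}, {}
    for c in _CLASSES:
        Xc = X[y == c]
        values[c] = Xc
        if spec.bandwidth == "normal_reference":
            h = np.array(
                [silverman_bandwidth(Xc[:, f]) for f in range(Xc.shape[1])]
            )
            dead = np.flatnonzero(h == 0)
            if dead.size:
                raise ZeroVarianceError(
                    f"class {c:+d} has zero spread in feature(s) "
                    f"{dead.tolist()}; normal-reference bandwidth undefined"
                )
        else:
            h = np.full(Xc.shape[1], float(spec.bandwidth))
        bandwidths[c] = h
    return NaiveBayesLearner(
        spec=spec, log_priors=log_priors, values=values, bandwidths=bandwidths
    )
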