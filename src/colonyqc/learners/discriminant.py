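"""Gaussian discriminant-analysis binary classifiers (six variants).

The decision statistic for class c is the regularised log-density

    delta_c(x) = -1/2 (x - mu_c)^T S_c^- (x - mu_c)
                 - 1/2 logdet+(S_c) + log pi_c

where S_c is the pooled covariance for the linear variants or the
per-class covariance for the quadratic variants, reduced to its diagonal
for the diag_* variants.  S_c^- is the ordinary inverse for the plain
variants (which therefore require positive-definite covariances) and the
Moore-Penrose pseudoinverse with the pseudo-determinant (product of
nonzero eigenvalues) for the pseudo_* variants, so rank-deficient
covariances — routine when d exceeds the class size — still fit.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import linalg

from ..errors import (
    CovarianceNotPositiveDefiniteError,
    InsufficientDataError,
    ZeroVarianceError,
)
from .base import DiscriminantSpec, TrainedBinaryLearner

_CLASSES = (-1, 1)


def _pd_inverse_logdet(S: np.ndarray) -> tuple[np.ndarray, float]:
    """Inverse and log-determinant via Cholesky; raise if not PD."""
    try:
        L = np.linalg.cholesky(S)
    except np.linalg.LinAlgError as exc:
        raise CovarianceNotPositiveDefiniteError(
            "covariance matrix is singular or not positive definite"
        ) from exc
    inv = linalg.cho_solve((L, True), np.eye(S.shape[0]))
    logdet = 2.0 * np.log(np.diag(L)).sum()
    return inv, logdet


def _pseudo_inverse_logdet(S: np.ndarray) -> tuple[np.ndarray, float]:
    """Pseudoinverse and pseudo log-determinant from the eigendecomposition."""
    w, V = np.linalg.eigh(S)
    tol = S.shape[0] * np.finfo(float).eps * max(w.max(), 0.0)
    keep = w > tol
    if not keep.any():
        # zero covariance: pseudoinverse is 0, pseudo-determinant is 1
        return np.zeros_like(S), 0.0
    inv = (V[:, keep] / w[keep]) @ V[:, keep].T
    return inv, float(np.log(w[keep]).sum())


@dataclass
class DiscriminantLearner(TrainedBinaryLearner):
    means: dict
    inv_cov: dict        # class -> precision matrix (d x d)
    logdet: dict         # class -> log(pseudo)determinant
    log_priors: dict
    spec: DiscriminantSpec

    def __post_init__(self):
        self.n_features = self.means[_CLASSES[0]].shape[0]

    def predict_many(self, Q: np.ndarray) -> np.ndarray:
        Q = np.atleast_2d(np.asarray(Q, dtype=float))
        scores = np.empty((Q.shape[0], 2))
        for idx, c in enumerate(_CLASSES):
            Z = Q - self.means[c]
            quad = np.einsum("ij,jk,ik->i", Z, self.inv_cov[c], Z)
            scores[:, idx] = (
                -0.5 * quad - 0.5 * self.logdet[c] + self.log_priors[c]
            )
        # tie -> -1 (first class in _CLASSES order)
        return np.where(scores[:, 1] > scores[:, 0], 1, -1)


def discriminant_fit(
    X: np.ndarray, y: Sequence[int], spec: DiscriminantSpec
) -> DiscriminantLearner:
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    n, d = X.shape
    for c in _CLASSES:
        if (y == c).sum() < 2:
            raise InsufficientDataError(
                f"class {c:+d} needs at least 2 examples"
            )

    means, covs, counts = {}, {}, {}
    for c in _CLASSES:
        Xc = X[y == c]
        counts[c] = Xc.shape[0]
        means[c] = Xc.mean(axis=0)
        covs[c] = np.cov(Xc, rowvar=False, ddof=1).reshape(d, d)

    if spec.priors is not None:
        priors = {c: spec.priors[i] for i, c in enumerate(_CLASSES)}
    else:
        priors = {c: counts[c] / n for c in _CLASSES}
    log_priors = {
        c: (np.log(p) if p > 0 else -np.inf) for c, p in priors.items()
    }

    pooled = spec.variant in ("linear", "diag_linear", "pseudo_linear")
    diag = spec.variant in ("diag_linear", "diag_quadratic")
    pseudo = spec.variant in ("pseudo_linear", "pseudo_quadratic")

    if pooled:
        S = sum((counts[c] - 1) * covs[c] for c in _CLASSES) / (n - 2)
        class_cov = {c: S for c in _CLASSES}
    else:
        class_cov = covs

    def _reduce(S: np.ndarray, c: int) -> tuple[np.ndarray, float]:
        if diag:
            v = np.diag(S).copy()
            dead = np.flatnonzero(v == 0)
            if dead.size:
                raise ZeroVarianceError(
                    f"class {c:+d} has zero variance in feature(s) "
                    f"{dead.tolist()}"
                )
            return np.diag(1.0 / v), float(np.log(v).sum())
        if pseudo:
            return _pseudo_inverse_logdet(S)
        return _pd_inverse_logdet(S)

    inv_cov, logdet = {}, {}
    if pooled:
        # one shared covariance: reduce once, assign to both classes
        inv_shared, logdet_shared = _reduce(class_cov[_CLASSES[0]], 0)
        for c in _CLASSES:
            inv_cov[c], logdet[c] = inv_shared, logdet_shared
    else:
        for c in _CLASSES:
            inv_cov[c], logdet[c] = _reduce(class_cov[c], c)

    return DiscriminantLearner(
        means=means,
        inv_cov=inv_cov,
        logdet=logdet,
        log_priors=log_priors,
        spec=spec,
    )
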