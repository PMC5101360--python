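"""ECOC training and decoding.

Training fits one binary learner per coding-matrix column on the rows of
the classes that column includes (entry != 0), relabelled to the column's
signs.  Prediction collects the hard outputs of all learners into a
codeword s in {-1, +1}^Nc and decodes it against the class codewords with
the Hamming binary loss l(z) = (1 - sign(z)) / 2:

* ``hamming``              D(i) = sum_{j: m_ij != 0}  l(m_ij * s_j)
* ``loss_weighted``        D(i) = sum_j |m_ij| l(m_ij s_j) / sum_j |m_ij|
* ``performance_weighted`` D(i) = sum_j w_ij l(m_ij s_j), rows of w
  proportional to each learner's training accuracy on class i and
  normalised to sum 1.

The predicted class minimises D; ties go to the smallest row index.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .coding import CodingMatrix
from .errors import (
    MissingParameterError,
    UnknownLabelError,
    UntrainableColumnError,
)
from .features import FeatureTable
from .learners import LearnerSpec, TrainedBinaryLearner, fit_binary

DECODINGS = ("loss_weighted", "hamming", "performance_weighted")


def binary_loss(z: float) -> float:
    """Hamming loss on the margin product: l(+1)=0, l(-1)=1, l(0)=0.5."""
    return (1.0 - float(np.sign(z))) / 2.0


@dataclass
class ECOCModel:
    coding: CodingMatrix
    learners: list[TrainedBinaryLearner]
    learner_spec: LearnerSpec
    decoding: str = "loss_weighted"
    weights: np.ndarray | None = None  # performance_weighted only
    column_subset_sizes: tuple = ()

    @property
    def class_labels(self) -> tuple:
        return self.coding.class_labels

    def summary(self) -> str:
        from .learners import describe_spec

        lines = [
            f"design: {self.coding.design}",
            f"classes: {', '.join(map(str, self.class_labels))}",
            f"learner: {describe_spec(self.learner_spec)}",
            f"decoding: {self.decoding}",
            "columns:",
        ]
        for j, sz in enumerate(self.column_subset_sizes):
            lines.append(f"  f{j + 1}: {sz} training rows")
        return "\n".join(lines)


def decode(
    cm: CodingMatrix,
    s: np.ndarray,
    decoding: str = "loss_weighted",
    weights: np.ndarray | None = None,
) -> int:
    """Decode a codeword to a class row index (argmin of the loss D)."""
    s = np.asarray(s, dtype=float).ravel()
    E = np.asarray(cm.entries, dtype=float)
    if s.shape[0] != E.shape[1]:
        raise ValueError(
            f"codeword length {s.shape[0]} != {E.shape[1]} columns"
        )
    if decoding not in DECODINGS:
        raise ValueError(f"unknown decoding {decoding!r}")
    # elementwise Hamming loss on margin products m_ij * s_j
    L = (1.0 - np.sign(E * s)) / 2.0
    A = np.abs(E)
    if decoding == "hamming":
        D = (A * L).sum(axis=1)
    elif decoding == "loss_weighted":
        D = (A * L).sum(axis=1) / A.sum(axis=1)
    else:
        if weights is None:
            raise MissingParameterError(
                "performance_weighted decoding requires a weight matrix"
            )
        W = np.asarray(weights, dtype=float)
        if W.shape != E.shape:
            raise ValueError("weights must match the coding-matrix shape")
        D = (W * L).sum(axis=1)
    return int(np.argmin(D))  # argmin takes the smallest index on ties


def train_ecoc(
    table: FeatureTable,
    cm: CodingMatrix,
    spec: LearnerSpec,
    decoding: str = "loss_weighted",
) -> ECOCModel:
    """Fit one binary learner per coding-matrix column."""
    labels = np.asarray(table.labels)
    present = set(np.unique(labels).tolist())
    missing = [c for c in cm.class_labels if c not in present]
    unknown = present - set(cm.class_labels)
    if unknown:
        raise UnknownLabelError(
            f"labels {sorted(map(str, unknown))} not in the coding matrix's "
            f"class order"
        )
    row_index = np.array([cm.row_of(lab) for lab in labels])
    E = cm.entries

    learners: list[TrainedBinaryLearner] = []
    subset_sizes = []
    for j in range(cm.n_columns):
        signs = E[row_index, j]
        mask = signs != 0
        ysub = signs[mask].astype(int)
        if not ((ysub == 1).any() and (ysub == -1).any()):
            raise UntrainableColumnError(
                j,
                f"column {j}: included classes contribute only one polarity"
                + (f" (classes absent from data: {missing})" if missing else ""),
            )
        Xsub = table.features[mask]
        try:
            learners.append(fit_binary(Xsub, ysub, spec))
        except Exception as exc:
            exc.args = (f"column {j}: {exc}",) + exc.args[1:]
            raise
        subset_sizes.append(int(mask.sum()))

    weights = None
    if decoding == "performance_weighted":
        weights = _performance_weights(table, cm, learners, row_index)

    return ECOCModel(
        coding=cm,
        learners=learners,
        learner_spec=spec,
        decoding=decoding,
        weights=weights,
        column_subset_sizes=tuple(subset_sizes),
    )


def _performance_weights(table, cm, learners, row_index) -> np.ndarray:
    """w_ij = training accuracy of learner j on class i (0 where m_ij = 0),
    rows normalised to sum 1."""
    E = cm.entries
    M, Nc = E.shape
    preds = np.stack(
        [lrn.predict_many(table.features) for lrn in learners], axis=1
    )  # n x Nc
    W = np.zeros((M, Nc))
    for i in range(M):
        rows = row_index == i
        if not rows.any():
            continue
        for j in range(Nc):
            if E[i, j] == 0:
                continue
            W[i, j] = (preds[rows, j] == E[i, j]).mean()
    sums = W.sum(axis=1, keepdims=True)
    return np.divide(W, np.where(sums > 0, sums, 1.0))


def predict_codeword(model: ECOCModel, x: np.ndarray) -> np.ndarray:
    """The length-Nc vector of hard binary predictions for one example."""
    x = np.atleast_2d(np.asarray(x, dtype=float))
    return np.array([lrn.predict_many(x)[0] for lrn in model.learners])


def predict_ecoc(model: ECOCModel, x: np.ndarray):
    """Predict the class label of one feature vector."""
    s = predict_codeword(model, x)
    idx = decode(model.coding, s, model.decoding, model.weights)
    return model.class_labels[idx]


def predict_ecoc_many(model: ECOCModel, X: np.ndarray) -> np.ndarray:
    """Vectorised prediction for a stack of feature vectors."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    S = np.stack([lrn.predict_many(X) for lrn in model.learners], axis=1)
    out = [
        model.class_labels[decode(model.coding, s, model.decoding, model.weights)]
        for s in S
    ]
    return np.asarray(out)
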