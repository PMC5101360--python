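"""Leave-one-out evaluation, nested model selection, and metrics.

Two protocols:

* plain leave-one-out (LOO) for learners without tunable parameters —
  each example is predicted by an ensemble trained on the other n-1;
* nested leave-one-out (NLOO) for k-NN, where each outer training fold
  runs a full inner LOO over the candidate k values, selects the k with
  the highest inner multiclass accuracy (ties -> smallest k, shared by
  all binary learners of the ensemble), and predicts the held-out
  example with that k.

Metrics are per-class true-positive counts (TP), true-positive rates
(TPR = TP / class size), the overall accuracy (ACC), and the full
confusion matrix.  Rendered percentages are rounded half-up to one
decimal.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .coding import CodingMatrix, build_coding_matrix
from .ecoc import predict_ecoc, train_ecoc
from .errors import (
    InsufficientDataError,
    UnknownLabelError,
    UntrainableFoldError,
)
from .features import FeatureTable, Preprocessor
from .learners import KNNSpec, LearnerSpec


def round_half_up(x: float, decimals: int = 1) -> float:
    """Round with ties away from zero, as the result tables format."""
    factor = 10.0**decimals
    return float(np.floor(abs(x) * factor + 0.5) / factor * np.sign(x))


def format_pct(x: float) -> str:
    return f"{round_half_up(100.0 * x):.1f}%"


@dataclass
class ClassMetrics:
    """Per-class TP/TPR, overall ACC, and the confusion matrix."""

    class_order: tuple
    tp: np.ndarray            # per class, integer counts
    class_sizes: np.ndarray
    confusion: np.ndarray     # rows = truth, columns = prediction
    acc: float

    @property
    def tpr(self) -> np.ndarray:
        return self.tp / self.class_sizes

    def tp_of(self, label) -> int:
        return int(self.tp[self.class_order.index(label)])

    def tpr_of(self, label) -> float:
        i = self.class_order.index(label)
        return float(self.tp[i] / self.class_sizes[i])

    def render_row(self) -> dict:
        """One report row shaped like the published tables:
        per-class 'TP (TPR%)' strings plus the ACC percentage."""
        row = {}
        for i, c in enumerate(self.class_order):
            row[str(c)] = f"{int(self.tp[i])} ({format_pct(self.tpr[i])})"
        row["ACC"] = format_pct(self.acc)
        return row


@dataclass
class NLOOResult:
    """LOO metrics plus the per-outer-fold model-selection record."""

    metrics: ClassMetrics
    selected_k: tuple            # one k per outer fold
    k_grid: tuple
    inner_accuracy: np.ndarray   # folds x |k grid|


def compute_metrics(
    truth: Sequence, predicted: Sequence, class_order: Sequence
) -> ClassMetrics:
    """Count TP per class, build the confusion matrix, compute ACC."""
    truth = np.asarray(truth)
    predicted = np.asarray(predicted)
    if len(truth) != len(predicted) or len(truth) == 0:
        raise ValueError("truth and predicted must have equal nonzero length")
    class_order = tuple(class_order)
    index = {c: i for i, c in enumerate(class_order)}
    M = len(class_order)
    confusion = np.zeros((M, M), dtype=int)
    for t, p in zip(truth, predicted):
        if t not in index or p not in index:
            raise UnknownLabelError(
                f"label {t if t not in index else p!r} outside class order"
            )
        confusion[index[t], index[p]] += 1
    tp = np.diag(confusion).copy()
    sizes = confusion.sum(axis=1)
    return ClassMetrics(
        class_order=class_order,
        tp=tp,
        class_sizes=sizes,
        confusion=confusion,
        acc=float(tp.sum() / len(truth)),
    )


def _resolve_coding(design, class_order) -> CodingMatrix:
    if isinstance(design, CodingMatrix):
        return design
    return build_coding_matrix(design, len(class_order), class_order)


def _check_folds(labels: np.ndarray) -> None:
    classes, counts = np.unique(labels, return_counts=True)
    thin = classes[counts < 2]
    if thin.size:
        row = int(np.flatnonzero(np.isin(labels, thin))[0])
        raise UntrainableFoldError(
            row,
            f"class(es) {thin.tolist()} have a single member; leaving out "
            f"row {row} would empty a class",
        )


def loo_evaluate(
    table: FeatureTable,
    design,
    spec: LearnerSpec,
    decoding: str = "loss_weighted",
    class_order: Sequence | None = None,
    per_fold_preprocess: bool = False,
) -> ClassMetrics:
    """Plain leave-one-out evaluation of one ECOC configuration.

    ``per_fold_preprocess`` refits the standardise-and-rescale transform
    on each training fold (leakage-free mode); by default the table is
    used as given, matching the study's whole-table preprocessing order.
    """
    if table.n < 3:
        raise InsufficientDataError("LOO needs at least 3 rows")
    _check_folds(table.labels)
    order = tuple(class_order) if class_order else table.class_order()
    cm = _resolve_coding(design, order)
    predictions = []
    for i in range(table.n):
        train_idx = np.delete(np.arange(table.n), i)
        train = table.subset(train_idx)
        query = table.features[i]
        if per_fold_preprocess:
            pp = Preprocessor().fit(train.features)
            train = FeatureTable(
                pp.transform(train.features), train.labels, train.ids
            )
            query = pp.transform(query[None, :])[0]
        model = train_ecoc(train, cm, spec, decoding)
        predictions.append(predict_ecoc(model, query))
    return compute_metrics(table.labels, predictions, order)


def _loo_predictions_knn(
    table: FeatureTable, cm: CodingMatrix, spec: KNNSpec, decoding: str
) -> np.ndarray:
    """All-fold LOO predictions for a fixed k-NN spec."""
    preds = []
    for i in range(table.n):
        train = table.subset(np.delete(np.arange(table.n), i))
        model = train_ecoc(train, cm, spec, decoding)
        preds.append(predict_ecoc(model, table.features[i]))
    return np.asarray(preds)


def nloo_evaluate(
    table: FeatureTable,
    design,
    base_spec: KNNSpec,
    k_grid: Sequence[int],
    decoding: str = "loss_weighted",
    class_order: Sequence | None = None,
) -> NLOOResult:
    """Nested leave-one-out: outer model evaluation, inner k selection.

    ``base_spec`` fixes the distance and weighting; ``k_grid`` lists the
    candidate neighbourhood sizes (all < n - 1).
    """
    k_grid = tuple(sorted(set(int(k) for k in k_grid)))
    if not k_grid:
        raise ValueError("k grid must be nonempty")
    if table.n < 4:
        raise InsufficientDataError("NLOO needs at least 4 rows")
    if max(k_grid) >= table.n - 1:
        raise InsufficientDataError(
            f"largest k ({max(k_grid)}) must be < n - 1 = {table.n - 1}"
        )
    _check_folds(table.labels)
    order = tuple(class_order) if class_order else table.class_order()
    cm = _resolve_coding(design, order)

    predictions = []
    selected = []
    inner_acc = np.zeros((table.n, len(k_grid)))
    for i in range(table.n):
        train = table.subset(np.delete(np.arange(table.n), i))
        for g, k in enumerate(k_grid):
            inner_preds = _loo_predictions_knn(
                train, cm, base_spec.with_k(k), decoding
            )
            inner_acc[i, g] = (inner_preds == train.labels).mean()
        best = int(np.argmax(inner_acc[i]))  # ties -> smallest k (sorted)
        k_star = k_grid[best]
        selected.append(k_star)
        model = train_ecoc(train, cm, base_spec.with_k(k_star), decoding)
        predictions.append(predict_ecoc(model, table.features[i]))

    metrics = compute_metrics(table.labels, predictions, order)
    return NLOOResult(
        metrics=metrics,
        selected_k=tuple(selected),
        k_grid=k_grid,
        inner_accuracy=inner_acc,
    )


#: odd k from 1 to 23, the study's default candidate grid
DEFAULT_K_GRID = tuple(range(1, 24, 2))
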