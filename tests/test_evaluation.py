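"""Metrics arithmetic against the published worked examples, and the
LOO / nested-LOO protocols."""

import numpy as np
import pytest

from colonyqc.errors import UnknownLabelError, UntrainableFoldError
from colonyqc.evaluation import (
    compute_metrics,
    format_pct,
    loo_evaluate,
    nloo_evaluate,
    round_half_up,
)
from colonyqc.features import FeatureTable
from colonyqc.learners import KNNSpec, TreeSpec
from conftest import make_cluster_table

ORDER = ("bad", "good", "semigood")
SIZES = (41, 74, 58)


def predictions_with_tp(tp):
    """Build truth/prediction label lists realising given per-class TPs
    (misclassified rows all sent to an arbitrary other class)."""
    truth, pred = [], []
    for c, (n, correct) in enumerate(zip(SIZES, tp)):
        other = ORDER[(c + 1) % 3]
        truth += [ORDER[c]] * n
        pred += [ORDER[c]] * correct + [other] * (n - correct)
    return truth, pred


@pytest.mark.parametrize(
    "tp,acc_pct,tpr_pct",
    [
        ((25, 58, 25), "62.4%", ("61.0%", "78.4%", "43.1%")),
        ((17, 34, 16), "38.7%", ("41.5%", "45.9%", "27.6%")),
        ((41, 0, 0), "23.7%", ("100.0%", "0.0%", "0.0%")),
        ((19, 50, 30), "57.2%", ("46.3%", "67.6%", "51.7%")),
    ],
)
def test_metrics_reproduce_published_cells(tp, acc_pct, tpr_pct):
    truth, pred = predictions_with_tp(tp)
    m = compute_metrics(truth, pred, ORDER)
    assert tuple(m.tp) == tp
    assert format_pct(m.acc) == acc_pct
    assert tuple(format_pct(x) for x in m.tpr) == tpr_pct
    assert m.confusion.sum(axis=1).tolist() == list(SIZES)
    assert np.trace(m.confusion) == sum(tp)


def test_perfect_predictions():
    truth, pred = predictions_with_tp(SIZES)
    m = compute_metrics(truth, pred, ORDER)
    assert m.acc == 1.0
    assert np.array_equal(np.diag(np.diag(m.confusion)), m.confusion)


def test_unknown_label_raises():
    with pytest.raises(UnknownLabelError):
        compute_metrics(["bad"], ["excellent"], ORDER)


def test_round_half_up_matches_table_formatting():
    assert round_half_up(57.2254) == 57.2
    assert round_half_up(41.4634) == 41.5
    assert round_half_up(62.45) == 62.5  # exact half rounds up


def test_loo_on_separable_clusters_is_perfect():
    table = make_cluster_table(n_per_class=2, labels=("neg", "pos"), separation=12.0)
    m = loo_evaluate(table, "ova", KNNSpec(k=1))
    assert m.acc == 1.0


def test_loo_makes_exactly_n_held_out_predictions(separable_table):
    m = loo_evaluate(separable_table, "ovo", KNNSpec(k=1))
    assert m.confusion.sum() == separable_table.n


def test_loo_constant_predictor_scores_class_frequency():
    # identical features everywhere: every tree is a single majority leaf,
    # the decoded class is always the same, so ACC = that class's frequency
    n = (5, 3, 2)
    feats = np.ones((sum(n), 3))
    labels = np.array(
        ["bad"] * n[0] + ["good"] * n[1] + ["semigood"] * n[2]
    )
    table = FeatureTable(features=feats, labels=labels)
    m = loo_evaluate(table, "ova", TreeSpec())
    predicted_class = ORDER[int(np.argmax(m.confusion.sum(axis=0)))]
    freq = n[ORDER.index(predicted_class)] / sum(n)
    assert m.acc == pytest.approx(freq)


def test_loo_rejects_singleton_class():
    table = make_cluster_table(n_per_class=3)
    table.labels[0] = "rare"
    with pytest.raises((UntrainableFoldError, UnknownLabelError)):
        loo_evaluate(
            table, "ova", KNNSpec(k=1),
            class_order=("bad", "good", "rare", "semigood"),
        )


def test_per_fold_preprocessing_mode_runs(separable_table):
    m = loo_evaluate(
        separable_table, "ova", KNNSpec(k=1), per_fold_preprocess=True
    )
    assert m.acc == 1.0


def test_nloo_records_selection_per_fold(separable_table):
    res = nloo_evaluate(separable_table, "ova", KNNSpec(k=1), k_grid=(1, 3))
    assert len(res.selected_k) == separable_table.n
    assert res.inner_accuracy.shape == (separable_table.n, 2)
    # tight clusters: every inner LOO is perfect for both k, tie -> k = 1
    assert set(res.selected_k) == {1}
    assert np.all(res.inner_accuracy == 1.0)


def test_nloo_with_single_k_reduces_to_loo(separable_table):
    res = nloo_evaluate(separable_table, "ovo", KNNSpec(k=3), k_grid=(3,))
    loo = loo_evaluate(separable_table, "ovo", KNNSpec(k=3))
    assert np.array_equal(res.metrics.confusion, loo.confusion)
    assert res.metrics.acc == loo.acc


def test_nloo_selected_k_attains_max_inner_accuracy(separable_table):
    res = nloo_evaluate(separable_table, "ordinal", KNNSpec(k=1), k_grid=(1, 3, 5))
    for fold, k in enumerate(res.selected_k):
        g = res.k_grid.index(k)
        assert res.inner_accuracy[fold, g] == res.inner_accuracy[fold].max()
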