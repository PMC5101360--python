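"""ECOC training subsets, the Hamming binary loss, decoding (incl. the
exhaustive codeword oracle), and end-to-end ensemble prediction."""

import itertools

import numpy as np
import pytest

from colonyqc.coding import build_coding_matrix
from colonyqc.ecoc import (
    binary_loss,
    decode,
    predict_ecoc,
    predict_ecoc_many,
    train_ecoc,
)
from colonyqc.errors import MissingParameterError, UntrainableColumnError
from colonyqc.features import FeatureTable
from colonyqc.learners import KNNSpec, TreeSpec
from conftest import make_cluster_table

ORDER = ("bad", "good", "semigood")


def test_binary_loss_values():
    assert binary_loss(1.0) == 0.0
    assert binary_loss(-1.0) == 1.0
    assert binary_loss(0.0) == 0.5
    assert binary_loss(3.7) == 0.0


def test_ovo_columns_train_on_two_classes_only(separable_table):
    cm = build_coding_matrix("ovo", 3, ORDER)
    model = train_ecoc(separable_table, cm, KNNSpec(k=1))
    # 6 rows per class: every pairwise column sees exactly 12 rows
    assert model.column_subset_sizes == (12, 12, 12)


def test_ova_columns_train_on_all_rows(separable_table):
    cm = build_coding_matrix("ova", 3, ORDER)
    model = train_ecoc(separable_table, cm, KNNSpec(k=1))
    assert model.column_subset_sizes == (18, 18, 18)


def test_missing_class_makes_columns_untrainable():
    table = make_cluster_table(labels=("bad", "good"))
    cm = build_coding_matrix("ovo", 3, ORDER)
    with pytest.raises(UntrainableColumnError) as err:
        train_ecoc(table, cm, KNNSpec(k=1))
    # pairs (bad, semigood) and (good, semigood) are columns 1 and 2
    assert err.value.column in (1, 2)


def brute_force_decode(E, s, decoding, weights=None):
    best, best_D = None, None
    for i in range(E.shape[0]):
        D = 0.0
        norm = 0.0
        for j in range(E.shape[1]):
            m = E[i, j]
            loss = binary_loss(m * s[j])
            if decoding == "hamming":
                D += loss if m != 0 else 0.0
            elif decoding == "loss_weighted":
                D += abs(m) * loss
                norm += abs(m)
            else:
                D += weights[i, j] * loss
        if decoding == "loss_weighted":
            D /= norm
        if best_D is None or D < best_D - 1e-12:
            best, best_D = i, D
    return best


def test_decode_exact_and_tied_codewords():
    cm = build_coding_matrix("ova", 3)
    assert decode(cm, [1, -1, -1]) == 0  # exact row match, D = 0
    assert decode(cm, [1, 1, -1]) == 0   # rows 0 and 1 tie; smallest index


@pytest.mark.parametrize("design", ["ova", "ovo", "ordinal", "ternary_complete"])
@pytest.mark.parametrize("decoding", ["loss_weighted", "hamming"])
def test_decode_matches_exhaustive_minimizer(design, decoding):
    cm = build_coding_matrix(design, 3)
    for s in itertools.product((-1, 1), repeat=cm.n_columns):
        got = decode(cm, np.array(s), decoding)
        want = brute_force_decode(cm.entries, s, decoding)
        assert got == want


@pytest.mark.parametrize("design", ["ova", "ovo", "ordinal", "ternary_complete"])
def test_exact_class_codewords_decode_to_their_class(design):
    cm = build_coding_matrix(design, 3)
    for c in range(3):
        for fill in (-1, 1):
            s = np.where(cm.entries[c] == 0, fill, cm.entries[c])
            assert decode(cm, s) == c


def test_hamming_equals_loss_weighted_for_balanced_rows():
    # OVA rows all have the same number of nonzero entries, so the
    # normalisation cannot change the argmin
    cm = build_coding_matrix("ova", 3)
    for s in itertools.product((-1, 1), repeat=3):
        assert decode(cm, s, "loss_weighted") == decode(cm, s, "hamming")


def test_performance_weighted_requires_weights():
    cm = build_coding_matrix("ova", 3)
    with pytest.raises(MissingParameterError):
        decode(cm, [1, -1, -1], "performance_weighted")


def test_training_set_predictions_are_perfect_on_separable_data(separable_table):
    cm = build_coding_matrix("ova", 3, ORDER)
    model = train_ecoc(separable_table, cm, KNNSpec(k=1))
    preds = predict_ecoc_many(model, separable_table.features)
    assert np.array_equal(preds, separable_table.labels)


def test_two_class_model_maps_binary_learner_through_column():
    table = make_cluster_table(labels=("neg", "pos"), separation=10.0)
    cm = build_coding_matrix("ovo", 2, ("neg", "pos"))
    model = train_ecoc(table, cm, KNNSpec(k=1))
    assert predict_ecoc(model, table.features[0]) == "neg"
    assert predict_ecoc(model, table.features[-1]) == "pos"


def test_prediction_invariant_to_joint_column_permutation(separable_table):
    cm = build_coding_matrix("ternary_complete", 3, ORDER)
    model = train_ecoc(separable_table, cm, TreeSpec())
    perm = [3, 0, 5, 1, 4, 2]
    from colonyqc.coding import CodingMatrix
    from colonyqc.ecoc import ECOCModel

    permuted = ECOCModel(
        coding=CodingMatrix(
            entries=cm.entries[:, perm],
            design=cm.design,
            class_labels=cm.class_labels,
        ),
        learners=[model.learners[j] for j in perm],
        learner_spec=model.learner_spec,
        decoding=model.decoding,
    )
    rng = np.random.default_rng(11)
    Q = rng.normal(size=(15, separable_table.dim))
    assert np.array_equal(
        predict_ecoc_many(model, Q), predict_ecoc_many(permuted, Q)
    )


def test_performance_weighted_end_to_end(separable_table):
    cm = build_coding_matrix("ovo", 3, ORDER)
    model = train_ecoc(
        separable_table, cm, KNNSpec(k=1), decoding="performance_weighted"
    )
    assert model.weights.shape == cm.entries.shape
    assert np.allclose(model.weights.sum(axis=1), 1.0)
    preds = predict_ecoc_many(model, separable_table.features)
    assert np.array_equal(preds, separable_table.labels)


def test_end_to_end_determinism(separable_table):
    cm = build_coding_matrix("ovo", 3, ORDER)
    rng = np.random.default_rng(5)
    Q = rng.normal(size=(10, separable_table.dim))
    p1 = predict_ecoc_many(train_ecoc(separable_table, cm, TreeSpec()), Q)
    p2 = predict_ecoc_many(train_ecoc(separable_table, cm, TreeSpec()), Q)
    assert np.array_equal(p1, p2)
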