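import numpy as np
import pytest

from colonyqc.features import FeatureTable


@pytest.fixture
def rng():
    return np.random.default_rng(20261001)


def make_cluster_table(
    n_per_class=6, dim=8, separation=8.0, seed=0, labels=("bad", "good", "semigood")
) -> FeatureTable:
    """Tight, well-separated Gaussian clusters, one per class.  Means are
    block-structured (each class elevates its own block of coordinates) so
    rank- and shape-based distances see the signal as clearly as metric
    ones."""
    rng = np.random.default_rng(seed)
    block = max(1, dim // len(labels))
    rows, labs = [], []
    for c, lab in enumerate(labels):
        mean = np.zeros(dim)
        mean[c * block:(c + 1) * block] = separation
        rows.append(rng.normal(mean, 1.0, size=(n_per_class, dim)))
        labs += [lab] * n_per_class
    return FeatureTable(features=np.vstack(rows), labels=np.asarray(labs))


@pytest.fixture
def separable_table():
    return make_cluster_table()


@pytest.fixture
def binary_problem(rng):
    """A random 2-class problem with labels in {-1, +1}."""
    X = rng.normal(size=(20, 4))
    y = np.where(X[:, 0] + 0.3 * rng.normal(size=20) > 0, 1, -1)
    if len(np.unique(y)) < 2:  # pragma: no cover - essentially impossible
        y[0] = -y[0]
    return X, y
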