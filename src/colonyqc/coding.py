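"""Construction and validation of ECOC coding matrices.

A coding matrix is an M x Nc integer matrix over {-1, 0, +1}: rows are the
codewords of the M classes, columns define the Nc binary dichotomies.  An
entry of +1 (-1) puts the class on the positive (negative) side of that
dichotomy; 0 excludes the class from the training of that binary learner
(ternary coding).

Five designs are supported:

=================  ==========================  ====================
design             columns                     coding
=================  ==========================  ====================
ova                M                           binary
ovo                M(M-1)/2                    ternary
ordinal            M-1                         binary
ternary_complete   (3^M - 2^(M+1) + 1)/2       ternary
binary_complete    2^(M-1) - 1                 binary
=================  ==========================  ====================

All constructions are deterministic: the one-vs-one columns enumerate the
class pairs (i, j), i < j, lexicographically with class i on the positive
side; the ordinal column t separates classes 1..t (negative) from t+1..M
(positive); the complete designs enumerate every admissible column,
canonicalise the sign so the first nonzero entry is -1, deduplicate and
sort lexicographically.  For M = 3 the ternary-complete matrix is emitted
in the conventional published order (a fixed permutation/sign map of the
canonical enumeration).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import InvalidClassCountError, UnsupportedDesignError

DESIGNS = ("ova", "ovo", "ordinal", "ternary_complete", "binary_complete")
#: designs whose matrices contain no zeros
BINARY_DESIGNS = frozenset({"ova", "ordinal", "binary_complete"})


def expected_column_count(design: str, M: int) -> int:
    """Closed-form number of dichotomies for a design with M classes."""
    if design == "ova":
        return M
    if design == "ovo":
        return M * (M - 1) // 2
    if design == "ordinal":
        return M - 1
    if design == "ternary_complete":
        return (3**M - 2 ** (M + 1) + 1) // 2
    if design == "binary_complete":
        return 2 ** (M - 1) - 1
    raise UnsupportedDesignError(f"unknown coding design {design!r}")


@dataclass(frozen=True)
class CodingMatrix:
    """An ECOC coding matrix plus the class order its rows refer to."""

    entries: np.ndarray
    design: str
    class_labels: tuple = ()

    def __post_init__(self):
        entries = np.asarray(self.entries, dtype=np.int8)
        object.__setattr__(self, "entries", entries)
        if not self.class_labels:
            object.__setattr__(
                self, "class_labels", tuple(range(entries.shape[0]))
            )

    @property
    def n_classes(self) -> int:
        return self.entries.shape[0]

    @property
    def n_columns(self) -> int:
        return self.entries.shape[1]

    def row_of(self, label) -> int:
        return self.class_labels.index(label)

    def to_csv(self, path: str | Path) -> None:
        """Write as plain CSV: one row per class, columns f1..fNc."""
        df = pd.DataFrame(
            self.entries,
            index=[str(c) for c in self.class_labels],
            columns=[f"f{j + 1}" for j in range(self.n_columns)],
        )
        df.index.name = "class"
        df.to_csv(path)

    @classmethod
    def from_csv(cls, path: str | Path, design: str = "ova") -> "CodingMatrix":
        df = pd.read_csv(path, index_col=0)
        return cls(
            entries=df.to_numpy(dtype=np.int8),
            design=design,
            class_labels=tuple(df.index.astype(str)),
        )


@dataclass(frozen=True)
class Violation:
    """One violated coding-matrix invariant."""

    code: str
    message: str
    rows: tuple = ()
    columns: tuple = ()


def _canonical_columns(columns: Iterable[tuple]) -> list[tuple]:
    """Sign-canonicalise (first nonzero -> -1), deduplicate, sort."""
    seen = set()
    for col in columns:
        arr = tuple(col)
        first = next((v for v in arr if v != 0), 0)
        if first > 0:
            arr = tuple(-v for v in arr)
        seen.add(arr)
    return sorted(seen)


# Fixed map from the canonical M=3 ternary-complete enumeration to the
# conventional published column order; signs flip column 4 back to its
# published polarity.
_TER3_PERMUTATION = (3, 0, 5, 2, 1, 4)
_TER3_SIGNS = (1, 1, 1, -1, 1, 1)


def build_coding_matrix(
    design: str, M: int, class_labels: Sequence | None = None
) -> CodingMatrix:
    """Construct the coding matrix for ``design`` with ``M`` classes.

    Parameters
    ----------
    design:
        One of ``ova``, ``ovo``, ``ordinal``, ``ternary_complete``,
        ``binary_complete``.
    M:
        Number of classes, at least 2.
    class_labels:
        Optional explicit row-to-label assignment (length M).  Defaults to
        the row indices 0..M-1.  Note the ordinal design is sensitive to
        this order.
    """
    if design not in DESIGNS:
        raise UnsupportedDesignError(f"unknown coding design {design!r}")
    if M < 2:
        raise InvalidClassCountError(f"need at least 2 classes, got {M}")
    if class_labels is not None and len(class_labels) != M:
        raise InvalidClassCountError(
            f"class_labels has length {len(class_labels)}, expected {M}"
        )

    if design == "ova":
        entries = -np.ones((M, M), dtype=np.int8)
        np.fill_diagonal(entries, 1)
    elif design == "ovo":
        cols = []
        for i, j in itertools.combinations(range(M), 2):
            col = np.zeros(M, dtype=np.int8)
            col[i], col[j] = 1, -1
            cols.append(col)
        entries = np.stack(cols, axis=1)
    elif design == "ordinal":
        entries = np.ones((M, M - 1), dtype=np.int8)
        for t in range(1, M):
            entries[:t, t - 1] = -1
    elif design == "ternary_complete":
        candidates = (
            col
            for col in itertools.product((-1, 0, 1), repeat=M)
            if any(v == 1 for v in col) and any(v == -1 for v in col)
        )
        canon = _canonical_columns(candidates)
        if M == 3:
            canon = [
                tuple(s * v for v in canon[p])
                for p, s in zip(_TER3_PERMUTATION, _TER3_SIGNS)
            ]
        entries = np.array(canon, dtype=np.int8).T
    else:  # binary_complete
        candidates = (
            col
            for col in itertools.product((-1, 1), repeat=M)
            if any(v == 1 for v in col) and any(v == -1 for v in col)
        )
        canon = _canonical_columns(candidates)
        entries = np.array(canon, dtype=np.int8).T

    labels = tuple(class_labels) if class_labels is not None else tuple(range(M))
    return CodingMatrix(entries=entries, design=design, class_labels=labels)


def validate_coding_matrix(cm: CodingMatrix) -> list[Violation]:
    """Check all structural invariants; return one descriptor per violation."""
    violations: list[Violation] = []
    E = np.asarray(cm.entries)
    M, Nc = E.shape

    bad = np.argwhere(~np.isin(E, (-1, 0, 1)))
    if bad.size:
        violations.append(
            Violation(
                code="entries-out-of-range",
                message="entries must lie in {-1, 0, +1}",
                rows=tuple(int(r) for r in np.unique(bad[:, 0])),
                columns=tuple(int(c) for c in np.unique(bad[:, 1])),
            )
        )

    if cm.design in BINARY_DESIGNS:
        zero_cols = tuple(int(j) for j in range(Nc) if (E[:, j] == 0).any())
        if zero_cols:
            violations.append(
                Violation(
                    code="zero-in-binary-design",
                    message=f"binary design {cm.design!r} contains 0 entries",
                    columns=zero_cols,
                )
            )

    lacking = tuple(
        int(j)
        for j in range(Nc)
        if not ((E[:, j] == 1).any() and (E[:, j] == -1).any())
    )
    if lacking:
        violations.append(
            Violation(
                code="column-lacks-both-polarities",
                message="every column needs at least one +1 and one -1",
                columns=lacking,
            )
        )

    for i, j in itertools.combinations(range(M), 2):
        if np.array_equal(E[i], E[j]):
            violations.append(
                Violation(
                    code="duplicate-rows",
                    message=f"rows {i} and {j} are identical",
                    rows=(i, j),
                )
            )

    for i, j in itertools.combinations(range(Nc), 2):
        if np.array_equal(E[:, i], E[:, j]):
            violations.append(
                Violation(
                    code="duplicate-columns",
                    message=f"columns {i} and {j} are identical",
                    columns=(i, j),
                )
            )
        elif np.array_equal(E[:, i], -E[:, j]):
            violations.append(
                Violation(
                    code="negated-columns",
                    message=f"columns {i} and {j} are exact negations",
                    columns=(i, j),
                )
            )

    try:
        expected = expected_column_count(cm.design, M)
    except UnsupportedDesignError:
        expected = None
    if expected is not None and Nc != expected:
        violations.append(
            Violation(
                code="column-count-mismatch",
                message=(
                    f"design {cm.design!r} with {M} classes needs "
                    f"{expected} columns, found {Nc}"
                ),
            )
        )

    return violations
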