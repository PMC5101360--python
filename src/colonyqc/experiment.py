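"""The full configuration grid and its report renderers.

The study design crosses four coding designs with 30 learner
configurations — 21 k-NN (7 distances x 3 weightings, k selected by
nested LOO), 3 discriminant variants + the classification tree, and 5
naive Bayes variants (normal + 4 smoothing kernels) — for 120 test
setups in total.  ``run_grid`` executes each entry with its evaluation
protocol and records failures (e.g. a non-positive-definite covariance)
as structured skip entries rather than aborting, since an unevaluable
configuration is itself a result.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .ecoc import DECODINGS
from .errors import DataError
from .evaluation import (
    DEFAULT_K_GRID,
    ClassMetrics,
    NLOOResult,
    loo_evaluate,
    nloo_evaluate,
)
from .features import FeatureTable
from .learners import (
    DISTANCES,
    WEIGHTINGS,
    DiscriminantSpec,
    KNNSpec,
    LearnerSpec,
    NaiveBayesSpec,
    TreeSpec,
    describe_spec,
)

logger = logging.getLogger(__name__)

DEFAULT_DESIGNS = ("ova", "ovo", "ordinal", "ternary_complete")
DEFAULT_DISCRIMINANT_VARIANTS = ("linear", "diag_linear", "pseudo_quadratic")
DEFAULT_NB_VARIANTS = ("normal", "gaussian", "box", "epanechnikov", "triangle")


@dataclass(frozen=True)
class GridEntry:
    design: str
    spec: LearnerSpec
    mode: str  # "loo" | "nloo"

    @property
    def name(self) -> str:
        return f"{self.design}/{describe_spec(self.spec)}"


@dataclass(frozen=True)
class GridResultEntry:
    entry: GridEntry
    result: ClassMetrics | NLOOResult | None
    skipped: str | None = None  # failure reason when result is None

    @property
    def metrics(self) -> ClassMetrics | None:
        if self.result is None:
            return None
        if isinstance(self.result, NLOOResult):
            return self.result.metrics
        return self.result


@dataclass(frozen=True)
class ExperimentGrid:
    """Axes of the configuration grid; defaults reproduce the 120 setups."""

    designs: tuple = DEFAULT_DESIGNS
    knn_distances: tuple = DISTANCES
    knn_weightings: tuple = WEIGHTINGS
    k_grid: tuple = DEFAULT_K_GRID
    discriminant_variants: tuple = DEFAULT_DISCRIMINANT_VARIANTS
    include_tree: bool = True
    nb_variants: tuple = DEFAULT_NB_VARIANTS
    decoding: str = "loss_weighted"

    def __post_init__(self):
        if self.decoding not in DECODINGS:
            raise ValueError(f"unknown decoding {self.decoding!r}")


def enumerate_grid(grid: ExperimentGrid | None = None) -> list[GridEntry]:
    """Deterministic design-major enumeration of all grid entries."""
    grid = grid or ExperimentGrid()
    entries: list[GridEntry] = []
    for design in grid.designs:
        for distance in grid.knn_distances:
            for weighting in grid.knn_weightings:
                entries.append(
                    GridEntry(
                        design,
                        KNNSpec(k=1, distance=distance, weighting=weighting),
                        "nloo",
                    )
                )
        for variant in grid.discriminant_variants:
            entries.append(
                GridEntry(design, DiscriminantSpec(variant=variant), "loo")
            )
        if grid.include_tree:
            entries.append(GridEntry(design, TreeSpec(), "loo"))
        for variant in grid.nb_variants:
            if variant == "normal":
                spec = NaiveBayesSpec(density="normal")
            else:
                spec = NaiveBayesSpec(density="kde", kernel=variant)
            entries.append(GridEntry(design, spec, "loo"))
    return entries


def run_entry(
    table: FeatureTable, entry: GridEntry, grid: ExperimentGrid
) -> GridResultEntry:
    """Run one configuration; data-level failures become skip entries."""
    try:
        if entry.mode == "nloo":
            result = nloo_evaluate(
                table,
                entry.design,
                entry.spec,
                grid.k_grid,
                decoding=grid.decoding,
            )
        else:
            result = loo_evaluate(
                table, entry.design, entry.spec, decoding=grid.decoding
            )
    except DataError as exc:
        logger.info("skipping %s: %s", entry.name, exc)
        return GridResultEntry(entry=entry, result=None,
                               skipped=f"{type(exc).__name__}: {exc}")
    logger.info("%s: ACC %.4f", entry.name,
                (result.metrics if isinstance(result, NLOOResult) else result).acc)
    return GridResultEntry(entry=entry, result=result)


def run_grid(
    table: FeatureTable, grid: ExperimentGrid | None = None
) -> list[GridResultEntry]:
    """Run every configuration of the grid on one feature table."""
    grid = grid or ExperimentGrid()
    return [run_entry(table, e, grid) for e in enumerate_grid(grid)]


# --- reporting --------------------------------------------------------------

def grid_config_hash(grid: ExperimentGrid) -> str:
    blob = repr(grid).encode()
    return hashlib.sha256(blob).hexdigest()[:12]


def results_to_frame(results: Sequence[GridResultEntry]) -> pd.DataFrame:
    """Tabular report: method, per-class 'TP (TPR%)' columns, ACC.

    Skipped entries carry the failure reason in the ACC column.  Full-
    precision values are kept in parallel columns for machine use.
    """
    rows = []
    for res in results:
        row = {"design": res.entry.design,
               "method": describe_spec(res.entry.spec),
               "mode": res.entry.mode}
        m = res.metrics
        if m is None:
            row["skipped"] = res.skipped
        else:
            row.update(m.render_row())
            row["skipped"] = ""
            for i, c in enumerate(m.class_order):
                row[f"TP_{c}"] = int(m.tp[i])
                row[f"TPR_{c}"] = float(m.tpr[i])
            row["ACC_value"] = float(m.acc)
            if isinstance(res.result, NLOOResult):
                row["selected_k"] = ";".join(map(str, res.result.selected_k))
        rows.append(row)
    return pd.DataFrame(rows)


def render_text(results: Sequence[GridResultEntry]) -> str:
    """Aligned plain-text rendering shaped like the published tables."""
    df = results_to_frame(results)
    keep = [c for c in df.columns
            if not c.startswith(("TP_", "TPR_", "ACC_value", "selected_k"))]
    df = df[keep].fillna("")
    if "skipped" in df.columns and (df["skipped"] == "").all():
        df = df.drop(columns=["skipped"])
    return df.to_string(index=False)


def results_to_json(results: Sequence[GridResultEntry]) -> str:
    payload = []
    for res in results:
        item = {"design": res.entry.design,
                "method": describe_spec(res.entry.spec),
                "mode": res.entry.mode,
                "skipped": res.skipped}
        m = res.metrics
        if m is not None:
            item["acc"] = float(m.acc)
            item["tp"] = {str(c): int(m.tp[i])
                          for i, c in enumerate(m.class_order)}
            item["tpr"] = {str(c): float(m.tpr[i])
                           for i, c in enumerate(m.class_order)}
            item["confusion"] = m.confusion.tolist()
            if isinstance(res.result, NLOOResult):
                item["selected_k"] = list(res.result.selected_k)
        payload.append(item)
    return json.dumps(payload, indent=2)


def write_report(
    results: Sequence[GridResultEntry],
    path: str | Path,
    fmt: str = "csv",
    header_note: str = "",
) -> None:
    path = Path(path)
    if fmt == "csv":
        results_to_frame(results).to_csv(path, index=False)
    elif fmt == "json":
        path.write_text(results_to_json(results))
    elif fmt == "text":
        note = f"# {header_note}\n" if header_note else ""
        path.write_text(note + render_text(results) + "\n")
    else:
        raise ValueError(f"unknown report format {fmt!r}")
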