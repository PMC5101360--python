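"""Image features: mean SIFT descriptors and table preprocessing.

Each colony image is reduced to a single 128-dimensional vector: run a
scale-invariant keypoint detector over the grayscale image, collect the
p x 128 descriptor matrix, and take the component-wise arithmetic mean.
The assembled n x 128 table is then column-standardised (zero mean, unit
sample variance) and min-max rescaled so every non-constant column spans
exactly [-1, +1].

Keypoint detection/description is delegated to scikit-image's SIFT
implementation; descriptor values are therefore deterministic for a fixed
backend but not identical across SIFT implementations.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import imageio.v3 as iio
import numpy as np
import pandas as pd
from skimage.feature import SIFT

from .errors import (
    EmptyInputError,
    InsufficientRowsError,
    NoKeypointsError,
    UnknownLabelError,
)

DESCRIPTOR_DIM = 128


@dataclass(frozen=True)
class DescriptorSet:
    """All keypoint descriptors of one image (p x 128)."""

    descriptors: np.ndarray

    def __post_init__(self):
        d = np.asarray(self.descriptors, dtype=float)
        if d.ndim != 2 or d.shape[0] < 1 or d.shape[1] != DESCRIPTOR_DIM:
            raise ValueError(
                f"descriptors must be p x {DESCRIPTOR_DIM} with p >= 1, "
                f"got shape {d.shape}"
            )
        object.__setattr__(self, "descriptors", d)

    @property
    def n_keypoints(self) -> int:
        return self.descriptors.shape[0]


@dataclass
class FeatureTable:
    """Per-image feature vectors with aligned labels and provenance ids."""

    features: np.ndarray
    labels: np.ndarray
    ids: tuple = ()

    def __post_init__(self):
        self.features = np.asarray(self.features, dtype=float)
        self.labels = np.asarray(self.labels)
        if self.features.ndim != 2 or self.features.shape[0] < 1:
            raise ValueError("features must be a nonempty 2-D matrix")
        if len(self.labels) != self.features.shape[0]:
            raise ValueError("labels must align with feature rows")
        if not self.ids:
            self.ids = tuple(f"row{i:04d}" for i in range(len(self.labels)))
        elif len(self.ids) != self.features.shape[0]:
            raise ValueError("ids must align with feature rows")

    @property
    def n(self) -> int:
        return self.features.shape[0]

    @property
    def dim(self) -> int:
        return self.features.shape[1]

    def class_order(self) -> tuple:
        """Distinct labels in sorted order (the default row order of
        coding matrices; for the study's labels this is bad < good <
        semigood, matching the published table columns)."""
        return tuple(sorted(np.unique(self.labels).tolist()))

    def subset(self, idx) -> "FeatureTable":
        idx = np.asarray(idx)
        return FeatureTable(
            features=self.features[idx],
            labels=self.labels[idx],
            ids=tuple(self.ids[i] for i in np.atleast_1d(idx)),
        )

    def to_csv(self, path: str | Path) -> None:
        """CSV with header id,label,f001..f128 at full decimal precision."""
        cols = [f"f{j + 1:03d}" for j in range(self.dim)]
        df = pd.DataFrame(self.features, columns=cols)
        df.insert(0, "label", self.labels)
        df.insert(0, "id", list(self.ids))
        df.to_csv(path, index=False, float_format="%.17g")

    @classmethod
    def from_csv(cls, path: str | Path) -> "FeatureTable":
        df = pd.read_csv(path, float_precision="round_trip")
        feature_cols = [c for c in df.columns if c.startswith("f")]
        return cls(
            features=df[feature_cols].to_numpy(dtype=float),
            labels=df["label"].to_numpy(),
            ids=tuple(df["id"].astype(str)),
        )


def load_image(path: str | Path) -> np.ndarray:
    """Read a PNG/TIFF image as a float grayscale array in [0, 1].

    Colour images are converted by the Rec. 601 luminance weights;
    integer dtypes are rescaled by their maximum representable value.
    """
    raw = np.asarray(iio.imread(path))
    img = raw
    if img.ndim == 3:
        img = img[..., :3] @ np.array([0.299, 0.587, 0.114])
    img = img.astype(float)
    if np.issubdtype(raw.dtype, np.integer):
        img = img / np.iinfo(raw.dtype).max
    return img


def extract_descriptors(
    image: np.ndarray,
    image_id: str = "<array>",
    backend: str = "sift",
    **backend_kwargs,
) -> DescriptorSet:
    """Detect keypoints and return their 128-wide descriptors.

    Raises :class:`NoKeypointsError` (carrying ``image_id``) when the
    detector finds nothing — e.g. on a constant image; callers may relax
    detection via ``backend_kwargs`` (forwarded to the backend).
    """
    if backend != "sift":
        raise ValueError(f"unknown descriptor backend {backend!r}")
    image = np.asarray(image, dtype=float)
    if image.ndim != 2 or min(image.shape) < 16:
        raise ValueError("image must be 2-D grayscale, at least 16 x 16")
    if np.ptp(image) == 0:
        raise NoKeypointsError(image_id, f"image {image_id!r} is constant")
    detector = SIFT(**backend_kwargs)
    try:
        detector.detect_and_extract(image)
    except RuntimeError as exc:  # skimage raises when nothing is found
        raise NoKeypointsError(image_id) from exc
    desc = np.asarray(detector.descriptors, dtype=float)
    if desc.size == 0:
        raise NoKeypointsError(image_id)
    return DescriptorSet(descriptors=desc)


def mean_descriptor(ds: DescriptorSet) -> np.ndarray:
    """Component-wise arithmetic mean over all keypoint descriptors."""
    if ds is None or ds.descriptors.shape[0] == 0:
        raise EmptyInputError("cannot average an empty descriptor set")
    return ds.descriptors.mean(axis=0)


@dataclass
class Preprocessor:
    """Column standardisation followed by min-max scaling to [-1, 1].

    Fitting records per-column mean, sample std (n-1), and the post-
    standardisation extremes; constant columns are mapped to all-zeros.
    A fitted instance can transform held-out rows with the training
    fold's parameters (the leakage-free per-fold mode).
    """

    mean_: np.ndarray | None = None
    std_: np.ndarray | None = None
    zmin_: np.ndarray | None = None
    zmax_: np.ndarray | None = None

    def fit(self, features: np.ndarray) -> "Preprocessor":
        X = np.asarray(features, dtype=float)
        if X.shape[0] < 2:
            raise InsufficientRowsError("preprocessing needs at least 2 rows")
        self.mean_ = X.mean(axis=0)
        self.std_ = X.std(axis=0, ddof=1)
        safe = np.where(self.std_ > 0, self.std_, 1.0)
        Z = (X - self.mean_) / safe
        self.zmin_ = Z.min(axis=0)
        self.zmax_ = Z.max(axis=0)
        return self

    def transform(self, features: np.ndarray) -> np.ndarray:
        X = np.asarray(features, dtype=float)
        safe_std = np.where(self.std_ > 0, self.std_, 1.0)
        Z = (X - self.mean_) / safe_std
        span = self.zmax_ - self.zmin_
        safe_span = np.where(span > 0, span, 1.0)
        out = 2.0 * (Z - self.zmin_) / safe_span - 1.0
        constant = (self.std_ == 0) | (span == 0)
        out[:, constant] = 0.0
        return out


def preprocess(table: FeatureTable) -> FeatureTable:
    """Standardise and rescale the whole table (the study's stated order:
    preprocessing precedes cross-validation)."""
    pp = Preprocessor().fit(table.features)
    return FeatureTable(
        features=pp.transform(table.features),
        labels=table.labels,
        ids=table.ids,
    )


def image_to_feature_row(image: np.ndarray, image_id: str = "<array>",
                         **backend_kwargs) -> np.ndarray:
    """Convenience: image -> descriptors -> mean descriptor."""
    return mean_descriptor(extract_descriptors(image, image_id, **backend_kwargs))


def build_feature_table(
    images: Sequence[np.ndarray],
    labels: Sequence,
    ids: Sequence[str] | None = None,
    **backend_kwargs,
) -> FeatureTable:
    """Assemble a raw (unpreprocessed) mean-descriptor table from images."""
    if len(images) == 0:
        raise EmptyInputError("no images given")
    if len(images) != len(labels):
        raise UnknownLabelError("labels must align with images")
    ids = tuple(ids) if ids is not None else tuple(
        f"img{i:04d}" for i in range(len(images))
    )
    rows = [
        image_to_feature_row(img, image_id=i, **backend_kwargs)
        for img, i in zip(images, ids)
    ]
    return FeatureTable(
        features=np.vstack(rows), labels=np.asarray(labels), ids=ids
    )
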