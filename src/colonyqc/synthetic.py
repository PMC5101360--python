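"""Synthetic colony data: Gaussian feature tables and rendered images.

The study's 173-image colony dataset is private, so everything testable
is exercised on synthetic stand-ins with the same composition (41 bad /
74 good / 58 semigood):

* :func:`generate_feature_table` draws 128-dimensional per-image mean
  descriptors from isotropic Gaussians whose class means sit pairwise
  ``separation`` * ``std`` apart along distinct coordinate axes;
* :func:`generate_colony_image` renders a colony-like grayscale image —
  an elliptical colony on a feeder-cell-textured background — whose
  class character follows the published grading criteria: *good* has a
  rounded shape with sharp, defined edges and an even translucent
  interior; *semigood* keeps clear edges but shows interior colour and
  structure changes; *bad* has partially lost edges and bright
  three-dimensional blobs.

Both generators are deterministic per seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .errors import TooSmallImageError
from .features import FeatureTable

#: published composition of the colony dataset
DEFAULT_CLASS_COUNTS = {"bad": 41, "good": 74, "semigood": 58}

#: rendering presets per quality grade: (edge_sharpness, heterogeneity, blobs)
CLASS_PRESETS = {
    "good": (0.9, 0.1, 0),
    "semigood": (0.8, 0.5, 0),
    "bad": (0.3, 0.6, 3),
}


@dataclass(frozen=True)
class SyntheticFeatureConfig:
    """Gaussian mean-descriptor generator settings.

    ``separation`` is the pairwise distance between class means in units
    of the within-class standard deviation.
    """

    class_counts: dict = field(
        default_factory=lambda: dict(DEFAULT_CLASS_COUNTS)
    )
    dim: int = 128
    separation: float = 3.0
    std: float = 1.0
    seed: int = 0

    def __post_init__(self):
        if any(n < 1 for n in self.class_counts.values()):
            raise ValueError("class counts must be >= 1")
        if self.separation < 0:
            raise ValueError("separation must be >= 0")
        if self.std <= 0:
            raise ValueError("std must be > 0")
        if self.dim < len(self.class_counts):
            raise ValueError("dim must be >= the number of classes")


@dataclass(frozen=True)
class SyntheticImageConfig:
    """Colony-image renderer settings (one image per config)."""

    label: str = "good"
    size: tuple = (256, 256)
    edge_sharpness: float | None = None   # None -> class preset
    heterogeneity: float | None = None
    blob_count: int | None = None
    feeder_amplitude: float = 0.08
    seed: int = 0

    def __post_init__(self):
        if self.label not in CLASS_PRESETS:
            raise ValueError(f"unknown class label {self.label!r}")
        for v, name in (
            (self.edge_sharpness, "edge_sharpness"),
            (self.heterogeneity, "heterogeneity"),
        ):
            if v is not None and not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.blob_count is not None and self.blob_count < 0:
            raise ValueError("blob_count must be >= 0")
        if max(self.size) > 1608 * 1208:
            raise ValueError("image size beyond supported range")

    def resolved(self) -> tuple[float, float, int]:
        sharp, hetero, blobs = CLASS_PRESETS[self.label]
        return (
            sharp if self.edge_sharpness is None else self.edge_sharpness,
            hetero if self.heterogeneity is None else self.heterogeneity,
            blobs if self.blob_count is None else self.blob_count,
        )


def generate_feature_table(cfg: SyntheticFeatureConfig) -> FeatureTable:
    """Draw a labelled Gaussian feature table, deterministic per seed."""
    rng = np.random.default_rng(cfg.seed)
    classes = sorted(cfg.class_counts)  # deterministic class order
    means = np.zeros((len(classes), cfg.dim))
    # distinct axes: pairwise mean distance is exactly separation * std
    for c in range(len(classes)):
        means[c, c] = cfg.separation * cfg.std / np.sqrt(2.0)
    rows, labels, ids = [], [], []
    for c, name in enumerate(classes):
        n = cfg.class_counts[name]
        rows.append(rng.normal(means[c], cfg.std, size=(n, cfg.dim)))
        labels += [name] * n
        ids += [f"synth-{name}-{i:03d}" for i in range(n)]
    return FeatureTable(
        features=np.vstack(rows), labels=np.asarray(labels), ids=tuple(ids)
    )


def class_means(cfg: SyntheticFeatureConfig) -> dict:
    """The true class means of :func:`generate_feature_table`."""
    classes = sorted(cfg.class_counts)
    out = {}
    for c, name in enumerate(classes):
        m = np.zeros(cfg.dim)
        m[c] = cfg.separation * cfg.std / np.sqrt(2.0)
        out[name] = m
    return out


def _smooth_noise(rng, shape, low_sigma, high_sigma) -> np.ndarray:
    """Bandpass-filtered noise, normalised to unit max amplitude."""
    noise = rng.normal(size=shape)
    band = ndimage.gaussian_filter(noise, low_sigma) - ndimage.gaussian_filter(
        noise, high_sigma
    )
    peak = np.abs(band).max()
    return band / peak if peak > 0 else band


def _render_colony(cfg: SyntheticImageConfig) -> tuple[np.ndarray, np.ndarray]:
    """Render one image; also return the normalised elliptical radius map
    (1.0 at the colony boundary), which the radial-profile helper uses."""
    h, w = cfg.size
    if min(h, w) < 32:
        raise TooSmallImageError("image must be at least 32 x 32")
    sharp, hetero, blobs = cfg.resolved()
    rng = np.random.default_rng(cfg.seed)

    yy, xx = np.mgrid[0:h, 0:w].astype(float)
    cy, cx = (h - 1) / 2.0, (w - 1) / 2.0
    # slightly jittered elliptical colony footprint
    ry = 0.35 * h * (1.0 + 0.08 * rng.uniform(-1, 1))
    rx = 0.35 * w * (1.0 + 0.08 * rng.uniform(-1, 1))
    r = np.sqrt(((yy - cy) / ry) ** 2 + ((xx - cx) / rx) ** 2)

    # edge transition width shrinks with sharpness
    width = 0.008 + 0.18 * (1.0 - sharp)
    mask = 1.0 / (1.0 + np.exp((r - 1.0) / width))

    background = 0.45 + cfg.feeder_amplitude * _smooth_noise(
        rng, (h, w), 1.5, 5.0
    )

    interior = 0.72 + 0.35 * hetero * _smooth_noise(rng, (h, w), 6.0, 20.0)

    image = background * (1.0 - mask) + interior * mask

    # bright rounded bumps: the three-dimensional structures of bad colonies
    sigma = 0.06 * min(h, w)
    for _ in range(blobs):
        theta = rng.uniform(0, 2 * np.pi)
        rho = rng.uniform(0.0, 0.55)
        by = cy + rho * ry * np.sin(theta)
        bx = cx + rho * rx * np.cos(theta)
        bump = np.exp(-(((yy - by) ** 2 + (xx - bx) ** 2) / (2 * sigma**2)))
        image += 0.45 * bump

    return np.clip(image, 0.0, 1.0), r


def generate_colony_image(cfg: SyntheticImageConfig) -> np.ndarray:
    """Render one colony-like grayscale image in [0, 1]."""
    image, _ = _render_colony(cfg)
    return image


def colony_radial_profile(
    cfg: SyntheticImageConfig, n_bins: int = 80
) -> np.ndarray:
    """Mean intensity per bin of normalised colony radius (0 = centre,
    1 = boundary; bins run to 1.4 to cover the edge transition)."""
    image, r = _render_colony(cfg)
    edges = np.linspace(0.0, 1.4, n_bins + 1)
    idx = np.clip(np.digitize(r.ravel(), edges) - 1, 0, n_bins - 1)
    sums = np.bincount(idx, image.ravel(), minlength=n_bins)
    counts = np.bincount(idx, minlength=n_bins)
    return sums / np.maximum(counts, 1)


def generate_image_set(
    per_class: int = 20,
    size: tuple = (256, 256),
    seed: int = 0,
    feeder_amplitude: float = 0.08,
) -> tuple[list[np.ndarray], list[str], list[str]]:
    """Render ``per_class`` images for each quality grade.

    Returns (images, labels, ids); image seeds are derived from ``seed``
    so the whole set is reproducible.
    """
    images, labels, ids = [], [], []
    for c, label in enumerate(sorted(CLASS_PRESETS)):
        for i in range(per_class):
            cfg = SyntheticImageConfig(
                label=label,
                size=size,
                feeder_amplitude=feeder_amplitude,
                seed=seed * 100_003 + c * 1_000 + i,
            )
            images.append(generate_colony_image(cfg))
            labels.append(label)
            ids.append(f"synth-{label}-{i:03d}")
    return images, labels, ids
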