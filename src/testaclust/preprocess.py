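"""Image preprocessing: the three cluster-ready representations.

Each input patch is turned into the three derivatives that downstream
clustering consumes:

1. **grayscale** — luminance image in [0, 1];
2. **threshold** — global binarization at a fixed gray level (default 0.6;
   pixels *at or above* the threshold are foreground);
3. **colored components** — 8-connected labelling of the binary foreground,
   one distinct color per component, with per-component region measurements.

The module also provides patch extraction from composite frames (crop to the
largest foreground component's bounding box, rescale to 250 × 250), small
rotation/shift augmentation, seeded shuffling/splitting, and feature
vectorization for clustering.

Coordinates are row-major, origin top-left, 0-based; bounding boxes are
half-open.
"""

from __future__ import annotations

import dataclasses
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage import measure, transform
from skimage.color import hsv2rgb

from ._seeds import derive_seed
from .errors import EmptyPatchError, InvalidInputError
from .synthetic import PATCH_SIDE, SeedImage

__all__ = [
    "PreprocessConfig",
    "AugmentConfig",
    "RepresentationSet",
    "to_grayscale",
    "binarize",
    "label_components",
    "measure_regions",
    "colorize_labels",
    "compute_representations",
    "extract_patch",
    "augment",
    "shuffle_split",
    "vectorize",
    "REGION_TABLE_COLUMNS",
]

#: ITU-R BT.601 luminance weights (R, G, B).
_LUMA_WEIGHTS = np.array([0.299, 0.587, 0.114])

REGION_TABLE_COLUMNS = [
    "label", "area", "bbox_r0", "bbox_c0", "bbox_r1", "bbox_c1",
    "centroid_r", "centroid_c", "perimeter", "eccentricity",
]


@dataclasses.dataclass(frozen=True)
class PreprocessConfig:
    """Preprocessing knobs.

    ``threshold`` is the global binarization level in the closed range
    [0, 1]; ``connectivity`` is 4 or 8 (8 merges corner-touching pixels);
    ``downsample_side`` sets the side of the flattened pixel feature grid;
    ``adaptive`` switches to a local-mean threshold (offset by ``threshold``
    relative to 0.5) instead of the global one.
    """

    crop_size: int = PATCH_SIDE
    threshold: float = 0.6
    connectivity: int = 8
    downsample_side: int = 64
    adaptive: bool = False
    adaptive_block: int = 51

    def __post_init__(self):
        if not 0.0 <= self.threshold <= 1.0:
            raise InvalidInputError("threshold must be in [0, 1]")
        if self.crop_size <= 0:
            raise InvalidInputError("crop_size must be positive")
        if self.connectivity not in (4, 8):
            raise InvalidInputError("connectivity must be 4 or 8")
        if self.downsample_side <= 0:
            raise InvalidInputError("downsample_side must be positive")


@dataclasses.dataclass(frozen=True)
class AugmentConfig:
    """Random rotation (≤ max_rotation_deg) and shift (≤ shift_fraction × side)."""

    max_rotation_deg: float = 5.0
    shift_fraction: float = 0.01
    seed: int = 0

    def __post_init__(self):
        if self.max_rotation_deg < 0:
            raise InvalidInputError("max_rotation_deg must be >= 0")
        if not 0.0 <= self.shift_fraction < 1.0:
            raise InvalidInputError("shift_fraction must be in [0, 1)")


@dataclasses.dataclass
class RepresentationSet:
    """The three cluster-ready derivatives of one image."""

    image_id: str
    grayscale: np.ndarray
    binary: np.ndarray
    labels: np.ndarray
    colored: np.ndarray
    region_table: pd.DataFrame

    @property
    def n_components(self) -> int:
        return int(self.labels.max())


def to_grayscale(raster: np.ndarray) -> np.ndarray:
    """Convert a 3-channel image in [0, 1] to luminance (ITU-R BT.601 weights)."""
    arr = np.asarray(raster, dtype=float)
    if arr.ndim == 2:
        gray = arr
    elif arr.ndim == 3 and arr.shape[2] == 3:
        gray = arr @ _LUMA_WEIGHTS
    else:
        raise InvalidInputError(
            f"expected a 2-D gray or H x W x 3 color image, got shape {arr.shape}"
        )
    if gray.min() < -1e-9 or gray.max() > 1 + 1e-9:
        raise InvalidInputError("channel values must lie in [0, 1]")
    return np.clip(gray, 0.0, 1.0)


def binarize(gray: np.ndarray, threshold: float = 0.6) -> np.ndarray:
    """Global threshold: pixels >= threshold map to 1 (foreground), else 0."""
    if not 0.0 <= threshold <= 1.0:
        raise InvalidInputError("threshold must be in [0, 1]")
    arr = np.asarray(gray, dtype=float)
    if arr.min() < 0 or arr.max() > 1:
        raise InvalidInputError("gray values must lie in [0, 1]")
    return (arr >= threshold).astype(np.uint8)


def binarize_adaptive(gray: np.ndarray, offset: float = 0.0,
                      block: int = 51) -> np.ndarray:
    """Local-mean threshold: pixel >= local mean + offset maps to 1."""
    arr = np.asarray(gray, dtype=float)
    local = ndimage.uniform_filter(arr, size=block, mode="reflect")
    return (arr >= local + offset).astype(np.uint8)


def label_components(binary: np.ndarray, connectivity: int = 8):
    """Label maximal connected foreground regions 1..L (0 = background)."""
    arr = np.asarray(binary)
    if not np.isin(arr, (0, 1)).all():
        raise InvalidInputError("input must be binary (values in {0, 1})")
    if connectivity not in (4, 8):
        raise InvalidInputError("connectivity must be 4 or 8")
    skconn = 1 if connectivity == 4 else 2
    labels, count = measure.label(arr, connectivity=skconn, return_num=True)
    return labels.astype(np.int32), int(count)


def measure_regions(labels: np.ndarray) -> pd.DataFrame:
    """Per-component measurements: area, bounding box, centroid, perimeter, eccentricity."""
    labels = np.asarray(labels)
    if labels.max() == 0:
        return pd.DataFrame(columns=REGION_TABLE_COLUMNS)
    props = measure.regionprops_table(
        labels,
        properties=("label", "area", "bbox", "centroid", "perimeter",
                    "eccentricity"),
    )
    df = pd.DataFrame(props).rename(columns={
        "bbox-0": "bbox_r0", "bbox-1": "bbox_c0",
        "bbox-2": "bbox_r1", "bbox-3": "bbox_c1",
        "centroid-0": "centroid_r", "centroid-1": "centroid_c",
    })
    return df[REGION_TABLE_COLUMNS]


def colorize_labels(labels: np.ndarray, seed: int = 0) -> np.ndarray:
    """Map background to black and each label to a distinct color.

    Colors are evenly spaced hues in a seed-shuffled order, so any L gets
    exactly L distinct non-background colors, deterministically per seed.
    """
    labels = np.asarray(labels)
    count = int(labels.max())
    out = np.zeros(labels.shape + (3,), dtype=float)
    if count == 0:
        return out
    rng = np.random.default_rng(seed)
    hues = rng.permutation(count) / count
    sat = np.full(count, 0.75)
    val = 0.6 + 0.4 * (np.arange(count) % 2)  # alternate brightness for contrast
    palette = hsv2rgb(np.stack([hues, sat, val], axis=1)[None, :, :])[0]
    for lab in range(1, count + 1):
        out[labels == lab] = palette[lab - 1]
    return out


def compute_representations(image: SeedImage, config: PreprocessConfig | None = None,
                            color_seed: int = 0) -> RepresentationSet:
    """Derive the grayscale / threshold / colored-component set for one image."""
    config = config or PreprocessConfig()
    gray = to_grayscale(image.raster)
    if config.adaptive:
        binary = binarize_adaptive(gray, offset=config.threshold - 0.5,
                                   block=config.adaptive_block)
    else:
        binary = binarize(gray, config.threshold)
    labels, _ = label_components(binary, config.connectivity)
    table = measure_regions(labels)
    colored = colorize_labels(labels, seed=derive_seed(color_seed, image.id))
    return RepresentationSet(image_id=image.id, grayscale=gray, binary=binary,
                             labels=labels, colored=colored, region_table=table)


def extract_patch(image: np.ndarray, config: PreprocessConfig | None = None) -> SeedImage:
    """Crop the largest foreground component of a frame into a square patch.

    The frame is converted to grayscale, thresholded and labelled; the
    bounding box of the largest component is cropped and rescaled to
    ``crop_size`` × ``crop_size``.
    """
    config = config or PreprocessConfig()
    gray = to_grayscale(image)
    binary = binarize(gray, config.threshold)
    labels, count = label_components(binary, config.connectivity)
    if count == 0:
        raise EmptyPatchError("no foreground component to crop")
    areas = np.bincount(labels.ravel())[1:]
    biggest = int(np.argmax(areas)) + 1
    rows, cols = np.nonzero(labels == biggest)
    r0, r1 = rows.min(), rows.max() + 1
    c0, c1 = cols.min(), cols.max() + 1
    crop = gray[r0:r1, c0:c1]
    side = config.crop_size
    patch = transform.resize(crop, (side, side), order=1, anti_aliasing=True,
                             preserve_range=True)
    patch = np.clip(patch, 0.0, 1.0)
    return SeedImage(id="patch", raster=patch, truth=None, provenance="external")


def sample_transform(rng: np.random.Generator, config: AugmentConfig,
                     side: int = PATCH_SIDE):
    """Draw one (angle_deg, row_shift, col_shift) augmentation triple."""
    angle = rng.uniform(-config.max_rotation_deg, config.max_rotation_deg)
    max_shift = config.shift_fraction * side
    dr = rng.uniform(-max_shift, max_shift)
    dc = rng.uniform(-max_shift, max_shift)
    return angle, dr, dc


def augment(image: SeedImage, config: AugmentConfig | None = None) -> SeedImage:
    """Small random rotation and shift; dimensions and value range preserved."""
    config = config or AugmentConfig()
    rng = np.random.default_rng(config.seed)
    side = image.raster.shape[0]
    angle, dr, dc = sample_transform(rng, config, side)
    out = ndimage.rotate(image.raster, angle, reshape=False, order=1,
                         mode="reflect")
    out = ndimage.shift(out, (dr, dc), order=1, mode="reflect")
    out = np.clip(out, 0.0, 1.0)
    return SeedImage(id=f"{image.id}/aug{config.seed}", raster=out,
                     truth=image.truth, provenance=image.provenance)


def shuffle_split(images: Sequence, train_fraction: float, seed: int = 0):
    """Seeded shuffle then split: train size = floor(n × train_fraction)."""
    n = len(images)
    if n < 2:
        raise InvalidInputError("need at least 2 items to split")
    if not 0.0 < train_fraction < 1.0:
        raise InvalidInputError("train_fraction must be in (0, 1)")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    n_train = int(np.floor(n * train_fraction))
    train = [images[i] for i in perm[:n_train]]
    test = [images[i] for i in perm[n_train:]]
    return train, test


def _colored_features(rep: RepresentationSet) -> np.ndarray:
    """Fixed-length 10-vector summary of the colored-component representation.

    The colorized raster itself carries arbitrary colors, so the colored
    representation is summarized by its region statistics instead:
    [component count, area mean, area sd, perimeter mean, perimeter sd,
    eccentricity mean, eccentricity sd, foreground fraction,
    largest-component fraction, component density].
    """
    table = rep.region_table
    total_px = rep.binary.size
    if len(table) == 0:
        return np.zeros(10)
    area = table["area"].to_numpy(dtype=float)
    perim = table["perimeter"].to_numpy(dtype=float)
    ecc = table["eccentricity"].to_numpy(dtype=float)
    fg = float(area.sum())
    return np.array([
        float(len(table)),
        area.mean(), area.std(),
        perim.mean(), perim.std(),
        ecc.mean(), ecc.std(),
        fg / total_px,
        area.max() / total_px,
        len(table) / total_px * 1e4,  # components per 100 x 100 px
    ])


def vectorize(rep: RepresentationSet, which: str,
              config: PreprocessConfig | None = None) -> np.ndarray:
    """Feature vector for one representation.

    grayscale / threshold: the raster downsampled to ``downsample_side``²
    and flattened (values in [0, 1]); colored: the 10-element region-table
    summary.  Output length depends only on (which, config).
    """
    config = config or PreprocessConfig()
    if which == "grayscale":
        raster = rep.grayscale
    elif which == "threshold":
        raster = rep.binary.astype(float)
    elif which == "colored":
        return _colored_features(rep)
    else:
        raise InvalidInputError(
            "which must be 'grayscale', 'threshold' or 'colored'"
        )
    if raster is None:
        raise InvalidInputError(f"representation {which!r} missing")
    side = config.downsample_side
    small = transform.resize(raster, (side, side), order=1, anti_aliasing=True,
                             preserve_range=True)
    return np.clip(small, 0.0, 1.0).ravel()


def feature_matrix(reps: Sequence[RepresentationSet], which: str,
                   config: PreprocessConfig | None = None) -> np.ndarray:
    """Stack per-image feature vectors into an (n_images, n_features) matrix."""
    return np.vstack([vectorize(r, which, config) for r in reps])
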