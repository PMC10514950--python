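"""Shared domain types and conventions for cytology segmentation.

A sample is one RGB microscopy image with two binary ground-truth masks:
cytoplasm (whole-cell regions) and nucleus. Masks are {0, 1} uint8 in
memory, {0, 255} single-channel PNG on disk, row-major with the origin at
the top-left. Everything downstream — training, ensembling, evaluation —
speaks these types.
"""

from __future__ import annotations

import dataclasses
import enum
from pathlib import Path

import numpy as np
from PIL import Image
from scipy import ndimage

__all__ = [
    "TaskType", "ImageSample", "ProbabilityMap", "BinaryMask",
    "ConfusionCounts", "MetricSet", "validate_sample", "binarize_stored_mask",
    "render_overlay", "save_sample", "load_sample", "sample_paths",
]

MIN_SIZE = 16


class TaskType(enum.Enum):
    CYTOPLASM = "cytoplasm"
    NUCLEUS = "nucleus"


@dataclasses.dataclass
class ImageSample:
    id: str
    image: np.ndarray           # H x W x 3 uint8
    cytoplasm_mask: np.ndarray  # H x W uint8 in {0,1}
    nucleus_mask: np.ndarray    # H x W uint8 in {0,1}

    def mask_for(self, task: TaskType) -> np.ndarray:
        return self.cytoplasm_mask if task is TaskType.CYTOPLASM else self.nucleus_mask

    @property
    def shape(self) -> tuple[int, int]:
        return self.image.shape[:2]


@dataclasses.dataclass
class ProbabilityMap:
    task: TaskType
    probs: np.ndarray  # H x W floats in [0,1]

    def __post_init__(self):
        p = np.asarray(self.probs)
        if p.ndim != 2:
            raise ValueError("probability map must be 2-D")
        if p.size and (p.min() < 0 or p.max() > 1):
            raise ValueError("probabilities must lie in [0,1]")
        self.probs = p


@dataclasses.dataclass
class BinaryMask:
    task: TaskType
    mask: np.ndarray  # H x W in {0,1}

    def __post_init__(self):
        m = np.asarray(self.mask)
        if m.ndim != 2:
            raise ValueError("mask must be 2-D")
        if m.size and not np.isin(np.unique(m), (0, 1)).all():
            raise ValueError("mask values must be 0/1")
        self.mask = m.astype(np.uint8)


@dataclasses.dataclass(frozen=True)
class ConfusionCounts:
    """Pixel confusion totals; the sufficient statistic for all metrics."""

    tp: int = 0
    fp: int = 0
    tn: int = 0
    fn: int = 0

    def __add__(self, other: "ConfusionCounts") -> "ConfusionCounts":
        return ConfusionCounts(self.tp + other.tp, self.fp + other.fp,
                               self.tn + other.tn, self.fn + other.fn)

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn

    def as_array(self) -> np.ndarray:
        return np.array([self.tp, self.fp, self.fn, self.tn], dtype=np.int64)


@dataclasses.dataclass(frozen=True)
class MetricSet:
    dice: float
    sensitivity: float
    specificity: float

    def as_dict(self) -> dict[str, float]:
        return dataclasses.asdict(self)


def validate_sample(sample: ImageSample) -> list[str]:
    """Report every invariant violation; an empty list means conforming."""
    violations: list[str] = []
    img = np.asarray(sample.image)
    if img.ndim != 3 or img.shape[2] != 3:
        violations.append(f"image must be HxWx3, got shape {img.shape}")
        return violations
    h, w = img.shape[:2]
    if h < MIN_SIZE or w < MIN_SIZE:
        violations.append(f"image {h}x{w} below minimum size {MIN_SIZE}")
    for name, mask in (("cytoplasm", sample.cytoplasm_mask),
                       ("nucleus", sample.nucleus_mask)):
        m = np.asarray(mask)
        if m.ndim != 2:
            violations.append(f"{name} mask must be 2-D, got {m.ndim}-D")
            continue
        if m.shape != (h, w):
            violations.append(
                f"{name} mask shape {m.shape} mismatches image {(h, w)}")
        bad = np.setdiff1d(np.unique(m), [0, 1])
        if bad.size:
            violations.append(
                f"{name} mask contains non-binary values {bad[:4].tolist()}")
    return violations


def binarize_stored_mask(raster: np.ndarray) -> np.ndarray:
    """Stored 8-bit grayscale -> {0,1}; >127 is foreground.

    Guards against lossy-compression speckle in legacy JPEG-encoded masks:
    either a clean {0,255} PNG or a mildly corrupted JPEG binarizes to the
    same mask.
    """
    r = np.asarray(raster)
    if r.ndim != 2:
        raise ValueError(f"expected single-channel raster, got shape {r.shape}")
    return (r > 127).astype(np.uint8)


def _boundary(mask: np.ndarray) -> np.ndarray:
    """Pixels inside the mask that touch its outside (border pixels count)."""
    m = mask.astype(bool)
    eroded = ndimage.binary_erosion(m, structure=np.ones((3, 3)), border_value=0)
    return m & ~eroded


CYTO_COLOR = (0, 200, 0)
NUC_COLOR = (220, 0, 0)


def render_overlay(sample: ImageSample, pred_cyto: BinaryMask,
                   pred_nuc: BinaryMask) -> np.ndarray:
    """Draw predicted cytoplasm/nucleus boundaries on a copy of the image."""
    h, w = sample.shape
    for bm in (pred_cyto, pred_nuc):
        if bm.mask.shape != (h, w):
            raise ValueError(
                f"prediction shape {bm.mask.shape} mismatches image {(h, w)}")
    out = np.asarray(sample.image).copy()
    for bm, color in ((pred_cyto, CYTO_COLOR), (pred_nuc, NUC_COLOR)):
        out[_boundary(bm.mask)] = color
    return out


# -- disk format ----------------------------------------------------------
# <id>.png (RGB image), <id>_cyto.png, <id>_nuc.png (8-bit {0,255} masks)

def sample_paths(directory: str | Path, sample_id: str) -> tuple[Path, Path, Path]:
    d = Path(directory)
    return (d / f"{sample_id}.png", d / f"{sample_id}_cyto.png",
            d / f"{sample_id}_nuc.png")


def save_sample(sample: ImageSample, directory: str | Path) -> None:
    img_p, cyto_p, nuc_p = sample_paths(directory, sample.id)
    img_p.parent.mkdir(parents=True, exist_ok=True)
    Image.fromarray(np.asarray(sample.image, dtype=np.uint8), "RGB").save(img_p)
    Image.fromarray((sample.cytoplasm_mask * 255).astype(np.uint8), "L").save(cyto_p)
    Image.fromarray((sample.nucleus_mask * 255).astype(np.uint8), "L").save(nuc_p)


def load_sample(directory: str | Path, sample_id: str) -> ImageSample:
    img_p, cyto_p, nuc_p = sample_paths(directory, sample_id)
    image = np.asarray(Image.open(img_p).convert("RGB"))
    cyto = binarize_stored_mask(np.asarray(Image.open(cyto_p).convert("L")))
    nuc = binarize_stored_mask(np.asarray(Image.open(nuc_p).convert("L")))
    return ImageSample(sample_id, image, cyto, nuc)
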