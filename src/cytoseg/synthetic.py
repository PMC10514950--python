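"""Seeded generator of Pap-stain-like cytology images with exact ground truth.

Cells are rotated filled ellipses on a light, slightly blue background;
each cell carries exactly one darker nucleus ellipse geometrically
contained in it, so the nucleus mask is a pixelwise subset of the
cytoplasm mask by construction. Cells may overlap (semantic masks take
the union) and may be cropped by the frame border, mirroring real tiles
where a neighbouring crop cut the cell. Per-cell hue, brightness jitter,
Gaussian blur and pixel noise make photometric augmentation meaningful.
Nucleus pixels are a small minority class (a few percent of the frame),
which is what motivates the positive-class weight in training.

Determinism: each sample's random stream is derived from ``(seed, index)``
only, so datasets are order-independent and reproducible bit-for-bit.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
from scipy import ndimage

from .core import ImageSample, save_sample

__all__ = ["SyntheticConfig", "generate_sample", "generate_dataset",
           "read_manifest", "MANIFEST_NAME"]

MANIFEST_NAME = "manifest.txt"


@dataclasses.dataclass(frozen=True)
class SyntheticConfig:
    image_size: tuple[int, int] = (512, 512)          # (H, W)
    n_cells_range: tuple[int, int] = (4, 10)
    cyto_axis_range: tuple[int, int] = (40, 110)      # ellipse semi-axes, px
    nucleus_fraction_range: tuple[float, float] = (0.15, 0.35)
    border_crop_prob: float = 0.2
    overlap_allowed: bool = True
    noise_sd: float = 6.0                             # 8-bit intensity units
    blur_sigma_range: tuple[float, float] = (0.4, 1.2)
    seed: int = 0

    def __post_init__(self):
        h, w = self.image_size
        if h < 32 or w < 32:
            raise ValueError("image_size must be at least 32x32")
        for name in ("n_cells_range", "cyto_axis_range",
                     "nucleus_fraction_range", "blur_sigma_range"):
            lo, hi = getattr(self, name)
            if lo > hi:
                raise ValueError(f"{name} must be ordered, got ({lo}, {hi})")
        lo, hi = self.nucleus_fraction_range
        if lo <= 0 or hi > 0.5:
            raise ValueError("nucleus_fraction_range must lie in (0, 0.5]")
        if not 0 <= self.border_crop_prob <= 1:
            raise ValueError("border_crop_prob must lie in [0,1]")
        if self.noise_sd < 0 or self.blur_sigma_range[0] < 0:
            raise ValueError("noise_sd and blur sigmas must be >= 0")

    @classmethod
    def tiny(cls, seed: int = 0) -> "SyntheticConfig":
        """64x64 preset with the same area statistics, for CPU-scale runs."""
        return cls(image_size=(64, 64), n_cells_range=(2, 5),
                   cyto_axis_range=(7, 16), seed=seed)

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self))

    @classmethod
    def from_json(cls, s: str) -> "SyntheticConfig":
        d = json.loads(s)
        for k, v in d.items():
            if isinstance(v, list):
                d[k] = tuple(v)
        return cls(**d)


# Pap-stain-ish palette: cytoplasm cyan or pink, nuclei dark purple.
_CYTO_HUES = [(95, 165, 175), (190, 140, 170), (120, 160, 185), (170, 120, 160)]
_NUC_COLOR = np.array([70, 40, 95], dtype=np.float64)
_BG_COLOR = np.array([246, 246, 252], dtype=np.float64)


@dataclasses.dataclass
class _Cell:
    cx: float
    cy: float
    a: float            # semi-axes of the cytoplasm ellipse
    b: float
    theta: float
    nf: float           # nucleus-to-cell axis ratio
    ncx: float          # nucleus centre
    ncy: float
    color: np.ndarray


def _ellipse_mask(shape, cx, cy, a, b, theta) -> np.ndarray:
    """Rasterise a rotated ellipse, evaluated only on its bounding box."""
    h, w = shape
    r = max(a, b)
    y0, y1 = max(0, int(cy - r) - 1), min(h, int(cy + r) + 2)
    x0, x1 = max(0, int(cx - r) - 1), min(w, int(cx + r) + 2)
    out = np.zeros(shape, dtype=bool)
    if y0 >= y1 or x0 >= x1:
        return out
    yy, xx = np.mgrid[y0:y1, x0:x1]
    dx, dy = xx - cx, yy - cy
    ct, st = np.cos(theta), np.sin(theta)
    u = dx * ct + dy * st
    v = -dx * st + dy * ct
    out[y0:y1, x0:x1] = (u / a) ** 2 + (v / b) ** 2 <= 1.0
    return out


def _sample_cells(config: SyntheticConfig, rng: np.random.Generator) -> list[_Cell]:
    h, w = config.image_size
    n = int(rng.integers(config.n_cells_range[0], config.n_cells_range[1] + 1))
    cells: list[_Cell] = []
    for _ in range(n):
        a = rng.uniform(*config.cyto_axis_range)
        b = rng.uniform(*config.cyto_axis_range)
        theta = rng.uniform(0, np.pi)
        r = max(a, b)
        for _try in range(40):
            if rng.random() < config.border_crop_prob:
                # centre within one semi-axis of a frame edge -> likely cropped
                edge = rng.integers(4)
                d = rng.uniform(0, r)
                if edge == 0:
                    cx, cy = rng.uniform(0, w), d
                elif edge == 1:
                    cx, cy = rng.uniform(0, w), h - d
                elif edge == 2:
                    cx, cy = d, rng.uniform(0, h)
                else:
                    cx, cy = w - d, rng.uniform(0, h)
            else:
                cx = rng.uniform(r * 0.7, w - r * 0.7) if w > 1.4 * r else w / 2
                cy = rng.uniform(r * 0.7, h - r * 0.7) if h > 1.4 * r else h / 2
            if config.overlap_allowed or not any(
                    (cx - c.cx) ** 2 + (cy - c.cy) ** 2 < (r + max(c.a, c.b)) ** 2
                    for c in cells):
                break
        nf = rng.uniform(*config.nucleus_fraction_range)
        # nucleus centre offset inside the (1-nf)-scaled ellipse keeps the
        # nucleus ellipse geometrically contained in the cell ellipse
        rho = np.sqrt(rng.random()) * (1.0 - nf)
        phi = rng.uniform(0, 2 * np.pi)
        ou = rho * np.cos(phi) * a
        ov = rho * np.sin(phi) * b
        ct, st = np.cos(theta), np.sin(theta)
        ncx = cx + ou * ct - ov * st
        ncy = cy + ou * st + ov * ct
        color = np.array(_CYTO_HUES[rng.integers(len(_CYTO_HUES))], dtype=np.float64)
        color = np.clip(color + rng.normal(0, 12, size=3), 0, 255)
        cells.append(_Cell(cx, cy, a, b, theta, nf, ncx, ncy, color))
    return cells


def generate_sample(config: SyntheticConfig, index: int) -> ImageSample:
    """Deterministic sample ``index`` under ``config.seed``."""
    rng = np.random.default_rng(
        np.random.SeedSequence(entropy=config.seed & 0x7FFFFFFF, spawn_key=(index,)))
    h, w = config.image_size
    cells = _sample_cells(config, rng)

    img = np.tile(_BG_COLOR, (h, w, 1))
    cyto = np.zeros((h, w), dtype=bool)
    nuc = np.zeros((h, w), dtype=bool)
    for cell in cells:  # back-to-front; later cells paint over earlier ones
        cmask = _ellipse_mask((h, w), cell.cx, cell.cy, cell.a, cell.b, cell.theta)
        nmask = _ellipse_mask((h, w), cell.ncx, cell.ncy,
                              cell.nf * cell.a, cell.nf * cell.b, cell.theta)
        alpha = rng.uniform(0.45, 0.7)
        img[cmask] = (1 - alpha) * img[cmask] + alpha * cell.color
        nalpha = rng.uniform(0.75, 0.9)
        img[nmask] = (1 - nalpha) * img[nmask] + nalpha * _NUC_COLOR
        cyto |= cmask
        nuc |= nmask
    nuc &= cyto  # containment holds geometrically; enforce exactly anyway

    sigma = rng.uniform(*config.blur_sigma_range)
    if sigma > 0:
        img = ndimage.gaussian_filter(img, sigma=(sigma, sigma, 0))
    if config.noise_sd > 0:
        img = img + rng.normal(0, config.noise_sd, size=img.shape)
    img = np.clip(np.round(img), 0, 255).astype(np.uint8)
    return ImageSample(f"synth_{index:05d}", img,
                       cyto.astype(np.uint8), nuc.astype(np.uint8))


def generate_dataset(config: SyntheticConfig, n_samples: int,
                     out_dir: str | Path) -> list[str]:
    """Write ``n_samples`` triplets plus a manifest; return the sample ids."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    ids = []
    for i in range(n_samples):
        sample = generate_sample(config, i)
        save_sample(sample, out)
        ids.append(sample.id)
    manifest = out / MANIFEST_NAME
    with manifest.open("w") as fh:
        fh.write(f"# config: {config.to_json()}\n")
        for sid in ids:
            fh.write(sid + "\n")
    return ids


def read_manifest(directory: str | Path) -> tuple[SyntheticConfig | None, list[str]]:
    config = None
    ids = []
    for line in (Path(directory) / MANIFEST_NAME).read_text().splitlines():
        if line.startswith("# config: "):
            config = SyntheticConfig.from_json(line[len("# config: "):])
        elif line.strip():
            ids.append(line.strip())
    return config, ids
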