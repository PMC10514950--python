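"""Cx22-format conversion, dataset loading, and the train/validation split.

The source distribution ships MATLAB v7.3 ``.mat`` containers (HDF5
underneath) holding 512x512 RGB images and paired cytoplasm/nucleus
masks. ``convert_cx22_container`` rewrites a container into the package's
lossless PNG triplet layout; dataset key names are auto-discovered by
array shape, with a manual override for containers whose internal layout
differs. A synthetic fixture writer is provided so the conversion path is
testable without the real download.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import h5py
import numpy as np

from .core import ImageSample, binarize_stored_mask, load_sample, sample_paths, save_sample, validate_sample

__all__ = [
    "DatasetSplit", "convert_cx22_container", "write_cx22_container",
    "load_dataset", "split_train_val", "Cx22FormatError",
]


class Cx22FormatError(RuntimeError):
    pass


@dataclasses.dataclass(frozen=True)
class DatasetSplit:
    train: list[str]
    val: list[str]
    ratio: float
    seed: int


def _normalize_image_array(arr: np.ndarray) -> np.ndarray:
    """Accept (N,H,W,3) or MATLAB-transposed (3,W,H,N); return (N,H,W,3)."""
    if arr.ndim != 4:
        raise Cx22FormatError(f"image array must be 4-D, got shape {arr.shape}")
    if arr.shape[-1] == 3:
        return arr
    if arr.shape[0] == 3:
        return arr.transpose(3, 2, 1, 0)
    raise Cx22FormatError(f"cannot locate colour axis in image array {arr.shape}")


def _normalize_mask_array(arr: np.ndarray, image_shape: tuple) -> np.ndarray:
    """Accept (N,H,W) or MATLAB-transposed (W,H,N); return (N,H,W)."""
    if arr.ndim != 3:
        raise Cx22FormatError(f"mask array must be 3-D, got shape {arr.shape}")
    n, h, w = image_shape[:3]
    if arr.shape == (n, h, w):
        return arr
    if arr.shape == (w, h, n):
        return arr.transpose(2, 1, 0)
    raise Cx22FormatError(
        f"mask array shape {arr.shape} incompatible with images {image_shape}")


def _discover_keys(f: h5py.File) -> dict[str, str]:
    """Map roles to dataset names by shape: the 4-D array with a 3-sized
    axis is the image stack; the two matching 3-D arrays are the masks."""
    image_key = None
    mask_keys = []

    def visit(name, obj):
        nonlocal image_key
        if not isinstance(obj, h5py.Dataset):
            return
        if obj.ndim == 4 and 3 in (obj.shape[0], obj.shape[-1]):
            image_key = name
        elif obj.ndim == 3:
            mask_keys.append(name)

    f.visititems(visit)
    if image_key is None:
        raise Cx22FormatError("no 4-D image dataset found in container")
    if len(mask_keys) < 2:
        raise Cx22FormatError(
            f"expected two 3-D mask datasets, found {mask_keys}")
    return {"image": image_key, "masks": sorted(mask_keys)[:2]}


def convert_cx22_container(container_path: str | Path, out_dir: str | Path,
                           keys: dict[str, str] | None = None) -> int:
    """Convert one HDF5 .mat container to PNG triplets; return count written.

    ``keys`` may name the datasets explicitly: ``{"image": ..., "cyto": ...,
    "nuc": ...}``. Without it, datasets are discovered by shape and the mask
    with the larger mean foreground area is taken as cytoplasm (nuclei are
    by far the smaller structure).
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    with h5py.File(container_path, "r") as f:
        if len(f.keys()) == 0:
            return 0
        groups = [k for k in f if isinstance(f[k], h5py.Group)]
        if groups and keys is None:
            return _convert_grouped(f, groups, out)
        if keys:
            for role in ("image", "cyto", "nuc"):
                if role not in keys:
                    raise Cx22FormatError(f"keys override missing {role!r}")
                if keys[role] not in f:
                    raise Cx22FormatError(
                        f"dataset {keys[role]!r} (role {role}) absent from container")
            images = np.asarray(f[keys["image"]])
            cyto_raw = np.asarray(f[keys["cyto"]])
            nuc_raw = np.asarray(f[keys["nuc"]])
        else:
            found = _discover_keys(f)
            images = np.asarray(f[found["image"]])
            m0 = np.asarray(f[found["masks"][0]])
            m1 = np.asarray(f[found["masks"][1]])
            if m0.mean() >= m1.mean():
                cyto_raw, nuc_raw = m0, m1
            else:
                cyto_raw, nuc_raw = m1, m0
        ids = None
        if "ids" in f:
            ids = [s.decode() if isinstance(s, bytes) else str(s)
                   for s in np.asarray(f["ids"]).ravel()]
    images = _normalize_image_array(images)
    cyto = _normalize_mask_array(cyto_raw, images.shape)
    nuc = _normalize_mask_array(nuc_raw, images.shape)
    n = images.shape[0]
    for i in range(n):
        sid = ids[i] if ids else f"cx22_{i:05d}"
        cm = cyto[i]
        nm = nuc[i]
        # stored masks may be {0,1} or {0,255}; route through the binarizer
        cm8 = cm.astype(np.uint8) * 255 if cm.max(initial=0) <= 1 else cm.astype(np.uint8)
        nm8 = nm.astype(np.uint8) * 255 if nm.max(initial=0) <= 1 else nm.astype(np.uint8)
        sample = ImageSample(sid, images[i].astype(np.uint8),
                             binarize_stored_mask(cm8), binarize_stored_mask(nm8))
        problems = validate_sample(sample)
        if problems:
            raise Cx22FormatError(f"sample {sid}: " + "; ".join(problems))
        save_sample(sample, out)
    return n


def _convert_grouped(f: h5py.File, groups: list[str], out: Path) -> int:
    """Container variant with one HDF5 group per sample."""
    n = 0
    for gname in sorted(groups):
        g = f[gname]
        image = None
        masks = []
        for k in g:
            arr = np.asarray(g[k])
            if arr.ndim == 3 and arr.shape[-1] == 3:
                image = arr
            elif arr.ndim == 2:
                masks.append((k, arr))
        if image is None:
            raise Cx22FormatError(f"sample {gname}: no HxWx3 image dataset")
        if len(masks) < 2:
            raise Cx22FormatError(
                f"sample {gname}: expected cytoplasm and nucleus masks, "
                f"found {[k for k, _ in masks] or 'none'}")
        masks.sort(key=lambda kv: kv[1].mean(), reverse=True)  # bigger = cytoplasm
        (_, cm), (_, nm) = masks[0], masks[1]
        cm8 = cm.astype(np.uint8) * 255 if cm.max(initial=0) <= 1 else cm.astype(np.uint8)
        nm8 = nm.astype(np.uint8) * 255 if nm.max(initial=0) <= 1 else nm.astype(np.uint8)
        sample = ImageSample(gname, image.astype(np.uint8),
                             binarize_stored_mask(cm8), binarize_stored_mask(nm8))
        problems = validate_sample(sample)
        if problems:
            raise Cx22FormatError(f"sample {gname}: " + "; ".join(problems))
        save_sample(sample, out)
        n += 1
    return n


def write_cx22_container(samples: list[ImageSample], path: str | Path) -> None:
    """Write a synthetic Cx22-style HDF5 container (fixture builder)."""
    with h5py.File(path, "w") as f:
        if samples:
            f.create_dataset("images", data=np.stack([s.image for s in samples]))
            f.create_dataset("cyto_masks",
                             data=np.stack([s.cytoplasm_mask for s in samples]))
            f.create_dataset("nuc_masks",
                             data=np.stack([s.nucleus_mask for s in samples]))
            f.create_dataset("ids", data=np.array([s.id.encode() for s in samples]))


def list_sample_ids(directory: str | Path) -> list[str]:
    d = Path(directory)
    ids = sorted(p.stem for p in d.glob("*.png")
                 if not (p.stem.endswith("_cyto") or p.stem.endswith("_nuc")))
    return ids


def load_dataset(directory: str | Path) -> list[ImageSample]:
    """Load every triplet in a core-format directory, lexicographic by id."""
    d = Path(directory)
    ids = list_sample_ids(d)
    orphans = [sid for sid in ids
               if not all(p.exists() for p in sample_paths(d, sid))]
    if orphans:
        raise Cx22FormatError(f"samples missing mask files: {orphans}")
    samples = []
    for sid in ids:
        sample = load_sample(d, sid)
        problems = validate_sample(sample)
        if problems:
            raise Cx22FormatError(f"sample {sid}: " + "; ".join(problems))
        samples.append(sample)
    return samples


def split_train_val(ids: list[str], ratio: float, seed: int) -> DatasetSplit:
    """Uniform random partition at the image level; deterministic per seed."""
    if not 0 < ratio < 1:
        raise ValueError(f"ratio must lie in (0,1), got {ratio}")
    rng = np.random.default_rng(seed)
    order = list(ids)
    perm = rng.permutation(len(order))
    n_train = int(np.floor(ratio * len(order) + 0.5))
    if len(order) >= 2:
        n_train = min(max(n_train, 1), len(order) - 1)
    train = sorted(order[i] for i in perm[:n_train])
    val = sorted(order[i] for i in perm[n_train:])
    return DatasetSplit(train=train, val=val, ratio=ratio, seed=seed)
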