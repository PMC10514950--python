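"""Training recipe for one base model.

One binary segmentation network is trained per task with real-time
augmentation (flips applied jointly to image and masks; brightness/
contrast, Gaussian blur and hue/saturation to the image only), a weighted
binary cross-entropy on smoothed targets (positive-class weight 1 for
cytoplasm, 8 for the minority nucleus class; symmetric label smoothing
eps=0.1), Adam wrapped in lookahead (k=5, alpha=0.5), and a staged
learning-rate decay (x0.1 at 30/60/90% of the epochs). A model is trained
``n_runs`` times and the run with the smallest validation loss is kept.
"""

from __future__ import annotations

import dataclasses
import math
from pathlib import Path

import numpy as np
from scipy import ndimage
from skimage import color as skcolor

from . import nn
from .core import BinaryMask, ImageSample, ProbabilityMap, TaskType
from .models import ModelSpec, SegmentationModel, build_model
from .nn import functional as F

__all__ = [
    "TrainConfig", "TrainingHistory", "AugmentConfig", "augment",
    "smooth_labels", "weighted_bce", "lr_at_epoch", "lookahead_update",
    "train_model", "train_repeated", "select_best", "TrainingDiverged",
    "recalibrate_batchnorm",
]

lookahead_update = nn.lookahead_update  # re-exported: part of the recipe


class TrainingDiverged(RuntimeError):
    pass


@dataclasses.dataclass(frozen=True)
class AugmentConfig:
    """Probabilities and moderate magnitudes of the four transform families."""

    flip_p: float = 0.5
    brightness_contrast_p: float = 0.5
    brightness_limit: float = 0.2       # multiplicative, 1 +- limit
    contrast_limit: float = 0.2
    blur_p: float = 0.5
    blur_sigma: tuple[float, float] = (0.3, 1.0)
    hue_saturation_p: float = 0.5
    hue_shift: float = 0.03             # fraction of the hue circle
    saturation_limit: float = 0.2


@dataclasses.dataclass(frozen=True)
class TrainConfig:
    task: TaskType = TaskType.CYTOPLASM
    batch_size: int = 32
    epochs: int = 20
    base_lr: float = 1e-3
    lr_factor: float = 0.1
    milestones: tuple[float, ...] = (0.3, 0.6, 0.9)
    pos_weight: float | None = None     # None -> 1 for cytoplasm, 8 for nucleus
    label_smooth_eps: float = 0.1
    lookahead_k: int = 5
    lookahead_alpha: float = 0.5
    n_runs: int = 3
    amp: bool = False                   # accepted, no-op on this CPU backend
    seed: int = 0
    augment: AugmentConfig = dataclasses.field(default_factory=AugmentConfig)

    def __post_init__(self):
        if self.pos_weight is not None and self.pos_weight < 1:
            raise ValueError("pos_weight must be >= 1")
        if not 0 <= self.label_smooth_eps < 1:
            raise ValueError("label_smooth_eps must lie in [0,1)")
        if any(not 0 < m < 1 for m in self.milestones):
            raise ValueError("milestones must lie in (0,1)")
        if list(self.milestones) != sorted(set(self.milestones)):
            raise ValueError("milestones must be strictly increasing")

    @property
    def effective_pos_weight(self) -> float:
        if self.pos_weight is not None:
            return self.pos_weight
        return 8.0 if self.task is TaskType.NUCLEUS else 1.0


@dataclasses.dataclass
class TrainingHistory:
    train_loss: list[float] = dataclasses.field(default_factory=list)
    val_loss: list[float] = dataclasses.field(default_factory=list)
    val_dice: list[float] = dataclasses.field(default_factory=list)

    @property
    def best_val_loss(self) -> float:
        return min(self.val_loss) if self.val_loss else math.inf

    def to_csv(self, path: str | Path) -> None:
        with Path(path).open("w") as fh:
            fh.write("epoch,train_loss,val_loss,val_dice\n")
            for i, (tl, vl, vd) in enumerate(
                    zip(self.train_loss, self.val_loss, self.val_dice)):
                fh.write(f"{i},{tl:.6f},{vl:.6f},{vd:.6f}\n")


# -- augmentation ----------------------------------------------------------

def augment(sample: ImageSample, rng: np.random.Generator,
            config: AugmentConfig | None = None) -> ImageSample:
    """Randomly transformed copy; geometry moves masks too, photometry not."""
    cfg = config or AugmentConfig()
    img = sample.image.astype(np.float32)
    cyto, nuc = sample.cytoplasm_mask, sample.nucleus_mask
    if rng.random() < cfg.flip_p:
        img, cyto, nuc = img[:, ::-1], cyto[:, ::-1], nuc[:, ::-1]
    if rng.random() < cfg.flip_p:
        img, cyto, nuc = img[::-1], cyto[::-1], nuc[::-1]
    if rng.random() < cfg.brightness_contrast_p:
        alpha = 1.0 + rng.uniform(-cfg.contrast_limit, cfg.contrast_limit)
        beta = rng.uniform(-cfg.brightness_limit, cfg.brightness_limit) * 255.0
        img = (img - 127.5) * alpha + 127.5 + beta
    if rng.random() < cfg.blur_p:
        sigma = rng.uniform(*cfg.blur_sigma)
        img = ndimage.gaussian_filter(img, sigma=(sigma, sigma, 0))
    if rng.random() < cfg.hue_saturation_p:
        hsv = skcolor.rgb2hsv(np.clip(img, 0, 255) / 255.0)
        hsv[..., 0] = (hsv[..., 0] + rng.uniform(-cfg.hue_shift, cfg.hue_shift)) % 1.0
        sat = 1.0 + rng.uniform(-cfg.saturation_limit, cfg.saturation_limit)
        hsv[..., 1] = np.clip(hsv[..., 1] * sat, 0, 1)
        img = skcolor.hsv2rgb(hsv) * 255.0
    img = np.clip(np.round(img), 0, 255).astype(np.uint8)
    return ImageSample(sample.id, np.ascontiguousarray(img),
                       np.ascontiguousarray(cyto), np.ascontiguousarray(nuc))


# -- loss pieces -----------------------------------------------------------

def smooth_labels(mask: np.ndarray | BinaryMask, eps: float) -> np.ndarray:
    """Symmetric label smoothing: 1 -> 1-eps/2, 0 -> eps/2."""
    if not 0 <= eps < 1:
        raise ValueError("eps must lie in [0,1)")
    m = mask.mask if isinstance(mask, BinaryMask) else np.asarray(mask)
    return m.astype(np.float64) * (1.0 - eps) + eps / 2.0


def weighted_bce(probs: np.ndarray | ProbabilityMap, targets: np.ndarray,
                 pos_weight: float = 1.0) -> float:
    """Mean of ``-[w*t*log p + (1-t)*log(1-p)]``; plain BCE at ``w=1``."""
    p = probs.probs if isinstance(probs, ProbabilityMap) else np.asarray(probs)
    t = np.asarray(targets, dtype=np.float64)
    if p.shape != t.shape:
        raise ValueError(f"shape mismatch {p.shape} vs {t.shape}")
    p = np.clip(p.astype(np.float64), 1e-7, 1 - 1e-7)
    return float(-(pos_weight * t * np.log(p) + (1 - t) * np.log1p(-p)).mean())


def lr_at_epoch(epoch: int, config: TrainConfig) -> float:
    """Staged decay: x ``lr_factor`` once past each milestone epoch."""
    if not 0 <= epoch < config.epochs:
        raise ValueError(f"epoch {epoch} out of range [0, {config.epochs})")
    n_past = sum(epoch >= math.floor(m * config.epochs) for m in config.milestones)
    return config.base_lr * config.lr_factor ** n_past


# -- training loop ---------------------------------------------------------

def _batch_targets(samples: list[ImageSample], task: TaskType,
                   eps: float) -> np.ndarray:
    masks = np.stack([s.mask_for(task) for s in samples])[:, None]
    return smooth_labels(masks, eps).astype(np.float32)


def recalibrate_batchnorm(model: SegmentationModel,
                          samples: list[ImageSample],
                          batch_size: int) -> None:
    """Re-estimate batch-norm running statistics over ``samples``.

    Short runs leave the exponentially averaged statistics lagging far
    behind the final weights, which miscalibrates eval-mode predictions
    near the threshold. One no-grad sweep with cumulative (1/t) averaging
    pins the running statistics to the trained weights.
    """
    bns = [m for m in model.modules() if isinstance(m, nn.BatchNorm2d)]
    if not bns:
        return
    for bn in bns:
        bn.running_mean[...] = 0.0
        bn.running_var[...] = 1.0
    saved = [bn.momentum for bn in bns]
    model.train()
    with nn.no_grad():
        for t, start in enumerate(range(0, len(samples), batch_size)):
            for bn in bns:
                bn.momentum = 1.0 / (t + 1)
            chunk = samples[start:start + batch_size]
            model(nn.Tensor(model.preprocess(
                np.stack([s.image for s in chunk]))))
    for bn, mom in zip(bns, saved):
        bn.momentum = mom
    model.eval()


def _evaluate(model: SegmentationModel, samples: list[ImageSample],
              config: TrainConfig, batch_size: int) -> tuple[float, float]:
    """Validation loss (same smoothed/weighted form as training) and Dice."""
    w = config.effective_pos_weight
    losses = []
    tp = fp = fn = 0
    model.eval()
    with nn.no_grad():
        for i in range(0, len(samples), batch_size):
            chunk = samples[i:i + batch_size]
            x = model.preprocess(np.stack([s.image for s in chunk]))
            t = _batch_targets(chunk, config.task, config.label_smooth_eps)
            logits = model(nn.Tensor(x))
            losses.append(F.bce_with_logits(logits, t, w).item() * len(chunk))
            pred = F.sigmoid(logits).data[:, 0] > 0.5
            truth = np.stack([s.mask_for(config.task) for s in chunk]).astype(bool)
            tp += int((pred & truth).sum())
            fp += int((pred & ~truth).sum())
            fn += int((~pred & truth).sum())
    dice = 1.0 if 2 * tp + fp + fn == 0 else 2 * tp / (2 * tp + fp + fn)
    return sum(losses) / len(samples), dice


def train_model(spec: ModelSpec, config: TrainConfig,
                train_samples: list[ImageSample],
                val_samples: list[ImageSample],
                encoder_weights: str | None = None,
                run_index: int = 0) -> tuple[SegmentationModel, TrainingHistory]:
    """Run the full recipe once; fully deterministic given config.seed."""
    if not train_samples or not val_samples:
        raise ValueError("train and validation sets must be non-empty")
    root = np.random.SeedSequence(
        entropy=config.seed & 0x7FFFFFFF, spawn_key=(run_index,))
    init_seed = int(root.generate_state(1)[0] & 0x7FFFFFFF)
    model = build_model(spec, seed=init_seed, encoder_weights=encoder_weights)
    rng = np.random.default_rng(root.spawn(1)[0])
    history = TrainingHistory()
    if config.epochs == 0:
        return model, history
    w = config.effective_pos_weight
    inner = nn.Adam(model.parameters(), lr=config.base_lr)
    opt = nn.Lookahead(inner, k=config.lookahead_k, alpha=config.lookahead_alpha)
    n = len(train_samples)
    for epoch in range(config.epochs):
        inner.lr = lr_at_epoch(epoch, config)
        model.train()
        order = rng.permutation(n)
        epoch_loss = 0.0
        for start in range(0, n, config.batch_size):
            chunk = [augment(train_samples[i], rng, config.augment)
                     for i in order[start:start + config.batch_size]]
            x = model.preprocess(np.stack([s.image for s in chunk]))
            t = _batch_targets(chunk, config.task, config.label_smooth_eps)
            logits = model(nn.Tensor(x))
            loss = F.bce_with_logits(logits, t, w)
            if not np.isfinite(loss.item()):
                raise TrainingDiverged(
                    f"non-finite loss at epoch {epoch}, step {start // config.batch_size}")
            opt.zero_grad()
            loss.backward()
            opt.step()
            epoch_loss += loss.item() * len(chunk)
        recalibrate_batchnorm(model, train_samples, config.batch_size)
        val_loss, val_dice = _evaluate(model, val_samples, config, config.batch_size)
        if not np.isfinite(val_loss):
            raise TrainingDiverged(f"non-finite validation loss at epoch {epoch}")
        history.train_loss.append(epoch_loss / n)
        history.val_loss.append(val_loss)
        history.val_dice.append(val_dice)
    return model, history


def select_best(runs: list[tuple[SegmentationModel, TrainingHistory]]
                ) -> tuple[SegmentationModel, TrainingHistory]:
    """Keep the run with the smallest minimum validation loss (ties: first)."""
    if not runs:
        raise ValueError("select_best needs at least one run")
    best = min(range(len(runs)), key=lambda i: (runs[i][1].best_val_loss, i))
    return runs[best]


def train_repeated(spec: ModelSpec, config: TrainConfig,
                   train_samples: list[ImageSample],
                   val_samples: list[ImageSample],
                   encoder_weights: str | None = None
                   ) -> tuple[SegmentationModel, TrainingHistory]:
    """Train ``config.n_runs`` times and return the best run."""
    runs = [train_model(spec, config, train_samples, val_samples,
                        encoder_weights, run_index=r)
            for r in range(config.n_runs)]
    return select_best(runs)
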