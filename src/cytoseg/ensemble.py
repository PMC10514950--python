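"""Probability-map ensembling.

The final per-pixel probability is the unweighted arithmetic mean of the
base models' probabilities (optionally an inverse-validation-loss
weighted mean), thresholded strictly above the cut-off:

    pred = (1/M) * sum_i p_i > threshold

An exact tie at the threshold is negative (strict inequality).
"""

from __future__ import annotations

import dataclasses

import numpy as np

from .core import BinaryMask, ProbabilityMap

__all__ = ["EnsembleConfig", "average_probabilities", "weights_from_val_losses",
           "threshold_map"]


@dataclasses.dataclass(frozen=True)
class EnsembleConfig:
    method: str = "unweighted"
    M: int = 4
    threshold: float = 0.5
    weights: tuple[float, ...] | None = None

    def __post_init__(self):
        if self.method not in ("unweighted", "weighted"):
            raise ValueError(f"unknown ensemble method {self.method!r}")
        if self.M < 1:
            raise ValueError("M must be >= 1")
        if not 0 < self.threshold < 1:
            raise ValueError("threshold must lie in (0,1)")
        if self.weights is not None:
            if len(self.weights) != self.M:
                raise ValueError(f"need {self.M} weights, got {len(self.weights)}")
            if any(w <= 0 for w in self.weights):
                raise ValueError("weights must be positive")
            total = float(sum(self.weights))
            object.__setattr__(self, "weights",
                               tuple(w / total for w in self.weights))


def average_probabilities(maps: list[ProbabilityMap],
                          config: EnsembleConfig) -> ProbabilityMap:
    """Pixelwise (weighted) mean of M probability maps of one task."""
    if len(maps) != config.M:
        raise ValueError(f"expected {config.M} maps, got {len(maps)}")
    task = maps[0].task
    shape = maps[0].probs.shape
    for m in maps[1:]:
        if m.task is not task:
            raise ValueError("all maps must share the same task")
        if m.probs.shape != shape:
            raise ValueError(f"shape mismatch {m.probs.shape} vs {shape}")
    stack = np.stack([m.probs for m in maps])
    if config.method == "weighted":
        if config.weights is None:
            raise ValueError("weighted averaging needs weights")
        w = np.asarray(config.weights, dtype=np.float64)
        avg = np.tensordot(w, stack, axes=(0, 0))
    else:
        avg = stack.mean(axis=0)
    return ProbabilityMap(task, np.clip(avg, 0.0, 1.0))


def weights_from_val_losses(losses: list[float]) -> tuple[float, ...]:
    """Normalised inverse-loss weights: lower validation loss, higher weight."""
    arr = np.asarray(losses, dtype=np.float64)
    if arr.size == 0 or (arr <= 0).any():
        raise ValueError("losses must be positive and non-empty")
    inv = 1.0 / arr
    return tuple(inv / inv.sum())


def threshold_map(prob_map: ProbabilityMap, threshold: float = 0.5) -> BinaryMask:
    """Positive iff probability strictly exceeds the threshold."""
    if not 0 < threshold < 1:
        raise ValueError("threshold must lie in (0,1)")
    return BinaryMask(prob_map.task, (prob_map.probs > threshold).astype(np.uint8))
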