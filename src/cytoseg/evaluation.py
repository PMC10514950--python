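"""Micro-averaged segmentation metrics with pixel-level bootstrap inference.

Metrics are computed from confusion counts pooled over every pixel of the
test set (micro-averaging): Dice = 2TP/(2TP+FP+FN), sensitivity =
TP/(TP+FN), specificity = TN/(TN+FP). Confidence intervals come from a
pixel-level bootstrap (B resamples of the N evaluated pixels with
replacement), computed via an equivalent multinomial draw over the four
confusion categories; percentile intervals at the requested level.
Predictor comparisons use a paired bootstrap in which both predictors'
category draws per image share the same underlying pixel resample.
"""

from __future__ import annotations

import dataclasses
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
import pandas as pd

from .core import BinaryMask, ConfusionCounts, MetricSet, ProbabilityMap

__all__ = [
    "EvalConfig", "CIResult", "MetricReport", "confusion_counts",
    "compute_metrics", "evaluate_micro", "evaluate_macro", "roc_auc",
    "bootstrap_ci", "paired_bootstrap_test", "summarize_report",
    "round_half_away",
]

_METRICS = ("dice", "sensitivity", "specificity")


@dataclasses.dataclass(frozen=True)
class EvalConfig:
    B: int = 500
    ci_level: float = 0.95
    alpha: float = 0.05
    max_roc_pixels: int = 2_000_000
    seed: int = 0

    def __post_init__(self):
        if self.B < 1:
            raise ValueError("B must be >= 1")
        if not 0 < self.ci_level < 1:
            raise ValueError("ci_level must lie in (0,1)")


@dataclasses.dataclass(frozen=True)
class CIResult:
    point: float
    lo: float
    hi: float


@dataclasses.dataclass
class MetricReport:
    per_model: list[tuple[str, MetricSet]]
    average: MetricSet
    ensemble: MetricSet | None = None
    ensemble_cis: dict[str, CIResult] | None = None
    p_values: dict[str, float] | None = None

    def to_dataframe(self) -> pd.DataFrame:
        rows = []
        for name, ms in self.per_model:
            rows.append({"model": name, **_round_set(ms)})
        rows.append({"model": "Average value", **_round_set(self.average)})
        if self.ensemble is not None:
            row = {"model": "Ensemble model", **_round_set(self.ensemble)}
            if self.ensemble_cis:
                for k, ci in self.ensemble_cis.items():
                    row[f"{k}_ci"] = (f"{round_half_away(ci.lo, 4):.4f}-"
                                      f"{round_half_away(ci.hi, 4):.4f}")
            rows.append(row)
        return pd.DataFrame(rows)


def round_half_away(x: float, decimals: int = 4) -> float:
    """Round half away from zero (table convention), e.g. 0.95205 -> 0.9521."""
    q = Decimal(1).scaleb(-decimals)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


def _round_set(ms: MetricSet, decimals: int = 4) -> dict[str, float]:
    return {k: round_half_away(v, decimals) for k, v in ms.as_dict().items()}


# -- counts and point metrics ---------------------------------------------

def confusion_counts(pred: BinaryMask, truth: BinaryMask) -> ConfusionCounts:
    """Pixel confusion totals between one prediction and its ground truth."""
    if pred.mask.shape != truth.mask.shape:
        raise ValueError(
            f"shape mismatch {pred.mask.shape} vs {truth.mask.shape}")
    if pred.task is not truth.task:
        raise ValueError("prediction and truth tasks differ")
    code = 2 * truth.mask.astype(np.int64) + pred.mask.astype(np.int64)
    counts = np.bincount(code.ravel(), minlength=4)  # tn, fp, fn, tp
    return ConfusionCounts(tp=int(counts[3]), fp=int(counts[1]),
                           tn=int(counts[0]), fn=int(counts[2]))


def _metrics_from_arrays(tp, fp, fn, tn):
    """Vectorised metric evaluation with the vacuous-truth conventions."""
    tp, fp, fn, tn = (np.asarray(a, dtype=np.float64) for a in (tp, fp, fn, tn))
    dice_den = 2 * tp + fp + fn
    sens_den = tp + fn
    spec_den = tn + fp
    dice = np.where(dice_den > 0, 2 * tp / np.maximum(dice_den, 1), 1.0)
    sens = np.where(sens_den > 0, tp / np.maximum(sens_den, 1), 1.0)
    spec = np.where(spec_den > 0, tn / np.maximum(spec_den, 1), 1.0)
    return dice, sens, spec


def compute_metrics(counts: ConfusionCounts) -> MetricSet:
    """Dice/sensitivity/specificity; vacuous denominators count as perfect."""
    if counts.total == 0:
        raise ValueError("cannot compute metrics from empty counts")
    d, s, p = _metrics_from_arrays(counts.tp, counts.fp, counts.fn, counts.tn)
    return MetricSet(dice=float(d), sensitivity=float(s), specificity=float(p))


def evaluate_micro(preds: list[BinaryMask], truths: list[BinaryMask]
                   ) -> tuple[ConfusionCounts, MetricSet]:
    """Pool confusion counts over all images, then compute metrics once."""
    if len(preds) != len(truths):
        raise ValueError("prediction and truth lists differ in length")
    total = ConfusionCounts()
    for p, t in zip(preds, truths):
        total = total + confusion_counts(p, t)
    return total, compute_metrics(total)


def evaluate_macro(preds: list[BinaryMask], truths: list[BinaryMask]) -> MetricSet:
    """Per-image metrics averaged with equal image weight (non-default)."""
    sets = [compute_metrics(confusion_counts(p, t)) for p, t in zip(preds, truths)]
    return MetricSet(*(float(np.mean([getattr(m, k) for m in sets]))
                       for k in _METRICS))


# -- ROC / AUC -------------------------------------------------------------

def roc_auc(prob_maps: list[ProbabilityMap], truths: list[BinaryMask],
            config: EvalConfig | None = None
            ) -> tuple[np.ndarray, np.ndarray, float]:
    """Pooled pixel ROC curve (fpr, tpr) and the rank-based AUC.

    The AUC is the probability that a random positive pixel receives a
    higher score than a random negative one, ties counted half — computed
    from rank sums, not by curve integration.
    """
    from scipy.stats import rankdata
    from sklearn import metrics as skm

    cfg = config or EvalConfig()
    scores = np.concatenate([m.probs.ravel() for m in prob_maps])
    labels = np.concatenate([t.mask.ravel() for t in truths]).astype(bool)
    if scores.shape != labels.shape:
        raise ValueError("probability maps and truths are misaligned")
    if labels.all() or not labels.any():
        raise ValueError("ROC undefined: ground truth has a single class")
    if scores.size > cfg.max_roc_pixels:
        rng = np.random.default_rng(cfg.seed)
        keep = rng.choice(scores.size, size=cfg.max_roc_pixels, replace=False)
        scores, labels = scores[keep], labels[keep]
        if labels.all() or not labels.any():
            raise ValueError("ROC subsample degenerate; raise max_roc_pixels")
    n_pos = int(labels.sum())
    n_neg = labels.size - n_pos
    ranks = rankdata(scores)  # average ranks: ties count half in the AUC
    auc = (ranks[labels].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg)
    fpr, tpr, _ = skm.roc_curve(labels.astype(int), scores)
    return fpr, tpr, float(auc)


# -- bootstrap -------------------------------------------------------------

def _metric_from_count_rows(rows: np.ndarray, metric: str) -> np.ndarray:
    """rows: (..., 4) as (tp, fp, fn, tn)."""
    if metric not in _METRICS:
        raise ValueError(f"unknown metric {metric!r}; expected one of {_METRICS}")
    d, s, p = _metrics_from_arrays(rows[..., 0], rows[..., 1],
                                   rows[..., 2], rows[..., 3])
    return {"dice": d, "sensitivity": s, "specificity": p}[metric]


def bootstrap_ci(counts: ConfusionCounts, metric: str,
                 config: EvalConfig | None = None,
                 replicate_counts: np.ndarray | None = None) -> CIResult:
    """Percentile bootstrap CI for one micro metric.

    Each replicate resamples the N evaluated pixels with replacement; since
    a pixel only contributes through its confusion category, this is drawn
    as one multinomial over (tp, fp, fn, tn) — distributionally identical
    to per-pixel index resampling. ``replicate_counts`` (B x 4) overrides
    the draw, e.g. to feed externally resampled categories.
    """
    cfg = config or EvalConfig()
    n = counts.total
    if n == 0:
        raise ValueError("no pixels to resample")
    point = float(_metric_from_count_rows(counts.as_array()[None], metric)[0])
    if replicate_counts is None:
        rng = np.random.default_rng(cfg.seed)
        replicate_counts = rng.multinomial(n, counts.as_array() / n, size=cfg.B)
    reps = _metric_from_count_rows(np.asarray(replicate_counts), metric)
    lo_q = (1 - cfg.ci_level) / 2
    lo, hi = np.quantile(reps, [lo_q, 1 - lo_q])
    return CIResult(point=point, lo=float(lo), hi=float(hi))


def _shared_intervals(pa: np.ndarray, pb: np.ndarray):
    """Partition [0,1) by both category CDFs for a shared-uniform coupling.

    Resampling a pixel for predictors A and B with one shared uniform value
    keys both categories off the same draw; the induced joint distribution
    over (catA, catB) only depends on the merged CDF intervals, so one
    multinomial over those intervals reproduces it exactly.
    """
    ca = np.cumsum(pa)[:-1]
    cb = np.cumsum(pb)[:-1]
    edges = np.unique(np.concatenate([[0.0], ca, cb, [1.0]]))
    widths = np.diff(edges)
    mids = (edges[:-1] + edges[1:]) / 2
    cat_a = np.searchsorted(ca, mids, side="right")
    cat_b = np.searchsorted(cb, mids, side="right")
    return widths, cat_a, cat_b


def paired_bootstrap_test(counts_a: list[ConfusionCounts],
                          counts_b: list[ConfusionCounts],
                          metric: str,
                          config: EvalConfig | None = None) -> float:
    """Two-sided paired pixel-bootstrap p-value for metric(A) - metric(B).

    Per replicate and image the two predictors' resampled category counts
    are coupled through a shared pixel resample (identical marginals give
    identical draws), the micro metric difference is recorded, and the
    p-value is ``2 * min(P(diff <= 0), P(diff >= 0))`` floored at 1/B.
    """
    cfg = config or EvalConfig()
    if len(counts_a) != len(counts_b):
        raise ValueError("per-image count lists are misaligned")
    if not counts_a:
        raise ValueError("need at least one image")
    rng = np.random.default_rng(cfg.seed)
    tot_a = np.zeros((cfg.B, 4))
    tot_b = np.zeros((cfg.B, 4))
    for ca, cb in zip(counts_a, counts_b):
        if ca.total != cb.total:
            raise ValueError("paired counts cover different pixel totals")
        n = ca.total
        if n == 0:
            continue
        pa = ca.as_array() / n
        pb = cb.as_array() / n
        widths, cat_a, cat_b = _shared_intervals(pa, pb)
        draws = rng.multinomial(n, widths, size=cfg.B)  # (B, n_intervals)
        for cat in range(4):
            sel_a = cat_a == cat
            sel_b = cat_b == cat
            if sel_a.any():
                tot_a[:, cat] += draws[:, sel_a].sum(axis=1)
            if sel_b.any():
                tot_b[:, cat] += draws[:, sel_b].sum(axis=1)
    diffs = (_metric_from_count_rows(tot_a, metric)
             - _metric_from_count_rows(tot_b, metric))
    p = 2 * min(float((diffs <= 0).mean()), float((diffs >= 0).mean()))
    return float(min(1.0, max(p, 1.0 / cfg.B)))


# -- report ----------------------------------------------------------------

def summarize_report(per_model: list[tuple[str, MetricSet]],
                     ensemble: MetricSet | None = None,
                     cis: dict[str, CIResult] | None = None,
                     pvals: dict[str, float] | None = None) -> MetricReport:
    """Assemble the comparison table, including the arithmetic-mean row."""
    if not per_model:
        raise ValueError("need at least one model")
    avg = MetricSet(*(float(np.mean([getattr(ms, k) for _, ms in per_model]))
                      for k in _METRICS))
    return MetricReport(per_model=list(per_model), average=avg,
                        ensemble=ensemble, ensemble_cis=cis, p_values=pvals)
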