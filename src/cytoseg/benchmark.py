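"""CPU-scale reference study on synthetic data.

Runs the whole method at desk scale: the four selected base models
(U-Net and U-Net++ with resnet34/densenet121 encoders) in their
quarter-width variants, trained for 3 epochs on 200 synthetic 64x64
samples per task, then ensembled by unweighted averaging and scored on a
held-out synthetic test set. The short-run training preset uses a
constant learning rate of 5e-3 with batch size 8 and a single run per
model; everything else follows the standard recipe (augmentation,
weighted smoothed cross-entropy, Adam + lookahead).

This is the configuration exercised by the acceptance checks; it
demonstrates the ensemble-vs-base-mean behaviour of the method on data
whose ground truth is exact, not the accuracy of the full-scale study
(which needs the real dataset and GPU-scale training).
"""

from __future__ import annotations

import dataclasses

import numpy as np

from .core import BinaryMask, ProbabilityMap, TaskType
from .cx22 import split_train_val
from .ensemble import EnsembleConfig, average_probabilities, threshold_map
from .evaluation import (EvalConfig, bootstrap_ci, confusion_counts,
                         evaluate_micro, paired_bootstrap_test, roc_auc,
                         summarize_report)
from .models import ModelSpec
from .synthetic import SyntheticConfig, generate_sample
from .training import TrainConfig, train_repeated

__all__ = ["TINY_BASE_SPECS", "tiny_train_config", "run_tiny_study"]

TINY_BASE_SPECS = (
    ModelSpec("unet", "resnet34", tiny=True),
    ModelSpec("unet", "densenet121", tiny=True),
    ModelSpec("unetplusplus", "resnet34", tiny=True),
    ModelSpec("unetplusplus", "densenet121", tiny=True),
)

N_TRAIN = 200
N_TEST = 40


def tiny_train_config(task: TaskType, seed: int) -> TrainConfig:
    """Short-run preset: constant lr 5e-3, batch 8, 3 epochs, single run."""
    return TrainConfig(task=task, batch_size=8, epochs=3, base_lr=5e-3,
                       milestones=(), n_runs=1, seed=seed)


def run_tiny_study(seed: int = 0, tasks=(TaskType.CYTOPLASM, TaskType.NUCLEUS),
                   eval_config: EvalConfig | None = None) -> dict:
    """Train, ensemble and evaluate the desk-scale study; return all metrics.

    The result maps each task name to per-model metric sets, their
    arithmetic mean, the ensemble metrics with bootstrap CIs, paired
    p-values of ensemble vs each base model, and the pooled-pixel AUC.
    """
    seed = int(seed) & 0x7FFFFFFF
    data_cfg = SyntheticConfig.tiny(seed=seed)
    test_cfg = dataclasses.replace(data_cfg, seed=(seed + 1) & 0x7FFFFFFF)
    samples = {f"synth_{i:05d}": generate_sample(data_cfg, i)
               for i in range(N_TRAIN)}
    split = split_train_val(sorted(samples), ratio=0.9, seed=seed)
    train = [samples[i] for i in split.train]
    val = [samples[i] for i in split.val]
    test = [generate_sample(test_cfg, i) for i in range(N_TEST)]
    test_images = np.stack([s.image for s in test])
    ecfg = EnsembleConfig(M=len(TINY_BASE_SPECS))
    evcfg = eval_config or EvalConfig(seed=seed)

    results: dict = {}
    for task in tasks:
        tcfg = tiny_train_config(task, seed)
        truths = [BinaryMask(task, s.mask_for(task)) for s in test]
        prob_maps: dict[str, list[ProbabilityMap]] = {}
        per_model = []
        counts_by_model = {}
        for spec in TINY_BASE_SPECS:
            model, history = train_repeated(spec, tcfg, train, val)
            probs = model.predict_proba(test_images, batch_size=tcfg.batch_size)
            prob_maps[spec.name] = [ProbabilityMap(task, p) for p in probs]
            preds = [threshold_map(pm, ecfg.threshold)
                     for pm in prob_maps[spec.name]]
            _, ms = evaluate_micro(preds, truths)
            per_model.append((spec.name, ms))
            counts_by_model[spec.name] = [confusion_counts(p, t)
                                          for p, t in zip(preds, truths)]
            del model
        names = [s.name for s in TINY_BASE_SPECS]
        ens_maps = [average_probabilities([prob_maps[n][i] for n in names], ecfg)
                    for i in range(len(test))]
        ens_preds = [threshold_map(pm, ecfg.threshold) for pm in ens_maps]
        ecounts, emetrics = evaluate_micro(ens_preds, truths)
        ens_by_img = [confusion_counts(p, t) for p, t in zip(ens_preds, truths)]
        pvals = {n: paired_bootstrap_test(ens_by_img, counts_by_model[n],
                                          "dice", evcfg) for n in names}
        cis = {m: bootstrap_ci(ecounts, m, evcfg)
               for m in ("dice", "sensitivity", "specificity")}
        _, _, auc = roc_auc(ens_maps, truths, evcfg)
        report = summarize_report(per_model, emetrics, cis, pvals)
        results[task.value] = {
            "per_model": {n: ms.as_dict() for n, ms in per_model},
            "average": report.average.as_dict(),
            "ensemble": emetrics.as_dict(),
            "ensemble_ci": {k: dataclasses.asdict(v) for k, v in cis.items()},
            "p_values": pvals,
            "auc": auc,
            "n_test_pixels": ecounts.total,
        }
    return results
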