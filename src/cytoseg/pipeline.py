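"""End-to-end pipeline: data -> base-model training -> ensemble -> report.

For each task (cytoplasm, nucleus) every configured base model is trained
``n_runs`` times, the best run kept, probability maps predicted on the
held-out test set, averaged into the ensemble, thresholded, and scored
with micro metrics, bootstrap CIs for the ensemble, and paired bootstrap
comparisons against each base model. Every artifact the run writes is
listed in a JSON manifest together with a hash of the configuration and
the seeds used, so a rerun with identical config reproduces the outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from pathlib import Path

import numpy as np
from PIL import Image

from .core import BinaryMask, ImageSample, ProbabilityMap, TaskType, render_overlay
from .cx22 import load_dataset, split_train_val
from .ensemble import EnsembleConfig, average_probabilities, threshold_map, weights_from_val_losses
from .evaluation import (EvalConfig, bootstrap_ci, compute_metrics,
                         confusion_counts, evaluate_micro, paired_bootstrap_test,
                         roc_auc, summarize_report)
from .models import ModelSpec, build_model, load_checkpoint, save_checkpoint
from .synthetic import SyntheticConfig, generate_dataset
from .training import TrainConfig, train_repeated

logger = logging.getLogger("cytoseg.pipeline")

__all__ = ["PipelineConfig", "run_pipeline", "load_pipeline_config",
           "DEFAULT_BASE_SPECS", "save_probability_map", "load_probability_map"]

DEFAULT_BASE_SPECS = (
    ModelSpec("unet", "resnet34"),
    ModelSpec("unet", "densenet121"),
    ModelSpec("unetplusplus", "resnet34"),
    ModelSpec("unetplusplus", "densenet121"),
)

CONFIG_SCHEMA_VERSION = 1


@dataclasses.dataclass
class PipelineConfig:
    out_dir: str = "runs/pipeline"
    seed: int = 0
    # data: either a synthetic recipe or pre-converted directories
    synthetic: SyntheticConfig | None = None
    n_train: int = 200
    n_test: int = 50
    data_dir: str | None = None
    test_dir: str | None = None
    val_ratio: float = 0.1
    model_specs: tuple[ModelSpec, ...] = DEFAULT_BASE_SPECS
    train: TrainConfig = dataclasses.field(default_factory=TrainConfig)
    ensemble: EnsembleConfig | None = None
    eval: EvalConfig = dataclasses.field(default_factory=EvalConfig)
    tasks: tuple[TaskType, ...] = (TaskType.CYTOPLASM, TaskType.NUCLEUS)
    n_overlays: int = 3
    encoder_weights: str | None = None

    def config_hash(self) -> str:
        blob = json.dumps(_to_jsonable(self), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def _to_jsonable(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {k: _to_jsonable(v) for k, v in dataclasses.asdict(obj).items()}
    if isinstance(obj, TaskType):
        return obj.value
    if isinstance(obj, (tuple, list)):
        return [_to_jsonable(v) for v in obj]
    if isinstance(obj, dict):
        return {k: _to_jsonable(v) for k, v in obj.items()}
    return obj


def load_pipeline_config(path: str | Path) -> PipelineConfig:
    """Read a versioned YAML pipeline configuration."""
    import yaml

    raw = yaml.safe_load(Path(path).read_text()) or {}
    version = raw.pop("schema_version", CONFIG_SCHEMA_VERSION)
    if version != CONFIG_SCHEMA_VERSION:
        raise ValueError(f"unsupported config schema version {version}")
    kwargs: dict = {}
    if "synthetic" in raw:
        syn = raw.pop("synthetic")
        for k, v in list(syn.items()):
            if isinstance(v, list):
                syn[k] = tuple(v)
        kwargs["synthetic"] = SyntheticConfig(**syn)
    if "model_specs" in raw:
        kwargs["model_specs"] = tuple(ModelSpec(**d) for d in raw.pop("model_specs"))
    if "train" in raw:
        tr = raw.pop("train")
        if "task" in tr:
            tr["task"] = TaskType(tr["task"])
        if "milestones" in tr:
            tr["milestones"] = tuple(tr["milestones"])
        kwargs["train"] = TrainConfig(**tr)
    if "ensemble" in raw:
        en = raw.pop("ensemble")
        if "weights" in en and en["weights"] is not None:
            en["weights"] = tuple(en["weights"])
        kwargs["ensemble"] = EnsembleConfig(**en)
    if "eval" in raw:
        kwargs["eval"] = EvalConfig(**raw.pop("eval"))
    if "tasks" in raw:
        kwargs["tasks"] = tuple(TaskType(t) for t in raw.pop("tasks"))
    kwargs.update(raw)
    return PipelineConfig(**kwargs)


def save_probability_map(pm: ProbabilityMap, path: str | Path) -> None:
    """16-bit single-channel PNG, value = round(p * 65535)."""
    arr = np.round(pm.probs * 65535).astype(np.uint16)
    Image.fromarray(arr).save(path)


def load_probability_map(path: str | Path, task: TaskType) -> ProbabilityMap:
    arr = np.asarray(Image.open(path), dtype=np.float64) / 65535.0
    return ProbabilityMap(task, arr)


def _task_train_config(base: TrainConfig, task: TaskType, seed: int) -> TrainConfig:
    return dataclasses.replace(base, task=task, seed=seed)


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the full flow; returns the run manifest (also written to disk)."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    artifacts: list[str] = []

    def register(path: Path) -> Path:
        artifacts.append(str(path.relative_to(out)))
        return path

    stage = "data"
    try:
        if config.synthetic is not None:
            train_dir = out / "data" / "train"
            test_dir = out / "data" / "test"
            syn = dataclasses.replace(config.synthetic, seed=config.seed)
            ids = generate_dataset(syn, config.n_train, train_dir)
            # disjoint index range keeps test samples independent of train
            test_syn = dataclasses.replace(syn, seed=config.seed + 1)
            generate_dataset(test_syn, config.n_test, test_dir)
            for d in (train_dir, test_dir):
                for p in sorted(d.iterdir()):
                    register(p)
        else:
            if config.data_dir is None or config.test_dir is None:
                raise ValueError("need synthetic config or data_dir + test_dir")
            train_dir, test_dir = Path(config.data_dir), Path(config.test_dir)
            ids = [s.id for s in load_dataset(train_dir)]
        train_samples = {s.id: s for s in load_dataset(train_dir)}
        test_samples = load_dataset(test_dir)
        split = split_train_val(ids, 1.0 - config.val_ratio, config.seed)
        tr = [train_samples[i] for i in split.train]
        va = [train_samples[i] for i in split.val]
        logger.info("data ready: %d train / %d val / %d test",
                    len(tr), len(va), len(test_samples))

        manifest: dict = {
            "config_hash": config.config_hash(),
            "seed": config.seed,
            "config": _to_jsonable(config),
            "tasks": {},
        }
        test_images = np.stack([s.image for s in test_samples])

        for task in config.tasks:
            stage = f"train:{task.value}"
            tcfg = _task_train_config(config.train, task, config.seed)
            prob_maps_by_model: dict[str, list[ProbabilityMap]] = {}
            val_losses: dict[str, float] = {}
            task_dir = out / task.value
            task_dir.mkdir(parents=True, exist_ok=True)
            for spec in config.model_specs:
                logger.info("training %s for %s", spec.name, task.value)
                model, history = train_repeated(
                    spec, tcfg, tr, va, encoder_weights=config.encoder_weights)
                ckpt = register(task_dir / f"{spec.name}.npz")
                save_checkpoint(model, ckpt, {
                    "task": task.value, "seed": config.seed,
                    "best_val_loss": history.best_val_loss})
                history.to_csv(register(task_dir / f"{spec.name}_history.csv"))
                val_losses[spec.name] = history.best_val_loss
                probs = model.predict_proba(test_images,
                                            batch_size=tcfg.batch_size)
                prob_maps_by_model[spec.name] = [
                    ProbabilityMap(task, p) for p in probs]
                del model

            stage = f"ensemble:{task.value}"
            ecfg = config.ensemble or EnsembleConfig(M=len(config.model_specs))
            if ecfg.M != len(config.model_specs):
                ecfg = dataclasses.replace(ecfg, M=len(config.model_specs))
            if ecfg.method == "weighted" and ecfg.weights is None:
                ecfg = dataclasses.replace(ecfg, weights=weights_from_val_losses(
                    [val_losses[s.name] for s in config.model_specs]))
            names = [s.name for s in config.model_specs]
            ens_maps = [
                average_probabilities([prob_maps_by_model[n][i] for n in names], ecfg)
                for i in range(len(test_samples))]
            pred_dir = task_dir / "predictions"
            pred_dir.mkdir(exist_ok=True)
            for s, pm in zip(test_samples, ens_maps):
                save_probability_map(pm, register(pred_dir / f"{s.id}_prob.png"))

            stage = f"evaluate:{task.value}"
            truths = [BinaryMask(task, s.mask_for(task)) for s in test_samples]
            ens_preds = [threshold_map(pm, ecfg.threshold) for pm in ens_maps]
            ecounts, emetrics = evaluate_micro(ens_preds, truths)
            ens_counts_by_img = [confusion_counts(p, t)
                                 for p, t in zip(ens_preds, truths)]
            per_model = []
            pvals = {}
            for name in names:
                preds = [threshold_map(pm, ecfg.threshold)
                         for pm in prob_maps_by_model[name]]
                _, ms = evaluate_micro(preds, truths)
                per_model.append((name, ms))
                counts_by_img = [confusion_counts(p, t)
                                 for p, t in zip(preds, truths)]
                pvals[name] = paired_bootstrap_test(
                    ens_counts_by_img, counts_by_img, "dice", config.eval)
            cis = {m: bootstrap_ci(ecounts, m, config.eval)
                   for m in ("dice", "sensitivity", "specificity")}
            report = summarize_report(per_model, emetrics, cis, pvals)
            fpr, tpr, auc = roc_auc(ens_maps, truths, config.eval)
            import pandas as pd
            pd.DataFrame({"fpr": fpr, "tpr": tpr}).to_csv(
                register(task_dir / "roc.csv"), index=False)

            report_path = register(task_dir / "report.json")
            report_path.write_text(json.dumps({
                "task": task.value,
                "per_model": {n: ms.as_dict() for n, ms in report.per_model},
                "average": report.average.as_dict(),
                "ensemble": emetrics.as_dict(),
                "ensemble_ci": {k: dataclasses.asdict(v) for k, v in cis.items()},
                "p_values_vs_ensemble": pvals,
                "auc": auc,
                "val_losses": val_losses,
            }, indent=2))
            report.to_dataframe().to_csv(
                register(task_dir / "report.csv"), index=False)
            manifest["tasks"][task.value] = {
                "report": str(report_path.relative_to(out)),
                "ensemble_dice": emetrics.dice,
                "auc": auc,
            }

        stage = "overlays"
        overlay_dir = out / "overlays"
        overlay_dir.mkdir(exist_ok=True)
        cyto_preds = _reload_predictions(out, TaskType.CYTOPLASM, test_samples, config)
        nuc_preds = _reload_predictions(out, TaskType.NUCLEUS, test_samples, config)
        for s, cp, np_ in list(zip(test_samples, cyto_preds, nuc_preds))[:config.n_overlays]:
            ov = render_overlay(s, cp, np_)
            Image.fromarray(ov).save(register(overlay_dir / f"{s.id}_overlay.png"))

        stage = "manifest"
        manifest["artifacts"] = sorted(artifacts + ["manifest.json"])
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
        return manifest
    except Exception as exc:
        raise RuntimeError(f"pipeline failed during stage {stage!r}: {exc}") from exc


def _reload_predictions(out: Path, task: TaskType, test_samples: list[ImageSample],
                        config: PipelineConfig) -> list[BinaryMask]:
    ecfg = config.ensemble or EnsembleConfig(M=len(config.model_specs))
    pred_dir = out / task.value / "predictions"
    preds = []
    for s in test_samples:
        p = pred_dir / f"{s.id}_prob.png"
        if p.exists():
            preds.append(threshold_map(load_probability_map(p, task), ecfg.threshold))
        else:
            preds.append(BinaryMask(task, np.zeros(s.shape, dtype=np.uint8)))
    return preds
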