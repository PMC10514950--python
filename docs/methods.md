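# Methods

## Problem and model

Cervical cytology screening rests on per-cell morphology — nuclear size
and shape and the nucleus-to-cytoplasm ratio — so automated screening
needs both whole-cell (cytoplasm) and nucleus masks. `cytoseg` treats the
two as **independent binary semantic segmentation tasks**: for each task a
network maps a 512×512 RGB image to per-pixel foreground probabilities,
and no attempt is made to separate touching cells into instances
(instance identification is explicitly out of scope).

Each task is solved by a **deep ensemble**. Four encoder–decoder networks
— U-Net and U-Net++, each with a resnet34 or densenet121 encoder — are
trained independently; at inference the per-pixel prediction is

    pred = (1/M) · Σᵢ pᵢ  >  0.5,        M = 4

i.e. the unweighted arithmetic mean of the members' probabilities,
thresholded **strictly** above 0.5 (an exact tie is negative; constant-0.5
rasters are reachable from symmetric initialisations, so the tie rule is
load-bearing). Averaging operates on post-sigmoid probabilities, not on
logits. An inverse-validation-loss weighted mean
(wᵢ = (1/lossᵢ)/Σⱼ(1/lossⱼ)) is available but not the default; stacking
is deliberately not implemented.

The DeepLabV3 and DeepLabV3+ heads (with resnet34/resnet50 encoders, at
output stride 8 and 16 with ASPP rates 12/24/36) are included in the
model zoo as the remaining candidate architectures, but are not part of
the default ensemble. Transformer candidates (a ViT-hybrid U-Net with
vit_blocks = 12, vit_heads = 12, vit_dim_linear_mhsa_block = 3072,
patch_size = 8, vit_transformer_dim = 768; and a hierarchical-attention
segmenter with dims = (32, 64, 160, 256), heads = (1, 2, 5, 8),
ff_expansion = (8, 8, 4, 4), reduction_ratio = (8, 4, 2, 1),
num_layers = 2, decoder_dim = 256) are recorded here for completeness
only: at this data scale they collapse to all-positive/all-negative
predictors and are not built by this package.

## Architecture fidelity

The networks are implemented on the package's own numpy autodiff backend
(`cytoseg.nn`: strided/dilated/grouped convolution, batch norm, pooling,
nearest/bilinear upsampling, Adam + lookahead; every op is verified
against central finite differences). Fidelity to the reference
architectures is pinned by **exact trainable-parameter counts** at full
width:

| model | parameters |
|---|---|
| Unet_resnet34 | 24,436,369 |
| Unet_densenet121 | 13,607,633 |
| UnetPlusPlus_resnet34 | 26,078,609 |
| UnetPlusPlus_densenet121 | 30,072,273 |
| DeepLabV3_resnet34 | 26,007,105 |
| DeepLabV3_resnet50 | 39,633,729 |
| DeepLabV3Plus_resnet34 | 22,437,457 |
| DeepLabV3Plus_resnet50 | 26,677,585 |

U-Net/U-Net++ use five decoder stages of two 3×3 conv+BN+ReLU layers with
channels (256, 128, 64, 32, 16) ("10 conv layers") and a 3×3
single-channel head; the U-Net++ decoder is the nested dense grid with
per-column skip concatenation. All eight counts are asserted in the test
suite.

`tiny=True` builds quarter-width variants of the same topologies for
CPU-scale runs; tiny models are excluded from any count check.

**Initialisation.** `init='scratch'` uses He (fan-out) initialisation
everywhere. `init='imagenet'` loads encoder weights from a user-supplied
`.npz` (one entry per encoder parameter/buffer) and fine-tunes all
layers; pretrained natural-image encoders are not bundled with the
package, so without a weights file this init raises. The pipeline default
is therefore `scratch`. Inputs are scaled to [0,1]; imagenet-init models
additionally normalise by the standard ImageNet channel statistics, the
convention of the pretrained encoders.

## Training recipe

Per task and base model:

- **Loss**: weighted binary cross-entropy on smoothed targets,
  `mean(−[w·t·log p + (1−t)·log(1−p)])`, computed in logit space for
  stability (callers see probabilities). Positive-class weight w = 1 for
  cytoplasm and **w = 8 for the nucleus**, whose pixels are a small
  minority (≈3% of the frame under the synthetic defaults; the class
  imbalance is what motivates the weight). Symmetric label smoothing
  ε = 0.1 maps targets to {0.05, 0.95}; the weight multiplies the
  target-side term, so w = 1 reduces exactly to plain BCE.
- **Optimizer**: Adam (default moments) wrapped in lookahead with k = 5,
  α = 0.5 — every 5 inner steps the slow weights move halfway to the fast
  weights and the fast weights reset onto them.
- **Schedule**: base lr 1e-3, ×0.1 at 30/60/90% of the epochs
  (milestones at `floor(fraction·epochs)`, applied from the start of that
  0-based epoch). Batch size 32, 20 epochs at full scale.
- **Augmentation** (real-time, per sample): horizontal and vertical
  flips (applied identically to image and both masks), brightness/
  contrast, Gaussian blur, and hue/saturation — each family with
  probability 0.5 and moderate, config-exposed magnitudes. Photometric
  transforms never touch the masks.
- **Repeat-3 selection**: each model is trained `n_runs = 3` times and
  the run with the smallest epoch-minimum validation loss is kept (ties:
  earliest run). Validation loss uses the same smoothed, weighted form as
  training.
- `amp` is accepted for interface compatibility and is a no-op on this
  CPU backend; it is excluded from determinism contracts.

**Batch-norm recalibration.** At the end of every epoch the batch-norm
running statistics are re-estimated by one no-grad sweep over the
training set with cumulative (1/t) averaging. In short runs the
exponential running averages (momentum 0.1) lag far behind the trained
weights, which miscalibrates eval-mode probabilities around the 0.5
cut-off even when ranking (AUC) is already good; pinning the statistics
to the final weights removes that artefact. This changes no trainable
parameter and is part of this package's training loop, not of the loss
or optimizer.

Determinism: everything is keyed off one integer seed (model init,
shuffling, augmentation, bootstrap); identical configuration and seed
reproduce losses bit-for-bit on a fixed BLAS.

## Data

**Real data layout.** Samples are `<id>.png` (8-bit RGB) plus
`<id>_cyto.png` / `<id>_nuc.png` (8-bit single-channel, {0, 255}) in one
directory. Masks are persisted as lossless PNG; the reader binarises at
`>127` so legacy JPEG-round-tripped masks load identically. The source
distribution's MATLAB v7.3 (HDF5) containers are converted by
`convert-cx22` with shape-based key discovery (4-D array with a 3-sized
axis → images; matching 3-D arrays → masks, the larger-area one being
cytoplasm) and a manual `--keys` override, since the internal key layout
is not documented; MATLAB-transposed axis orders are detected and undone.
The predefined test split of the source dataset passes through untouched;
only the training set is split 0.9/0.1 into train/tuning, uniformly at
random at the image level under a fixed seed (no cross-validation).

**Synthetic generator.** `cytoseg.synthetic` emulates the statistical
structure of Pap-stained tiles so every downstream stage is testable
without a download: overlapping rotated elliptical cells (semi-axes
40–110 px at 512², 4–10 cells) on a light, slightly blue background;
per-cell cyan/pink staining with brightness jitter; exactly one dark
nucleus per cell with axis ratio f ∈ [0.15, 0.35], geometrically
contained in its cell (nucleus centre confined to the (1−f)-scaled
ellipse), so nucleus ⊆ cytoplasm holds pixelwise by construction; cells
near the border are cropped by the frame with probability 0.2, mirroring
real tiles cut by neighbouring crops; Gaussian blur (σ ∈ [0.4, 1.2]) and
pixel noise (sd 6). Masks are the unions of the cell and nucleus
ellipses (semantic, not instance, semantics; overlaps drawn
back-to-front). Per-sample streams derive from `(seed, index)`, so
datasets are order-independent and bit-reproducible. Under these
defaults the nucleus-positive fraction averages ≈0.03 — the minority
class the positive weight of 8 addresses.

What the generator does **not** model: chromatin texture, nucleoli,
dyskaryotic morphology, mucus/debris, uneven illumination, true staining
colour statistics (unconstrained choices), and instance ground truth.
Passing desk-scale tests therefore demonstrates the machinery —
training dynamics, ensembling, inference, metrics — not clinical-grade
accuracy on stained slides.

## Evaluation

Metrics are **micro-averaged**: confusion counts (TP, FP, TN, FN) are
pooled over every pixel of every test image, then

    sensitivity = TP/(TP+FN),  specificity = TN/(TN+FP),
    Dice = 2TP/(2TP+FP+FN)

are computed once. The standard Dice denominator is used; a circulating
variant printing TN in the denominator is a typographical error and is
not implemented (it is inconsistent with comparability to reported
baselines). Zero-denominator conventions: a vacuous denominator (no
positives in truth for sensitivity, no negatives for specificity, both
for Dice) scores 1.0 — no error was possible. Per-image macro-averaging
exists behind `evaluate_macro` but is not the default.

**Confidence intervals** are pixel-level bootstrap percentiles: B = 500
resamples of the N evaluated pixels with replacement, 95% percentile
interval. Because a pixel enters the metrics only through its confusion
category, a replicate is drawn as one multinomial over
(TP, FP, FN, TN)/N — distributionally identical to per-pixel index
resampling; the equivalence is enforced by a matched-draws oracle test.
Percentile (not BCa) intervals are used.

**Paired comparisons** between two predictors over the same truth use a
paired pixel bootstrap: per image and replicate, both predictors'
resampled category counts are coupled through a shared pixel resample
(implemented exactly via one multinomial over the merged CDF intervals
of the two category distributions — identical marginals then yield
identical draws), the micro-metric difference is recorded, and the
two-sided p-value is `2·min(P(diff≤0), P(diff≥0))`, floored at 1/B and
capped at 1. No multiple-testing correction is applied; p-values are
reported raw against α = 0.05.

**ROC/AUC** pools pixels (uniform seeded subsample above a cap), defines
AUC as the probability that a random positive pixel outranks a random
negative one with ties counted half (rank-sum form), and exports the
curve points; rank AUC and trapezoidal integration of the curve agree to
1e-9 in tests.

Report tables round to 4 decimals, half away from zero, and include an
"Average value" row that is the arithmetic mean of the per-model rows.

## Desk-scale reference study

Full-scale results require the real 1320-image dataset and GPU-scale
training and are not reproducible at desk scale. The package's
self-contained reference study (`cytoseg.benchmark.run_tiny_study`, also
what `scripts/acceptance.py` runs) uses: the four selected base models at
quarter width, 200 synthetic 64×64 samples per task (split 180/20),
40 held-out test samples from an independent seed, 3 epochs, batch 8,
single run per model, constant lr 5e-3, everything else per the recipe.
The constant short-run lr replaces the staged schedule because at 3
epochs the 30/60/90% milestones all floor to epochs 0–2 and would decay
the rate immediately; 5e-3 is used because the minority nucleus class
needs the larger steps to converge within ~75 updates. Typical results
(seeds 0–7): cytoplasm ensemble Dice 0.94–0.95, nucleus 0.66–0.70, and
the unweighted ensemble's Dice exceeds the members' arithmetic mean on
both tasks with paired p = 1/B — the qualitative ensemble claim, at desk
scale.

## Numerical choices and edge cases

- Probabilities are produced by a sigmoid; losses consume logits.
- `weighted_bce` on probabilities clamps to [1e-7, 1−1e-7].
- Thresholding is strict (`>`); exact ties go negative.
- Empty prediction/truth rasters and empty confusion totals raise.
- Bootstrap and ROC subsampling are seeded through `EvalConfig.seed`.
- Checkpoints are `.npz` state dicts with the model spec and training
  metadata embedded; probability maps persist as 16-bit PNGs
  (`round(p·65535)`), introducing ≤ 0.5/65535 quantisation.

## Known limitations

- Semantic masks only; touching cells are not separated and no
  object-level metrics (e.g. aggregated Jaccard) are computed.
- `init='imagenet'` depends on externally supplied encoder weights.
- The numpy backend is single-device and CPU-oriented; full-width
  512² training is out of its intended range.
- The synthetic generator's colour statistics are plausible but
  unconstrained by real slide data.
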