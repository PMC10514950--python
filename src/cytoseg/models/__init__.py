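"""Model zoo: candidate segmentation networks for the two cytology tasks.

Eight CNN combinations are supported — U-Net and U-Net++ with resnet34 or
densenet121 encoders, DeepLabV3 and DeepLabV3+ with resnet34 or resnet50 —
each buildable at full width (parameter counts are the architecture-fidelity
oracle) or as a quarter-width ``tiny`` variant for CPU-scale training runs.

Encoders may start from random (He) initialisation or from user-supplied
pretrained weights in ``.npz`` form (key per encoder parameter/buffer).
Pretrained natural-image encoders are not bundled with the package, so
``init='imagenet'`` requires an explicit weights file.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np

from .. import nn
from ..nn import functional as F
from .deeplab import DeepLabV3Decoder, DeepLabV3PlusDecoder
from .densenet import densenet121_encoder
from .resnet import resnet34_encoder, resnet50_encoder
from .unet import SegmentationHead, UnetDecoder, UnetPlusPlusDecoder

__all__ = [
    "ModelSpec", "SegmentationModel", "build_model", "count_parameters",
    "list_supported", "save_checkpoint", "load_checkpoint",
    "MissingPretrainedWeights", "IMAGENET_MEAN", "IMAGENET_STD",
]

ARCHITECTURES = ("unet", "unetplusplus", "deeplabv3", "deeplabv3plus")
ENCODERS = ("resnet34", "resnet50", "densenet121")
VALID_PAIRS = {
    "unet": ("resnet34", "densenet121"),
    "unetplusplus": ("resnet34", "densenet121"),
    "deeplabv3": ("resnet34", "resnet50"),
    "deeplabv3plus": ("resnet34", "resnet50"),
}

IMAGENET_MEAN = np.array([0.485, 0.456, 0.406], dtype=np.float32)
IMAGENET_STD = np.array([0.229, 0.224, 0.225], dtype=np.float32)

_TINY_WIDTH = 0.25


class MissingPretrainedWeights(RuntimeError):
    pass


@dataclasses.dataclass(frozen=True)
class ModelSpec:
    """Declarative architecture x encoder x initialisation choice."""

    architecture: str
    encoder: str
    init: str = "scratch"
    out_channels: int = 1
    tiny: bool = False

    def __post_init__(self):
        if self.architecture not in ARCHITECTURES:
            raise ValueError(f"unknown architecture {self.architecture!r}")
        if self.encoder not in ENCODERS:
            raise ValueError(f"unknown encoder {self.encoder!r}")
        if self.encoder not in VALID_PAIRS[self.architecture]:
            raise ValueError(
                f"{self.architecture} pairs only with "
                f"{VALID_PAIRS[self.architecture]}, got {self.encoder!r}")
        if self.init not in ("scratch", "imagenet"):
            raise ValueError(f"unknown init {self.init!r}")

    @property
    def name(self) -> str:
        arch = {"unet": "Unet", "unetplusplus": "UnetPlusPlus",
                "deeplabv3": "DeepLabV3", "deeplabv3plus": "DeepLabV3Plus"}[self.architecture]
        return f"{arch}_{self.encoder}" + ("_tiny" if self.tiny else "")

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self))

    @classmethod
    def from_json(cls, s: str) -> "ModelSpec":
        return cls(**json.loads(s))


class SegmentationModel(nn.Module):
    """Encoder-decoder network mapping an RGB batch to foreground probabilities.

    ``forward`` consumes a normalised NCHW tensor and returns logits at the
    input resolution; ``predict_proba`` consumes raw uint8 NHWC images and
    returns per-pixel probabilities in [0, 1].
    """

    def __init__(self, spec: ModelSpec, encoder, decoder, head,
                 upsample_to_input: bool):
        super().__init__()
        self.spec = spec
        self.encoder = encoder
        self.decoder = decoder
        self.head = head
        self.upsample_to_input = upsample_to_input

    def forward(self, x: nn.Tensor) -> nn.Tensor:
        size = x.shape[2:]
        feats = self.encoder(x)
        logits = self.head(self.decoder(feats))
        if self.upsample_to_input and logits.shape[2:] != tuple(size):
            logits = F.upsample_bilinear(logits, size)
        return logits

    # -- inference conveniences -------------------------------------------
    def preprocess(self, images: np.ndarray) -> np.ndarray:
        """uint8 NHWC (or HWC) -> normalised float32 NCHW."""
        arr = np.asarray(images)
        if arr.ndim == 3:
            arr = arr[None]
        arr = arr.astype(np.float32) / 255.0
        if self.spec.init == "imagenet":
            arr = (arr - IMAGENET_MEAN) / IMAGENET_STD
        return np.ascontiguousarray(arr.transpose(0, 3, 1, 2))

    def predict_proba(self, images: np.ndarray, batch_size: int = 8) -> np.ndarray:
        """Per-pixel foreground probabilities, shape (N, H, W)."""
        x = self.preprocess(images)
        self.eval()
        outs = []
        with nn.no_grad():
            for i in range(0, x.shape[0], batch_size):
                logits = self.forward(nn.Tensor(x[i:i + batch_size]))
                outs.append(F.sigmoid(logits).data[:, 0])
        return np.concatenate(outs, axis=0)


def build_model(spec: ModelSpec, seed: int = 0,
                encoder_weights: str | Path | None = None) -> SegmentationModel:
    """Construct a network from its spec with seeded initialisation."""
    nn.set_init_rng(np.random.default_rng(np.random.SeedSequence([seed & 0x7FFFFFFF, 77])))
    width = _TINY_WIDTH if spec.tiny else 1.0
    os_map = {"deeplabv3": 8, "deeplabv3plus": 16}
    output_stride = os_map.get(spec.architecture, 32)
    if spec.encoder == "resnet34":
        encoder = resnet34_encoder(width, output_stride)
    elif spec.encoder == "resnet50":
        encoder = resnet50_encoder(width, output_stride)
    else:
        encoder = densenet121_encoder(width)
    dec_ch = tuple(max(1, int(round(c * width))) for c in (256, 128, 64, 32, 16))
    if spec.architecture == "unet":
        decoder = UnetDecoder(encoder.out_channels, dec_ch)
        head = SegmentationHead(decoder.out_ch, spec.out_channels, kernel_size=3)
        upsample = False
    elif spec.architecture == "unetplusplus":
        decoder = UnetPlusPlusDecoder(encoder.out_channels, dec_ch)
        head = SegmentationHead(decoder.out_ch, spec.out_channels, kernel_size=3)
        upsample = False
    elif spec.architecture == "deeplabv3":
        decoder = DeepLabV3Decoder(encoder.out_channels, max(1, int(round(256 * width))))
        head = SegmentationHead(decoder.out_ch, spec.out_channels, kernel_size=1)
        upsample = True
    else:
        decoder = DeepLabV3PlusDecoder(encoder.out_channels, max(1, int(round(256 * width))))
        head = SegmentationHead(decoder.out_ch, spec.out_channels, kernel_size=1)
        upsample = True
    model = SegmentationModel(spec, encoder, decoder, head, upsample)
    if spec.init == "imagenet":
        if encoder_weights is None:
            raise MissingPretrainedWeights(
                "init='imagenet' needs an encoder weights file (.npz with one "
                "entry per encoder parameter/buffer); pretrained weights are "
                "not bundled. Build with init='scratch' or pass encoder_weights=...")
        load_encoder_weights(model, encoder_weights)
    return model


def load_encoder_weights(model: SegmentationModel, path: str | Path) -> None:
    with np.load(path) as npz:
        state = {k: npz[k] for k in npz.files}
    own = dict(model.encoder.named_parameters())
    bufs = dict(model.encoder.named_buffers())
    missing = (set(own) | set(bufs)) - set(state)
    if missing:
        raise MissingPretrainedWeights(
            f"encoder weights file lacks keys, e.g. {sorted(missing)[:3]}")
    for k, p in own.items():
        p.data = state[k].astype(p.data.dtype)
    for k, b in bufs.items():
        b[...] = state[k]


def count_parameters(model: SegmentationModel) -> int:
    """Total trainable scalar parameters (batch-norm stats excluded)."""
    return model.num_parameters()


def list_supported(tiny: bool = False, init: str = "scratch") -> list[ModelSpec]:
    """The eight supported CNN architecture/encoder combinations."""
    return [ModelSpec(a, e, init=init, tiny=tiny)
            for a in ARCHITECTURES for e in VALID_PAIRS[a]]


def save_checkpoint(model: SegmentationModel, path: str | Path,
                    metadata: dict | None = None) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    meta = dict(metadata or {})
    meta["spec"] = json.loads(model.spec.to_json())
    np.savez_compressed(path, __meta__=np.frombuffer(
        json.dumps(meta).encode(), dtype=np.uint8),
        **{k: v for k, v in model.state_dict().items()})


def load_checkpoint(path: str | Path) -> tuple[SegmentationModel, dict]:
    with np.load(path) as npz:
        meta = json.loads(bytes(npz["__meta__"]).decode())
        state = {k: npz[k] for k in npz.files if k != "__meta__"}
    spec = ModelSpec(**meta["spec"])
    model = build_model(dataclasses.replace(spec, init="scratch"), seed=0)
    model.spec = spec  # restore declared init (controls preprocessing)
    model.load_state_dict(state)
    return model, meta
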