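"""DenseNet-121 feature encoder.

Dense blocks of (6, 12, 24, 16) layers with growth rate 32 and
bottleneck factor 4, halving transitions in between and a final batch
norm, exactly the 117-convolution feature extractor of DenseNet-121.
Staged so the skip resolutions are H/2, H/4, H/8, H/16 with channel
counts (64, 256, 512, 1024) and a final H/32 map of 1024 channels; the
transition's average-pool opens the *next* stage so each skip is taken
before the resolution drops.
"""

from __future__ import annotations

from .. import nn
from ..nn import functional as F

__all__ = ["DenseNetEncoder", "densenet121_encoder"]


class DenseLayer(nn.Module):
    def __init__(self, in_ch: int, growth: int, bn_size: int):
        super().__init__()
        self.norm1 = nn.BatchNorm2d(in_ch)
        self.conv1 = nn.Conv2d(in_ch, bn_size * growth, 1, bias=False)
        self.norm2 = nn.BatchNorm2d(bn_size * growth)
        self.conv2 = nn.Conv2d(bn_size * growth, growth, 3, padding=1, bias=False)

    def forward(self, x):
        out = self.conv1(F.relu(self.norm1(x)))
        out = self.conv2(F.relu(self.norm2(out)))
        return F.concat([x, out], axis=1)


class DenseBlock(nn.Module):
    def __init__(self, in_ch: int, n_layers: int, growth: int, bn_size: int):
        super().__init__()
        ch = in_ch
        for i in range(n_layers):
            setattr(self, f"layer{i}", DenseLayer(ch, growth, bn_size))
            ch += growth
        self.out_ch = ch

    def forward(self, x):
        for m in self._modules.values():
            x = m(x)
        return x


class TransitionConv(nn.Module):
    """Norm + 1x1 halving conv; the 2x2 average pool is applied separately."""

    def __init__(self, in_ch: int):
        super().__init__()
        self.norm = nn.BatchNorm2d(in_ch)
        self.conv = nn.Conv2d(in_ch, in_ch // 2, 1, bias=False)
        self.out_ch = in_ch // 2

    def forward(self, x):
        return self.conv(F.relu(self.norm(x)))


class DenseNetEncoder(nn.Module):
    def __init__(self, block_layers=(6, 12, 24, 16), growth: int = 32,
                 bn_size: int = 4, width: float = 1.0):
        super().__init__()
        growth = max(1, int(round(growth * width)))
        stem = max(1, int(round(64 * width)))
        self.conv0 = nn.Conv2d(3, stem, 7, stride=2, padding=3, bias=False)
        self.norm0 = nn.BatchNorm2d(stem)
        self.pool0 = nn.MaxPool2d(3, 2, 1)
        ch = stem
        skips = [3, stem]
        for i, n in enumerate(block_layers):
            blk = DenseBlock(ch, n, growth, bn_size)
            setattr(self, f"block{i}", blk)
            ch = blk.out_ch
            if i < len(block_layers) - 1:
                skips.append(ch)
                tr = TransitionConv(ch)
                setattr(self, f"transition{i}", tr)
                ch = tr.out_ch
        self.norm5 = nn.BatchNorm2d(ch)
        self.n_blocks = len(block_layers)
        self.out_channels = tuple(skips + [ch])

    def forward(self, x) -> list:
        feats = [x]
        x = F.relu(self.norm0(self.conv0(x)))
        feats.append(x)
        x = self.pool0(x)
        for i in range(self.n_blocks):
            x = getattr(self, f"block{i}")(x)
            if i < self.n_blocks - 1:
                feats.append(x)
                x = getattr(self, f"transition{i}")(x)
                x = F.avg_pool2d_2x2(x)
        x = F.relu(self.norm5(x))
        feats.append(x)
        return feats


def densenet121_encoder(width: float = 1.0) -> DenseNetEncoder:
    return DenseNetEncoder((6, 12, 24, 16), growth=32, bn_size=4, width=width)
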