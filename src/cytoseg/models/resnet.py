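"""ResNet-34/50 feature encoders.

Stage layout follows the canonical residual networks: a 7x7 stem, a 3x3
max-pool, then four residual stages. As a segmentation encoder the
classification head is dropped and the per-stage feature maps are
returned (identity, stem, stage1..stage4), i.e. resolutions
H, H/2, H/4, H/8, H/16, H/32.

``width`` scales every channel count (1.0 = full; 0.25 = the tiny CPU
variant). ``output_stride`` < 32 converts the stride of the late stages
into dilation for the atrous-pyramid decoders.
"""

from __future__ import annotations

import numpy as np

from .. import nn
from ..nn import functional as F

__all__ = ["ResNetEncoder", "resnet34_encoder", "resnet50_encoder"]


def _c(base: int, width: float) -> int:
    return max(1, int(round(base * width)))


class BasicBlock(nn.Module):
    expansion = 1

    def __init__(self, in_ch: int, out_ch: int, stride: int = 1, dilation: int = 1,
                 downsample: nn.Module | None = None):
        super().__init__()
        self.conv1 = nn.Conv2d(in_ch, out_ch, 3, stride=stride, padding=dilation,
                               dilation=dilation, bias=False)
        self.bn1 = nn.BatchNorm2d(out_ch)
        self.conv2 = nn.Conv2d(out_ch, out_ch, 3, padding=dilation,
                               dilation=dilation, bias=False)
        self.bn2 = nn.BatchNorm2d(out_ch)
        self.downsample = downsample

    def forward(self, x):
        identity = x if self.downsample is None else self.downsample(x)
        out = F.relu(self.bn1(self.conv1(x)))
        out = self.bn2(self.conv2(out))
        return F.relu(F.add(out, identity))


class Bottleneck(nn.Module):
    expansion = 4

    def __init__(self, in_ch: int, mid_ch: int, stride: int = 1, dilation: int = 1,
                 downsample: nn.Module | None = None):
        super().__init__()
        out_ch = mid_ch * self.expansion
        self.conv1 = nn.Conv2d(in_ch, mid_ch, 1, bias=False)
        self.bn1 = nn.BatchNorm2d(mid_ch)
        self.conv2 = nn.Conv2d(mid_ch, mid_ch, 3, stride=stride, padding=dilation,
                               dilation=dilation, bias=False)
        self.bn2 = nn.BatchNorm2d(mid_ch)
        self.conv3 = nn.Conv2d(mid_ch, out_ch, 1, bias=False)
        self.bn3 = nn.BatchNorm2d(out_ch)
        self.downsample = downsample

    def forward(self, x):
        identity = x if self.downsample is None else self.downsample(x)
        out = F.relu(self.bn1(self.conv1(x)))
        out = F.relu(self.bn2(self.conv2(out)))
        out = self.bn3(self.conv3(out))
        return F.relu(F.add(out, identity))


class ResNetEncoder(nn.Module):
    def __init__(self, block, layers: list[int], width: float = 1.0,
                 output_stride: int = 32):
        super().__init__()
        if output_stride not in (8, 16, 32):
            raise ValueError("output_stride must be 8, 16 or 32")
        stem = _c(64, width)
        self.conv1 = nn.Conv2d(3, stem, 7, stride=2, padding=3, bias=False)
        self.bn1 = nn.BatchNorm2d(stem)
        self.maxpool = nn.MaxPool2d(3, 2, 1)
        self._in_ch = stem
        self._dilation = 1
        mids = [_c(c, width) for c in (64, 128, 256, 512)]
        strides = [1, 2, 2, 2]
        dilate = [False, False, output_stride <= 16, output_stride <= 8]
        self.layer1 = self._make_stage(block, mids[0], layers[0], strides[0], dilate[0])
        self.layer2 = self._make_stage(block, mids[1], layers[1], strides[1], dilate[1])
        self.layer3 = self._make_stage(block, mids[2], layers[2], strides[2], dilate[2])
        self.layer4 = self._make_stage(block, mids[3], layers[3], strides[3], dilate[3])
        self.out_channels = (3, stem, mids[0] * block.expansion,
                             mids[1] * block.expansion, mids[2] * block.expansion,
                             mids[3] * block.expansion)

    def _make_stage(self, block, mid: int, n_blocks: int, stride: int,
                    dilate: bool) -> nn.Sequential:
        prev_dilation = self._dilation
        if dilate:
            self._dilation *= stride
            stride = 1
        downsample = None
        out_ch = mid * block.expansion
        if stride != 1 or self._in_ch != out_ch:
            downsample = nn.Sequential(
                nn.Conv2d(self._in_ch, out_ch, 1, stride=stride, bias=False),
                nn.BatchNorm2d(out_ch))
        blocks = [block(self._in_ch, mid, stride, prev_dilation, downsample)]
        self._in_ch = out_ch
        for _ in range(1, n_blocks):
            blocks.append(block(self._in_ch, mid, 1, self._dilation))
        return nn.Sequential(*blocks)

    def forward(self, x) -> list:
        """Return the six pyramid features (input, stem, stage1..4)."""
        feats = [x]
        x = F.relu(self.bn1(self.conv1(x)))
        feats.append(x)
        x = self.maxpool(x)
        x = self.layer1(x)
        feats.append(x)
        x = self.layer2(x)
        feats.append(x)
        x = self.layer3(x)
        feats.append(x)
        x = self.layer4(x)
        feats.append(x)
        return feats


def resnet34_encoder(width: float = 1.0, output_stride: int = 32) -> ResNetEncoder:
    return ResNetEncoder(BasicBlock, [3, 4, 6, 3], width, output_stride)


def resnet50_encoder(width: float = 1.0, output_stride: int = 32) -> ResNetEncoder:
    return ResNetEncoder(Bottleneck, [3, 4, 6, 3], width, output_stride)
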