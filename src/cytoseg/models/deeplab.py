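"""DeepLabV3 and DeepLabV3+ heads with atrous spatial pyramid pooling.

DeepLabV3 runs the encoder at output stride 8 and applies an ASPP with
dilation rates (12, 24, 36), a 3x3 fusion conv and a 1x1 head, then
bilinear upsampling back to the input resolution. DeepLabV3+ runs at
output stride 16 with a separable-conv ASPP, fuses a 48-channel
projection of the stride-4 skip, and refines with a separable 3x3.
"""

from __future__ import annotations

from .. import nn
from ..nn import functional as F

__all__ = ["DeepLabV3Decoder", "DeepLabV3PlusDecoder"]


class ConvBNReLU(nn.Module):
    def __init__(self, in_ch, out_ch, k, dilation=1):
        super().__init__()
        pad = dilation if k == 3 else 0
        self.conv = nn.Conv2d(in_ch, out_ch, k, padding=pad, dilation=dilation, bias=False)
        self.bn = nn.BatchNorm2d(out_ch)

    def forward(self, x):
        return F.relu(self.bn(self.conv(x)))


class SeparableConvBNReLU(nn.Module):
    def __init__(self, in_ch, out_ch, dilation=1):
        super().__init__()
        self.depthwise = nn.Conv2d(in_ch, in_ch, 3, padding=dilation,
                                   dilation=dilation, groups=in_ch, bias=False)
        self.pointwise = nn.Conv2d(in_ch, out_ch, 1, bias=False)
        self.bn = nn.BatchNorm2d(out_ch)

    def forward(self, x):
        return F.relu(self.bn(self.pointwise(self.depthwise(x))))


class ASPPPooling(nn.Module):
    def __init__(self, in_ch, out_ch):
        super().__init__()
        self.conv = ConvBNReLU(in_ch, out_ch, 1)

    def forward(self, x):
        size = x.shape[2:]
        pooled = self.conv(F.global_avg_pool(x))
        return F.upsample_bilinear(pooled, size)


class ASPP(nn.Module):
    def __init__(self, in_ch: int, out_ch: int, rates=(12, 24, 36),
                 separable: bool = False):
        super().__init__()
        conv3 = SeparableConvBNReLU if separable else (
            lambda i, o, dilation: ConvBNReLU(i, o, 3, dilation=dilation))
        self.b0 = ConvBNReLU(in_ch, out_ch, 1)
        self.b1 = conv3(in_ch, out_ch, dilation=rates[0])
        self.b2 = conv3(in_ch, out_ch, dilation=rates[1])
        self.b3 = conv3(in_ch, out_ch, dilation=rates[2])
        self.pool = ASPPPooling(in_ch, out_ch)
        self.project = ConvBNReLU(5 * out_ch, out_ch, 1)

    def forward(self, x):
        branches = [self.b0(x), self.b1(x), self.b2(x), self.b3(x), self.pool(x)]
        return self.project(F.concat(branches, axis=1))


class DeepLabV3Decoder(nn.Module):
    output_stride = 8

    def __init__(self, encoder_channels: tuple[int, ...], out_ch: int = 256):
        super().__init__()
        self.aspp = ASPP(encoder_channels[-1], out_ch)
        self.fuse = ConvBNReLU(out_ch, out_ch, 3)
        self.out_ch = out_ch

    def forward(self, features: list):
        return self.fuse(self.aspp(features[-1]))


class DeepLabV3PlusDecoder(nn.Module):
    output_stride = 16

    def __init__(self, encoder_channels: tuple[int, ...], out_ch: int = 256,
                 low_level_ch: int = 48):
        super().__init__()
        scale = out_ch / 256  # keep tiny variants proportional
        low = max(1, int(round(low_level_ch * scale)))
        self.aspp = ASPP(encoder_channels[-1], out_ch, separable=True)
        self.aspp_refine = SeparableConvBNReLU(out_ch, out_ch)
        self.low_project = ConvBNReLU(encoder_channels[2], low, 1)
        self.fuse = SeparableConvBNReLU(out_ch + low, out_ch)
        self.out_ch = out_ch

    def forward(self, features: list):
        x = self.aspp_refine(self.aspp(features[-1]))
        x = F.upsample_bilinear(x, features[2].shape[2:])
        low = self.low_project(features[2])
        return self.fuse(F.concat([x, low], axis=1))
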