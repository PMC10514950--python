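"""U-Net and U-Net++ decoders over the pyramid encoders.

Both use five decoder stages of two 3x3 conv+BN+ReLU layers each (the
"10 conv layers" decoder), channel widths (256, 128, 64, 32, 16) at full
width, nearest-neighbour x2 upsampling, and a 3x3 single-channel
segmentation head. U-Net++ replaces the single skip at each resolution
with the dense grid of intermediate nodes, concatenating every earlier
node at that resolution with the encoder skip.
"""

from __future__ import annotations

from .. import nn
from ..nn import functional as F

__all__ = ["UnetDecoder", "UnetPlusPlusDecoder", "SegmentationHead"]


class DecoderBlock(nn.Module):
    def __init__(self, in_ch: int, skip_ch: int, out_ch: int):
        super().__init__()
        self.conv1 = nn.Conv2d(in_ch + skip_ch, out_ch, 3, padding=1, bias=False)
        self.bn1 = nn.BatchNorm2d(out_ch)
        self.conv2 = nn.Conv2d(out_ch, out_ch, 3, padding=1, bias=False)
        self.bn2 = nn.BatchNorm2d(out_ch)

    def forward(self, x, skip=None):
        x = F.upsample_nearest2x(x)
        if skip is not None:
            x = F.concat([x, skip], axis=1)
        x = F.relu(self.bn1(self.conv1(x)))
        return F.relu(self.bn2(self.conv2(x)))


class SegmentationHead(nn.Module):
    def __init__(self, in_ch: int, out_ch: int = 1, kernel_size: int = 3):
        super().__init__()
        self.conv = nn.Conv2d(in_ch, out_ch, kernel_size,
                              padding=kernel_size // 2, bias=True)

    def forward(self, x):
        return self.conv(x)


class UnetDecoder(nn.Module):
    def __init__(self, encoder_channels: tuple[int, ...],
                 decoder_channels: tuple[int, ...] = (256, 128, 64, 32, 16)):
        super().__init__()
        enc = list(encoder_channels[1:])[::-1]  # deepest first, input dropped
        in_chs = [enc[0]] + list(decoder_channels[:-1])
        skip_chs = enc[1:] + [0]
        for i, (ic, sc, oc) in enumerate(zip(in_chs, skip_chs, decoder_channels)):
            setattr(self, f"block{i}", DecoderBlock(ic, sc, oc))
        self.n_blocks = len(decoder_channels)
        self.out_ch = decoder_channels[-1]

    def forward(self, features: list):
        feats = features[1:][::-1]
        x = feats[0]
        skips = feats[1:]
        for i in range(self.n_blocks):
            skip = skips[i] if i < len(skips) else None
            x = getattr(self, f"block{i}")(x, skip)
        return x


class UnetPlusPlusDecoder(nn.Module):
    """Nested dense decoder; node x_{d}_{l} lives at depth d of column l."""

    def __init__(self, encoder_channels: tuple[int, ...],
                 decoder_channels: tuple[int, ...] = (256, 128, 64, 32, 16)):
        super().__init__()
        enc = list(encoder_channels[1:])[::-1]
        self.in_channels = [enc[0]] + list(decoder_channels[:-1])
        self.skip_channels = enc[1:] + [0]
        self.out_channels = list(decoder_channels)
        self.depth = len(self.in_channels) - 1
        for layer_idx in range(len(self.in_channels) - 1):
            for depth_idx in range(layer_idx + 1):
                if depth_idx == 0:
                    in_ch = self.in_channels[layer_idx]
                    skip_ch = self.skip_channels[layer_idx] * (layer_idx + 1)
                    out_ch = self.out_channels[layer_idx]
                else:
                    out_ch = self.skip_channels[layer_idx]
                    skip_ch = self.skip_channels[layer_idx] * (layer_idx + 1 - depth_idx)
                    in_ch = self.skip_channels[layer_idx - 1]
                setattr(self, f"x_{depth_idx}_{layer_idx}",
                        DecoderBlock(in_ch, skip_ch, out_ch))
        setattr(self, f"x_0_{len(self.in_channels) - 1}",
                DecoderBlock(self.in_channels[-1], 0, self.out_channels[-1]))
        self.out_ch = decoder_channels[-1]

    def forward(self, features: list):
        feats = features[1:][::-1]
        dense = {}
        for layer_idx in range(len(self.in_channels) - 1):
            for depth_idx in range(self.depth - layer_idx):
                if layer_idx == 0:
                    block = getattr(self, f"x_{depth_idx}_{depth_idx}")
                    dense[f"x_{depth_idx}_{depth_idx}"] = block(
                        feats[depth_idx], feats[depth_idx + 1])
                else:
                    col = depth_idx + layer_idx
                    cat = [dense[f"x_{idx}_{col}"] for idx in range(depth_idx + 1, col + 1)]
                    skip = F.concat(cat + [feats[col + 1]], axis=1)
                    block = getattr(self, f"x_{depth_idx}_{col}")
                    dense[f"x_{depth_idx}_{col}"] = block(
                        dense[f"x_{depth_idx}_{col - 1}"], skip)
        final = getattr(self, f"x_0_{self.depth}")
        return final(dense[f"x_0_{self.depth - 1}"])
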