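"""The RA-CNN architecture: R-blocks, grouped A-blocks and the RA-UNET core.

The network classifies a 3 x 224 x 224 beat scalogram into the four
AAMI classes N/S/V/F.  It is assembled from three interacting layers:

* **top layer** — a convolutional stem (7x7 stride-2 conv, 3x3 stride-2
  max pool, one R-block) producing the initial 56x56x16 feature map,
  followed after skip fusion by a bottleneck head (three strided
  R-blocks, global average pooling, a fully connected classifier);
* **middle layer** — a single R-block applied to the initial map;
* **bottom layer** — RA-UNET, a three-level encoder/decoder (max-pool
  down, bilinear up) with a grouped attention block after every sampling
  step and same-size additive skip connections.

The three 56x56x16 outputs are fused by elementwise sum, which keeps the
feature magnitudes from decaying through the stacked ReLU stages.

**R-block** is a pre-activation bottleneck: three BatchNorm-ReLU-Conv
stages (1x1 reduce, 3x3 with the block's stride, 1x1 expand) plus either
an identity shortcut (same channels, stride 1) or a single strided 1x1
projection.

**A-block** splits the channels into ``n`` groups and each group into a
channel-attention half and a spatial-attention half.  The channel half
weights its channels by a softmax over per-channel affine-transformed
global-average statistics; the spatial half weights its positions by a
softmax over per-channel affine-transformed group-normalised maps; both
halves keep a residual connection and are concatenated back together.
Every switch the ablation study flips (no R-block, no A-block,
channel-only, spatial-only, no top skip, no middle layer) is a
constructor flag.
"""

from __future__ import annotations

import numpy as np

from .nn import (
    BatchNorm2d,
    Conv2d,
    GlobalAvgPool2d,
    Linear,
    MaxPool2d,
    Module,
    Tensor,
    Upsample,
    concat,
    group_norm,
    softmax,
)

__all__ = ["RBlock", "ABlock", "RAUNet", "RACNN", "make_feature_block"]


class _BNReLUConv(Module):
    """One pre-activation stage: BatchNorm2d -> ReLU -> Conv2d."""

    def __init__(self, in_ch, out_ch, k, stride, rng):
        super().__init__()
        self.bn = BatchNorm2d(in_ch)
        self.conv = Conv2d(in_ch, out_ch, k, stride=stride, rng=rng)

    def forward(self, x):
        return self.conv(self.bn(x).relu())


class RBlock(Module):
    """Pre-activation bottleneck residual block with a conditional shortcut.

    Main path: 1x1 (in->mid), 3x3 (mid->mid, carries the stride),
    1x1 (mid->out).  When in_ch == out_ch and every stride is 1 the
    shortcut is the identity; otherwise it is a single strided 1x1
    projection convolution.
    """

    def __init__(self, in_ch: int, mid_ch: int, out_ch: int,
                 strides: tuple[int, int, int] = (1, 1, 1),
                 rng: np.random.Generator | None = None):
        super().__init__()
        if any(s not in (1, 2) for s in strides):
            raise ValueError("strides must be 1 or 2")
        self.in_ch, self.out_ch = in_ch, out_ch
        self.f1 = _BNReLUConv(in_ch, mid_ch, 1, strides[0], rng)
        self.f2 = _BNReLUConv(mid_ch, mid_ch, 3, strides[1], rng)
        self.f3 = _BNReLUConv(mid_ch, out_ch, 1, strides[2], rng)
        total_stride = strides[0] * strides[1] * strides[2]
        self.identity = (in_ch == out_ch) and total_stride == 1
        if not self.identity:
            self.proj = Conv2d(in_ch, out_ch, 1, stride=total_stride, pad=0, rng=rng)

    def forward(self, x: Tensor) -> Tensor:
        if x.shape[1] != self.in_ch:
            raise ValueError(f"expected {self.in_ch} channels, got {x.shape[1]}")
        main = self.f3(self.f2(self.f1(x)))
        shortcut = x if self.identity else self.proj(x)
        return main + shortcut


class _ConvReplacement(Module):
    """Plain 3x3 conv standing in for an R-block in the no-R-block ablation."""

    def __init__(self, in_ch, out_ch, stride, rng):
        super().__init__()
        self.conv = Conv2d(in_ch, out_ch, 3, stride=stride, rng=rng)

    def forward(self, x):
        return self.conv(x)


class _Identity(Module):
    def forward(self, x):
        return x


def make_feature_block(in_ch: int, mid_ch: int, out_ch: int,
                       strides: tuple[int, int, int] = (1, 1, 1),
                       use_rblock: bool = True,
                       rng: np.random.Generator | None = None) -> Module:
    """An R-block, or its ablation stand-in.

    Without R-blocks, strided / channel-changing blocks become the plain
    conv2d they contain and pure feature-processing blocks are removed.
    """
    if use_rblock:
        return RBlock(in_ch, mid_ch, out_ch, strides, rng)
    total_stride = strides[0] * strides[1] * strides[2]
    if in_ch == out_ch and total_stride == 1:
        return _Identity()
    return _ConvReplacement(in_ch, out_ch, total_stride, rng)


class ABlock(Module):
    """Grouped channel/spatial attention with residual halves.

    Channels are split into `groups` groups; each group's first half gets
    channel attention (softmax over channels of an affine-mapped global
    average), the second half spatial attention (softmax over positions
    of an affine-mapped group-normalised map).  W (scale) parameters are
    initialised to ones and b (shift) to zeros, one pair per group and
    branch, each of extent C/(2*groups).
    """

    def __init__(self, channels: int, groups: int = 2,
                 channel_att: bool = True, spatial_att: bool = True,
                 gn_groups: int = 1):
        super().__init__()
        if channels % (2 * groups):
            raise ValueError(f"channels ({channels}) must be divisible by "
                             f"2*groups ({2 * groups})")
        self.channels = channels
        self.groups = groups
        self.half = channels // (2 * groups)
        self.channel_att = channel_att
        self.spatial_att = spatial_att
        self.gn_groups = gn_groups
        self.W1 = Tensor(np.ones((groups, self.half)), requires_grad=True)
        self.b1 = Tensor(np.zeros((groups, self.half)), requires_grad=True)
        self.W2 = Tensor(np.ones((groups, self.half)), requires_grad=True)
        self.b2 = Tensor(np.zeros((groups, self.half)), requires_grad=True)

    def channel_weights(self, x1: Tensor, i: int) -> Tensor:
        """Softmax-normalised channel attention for group `i` half `x1`."""
        s = x1.mean(axis=(2, 3))  # (N, half): global average per channel
        u = s * self.W1[i].reshape(1, self.half) + self.b1[i].reshape(1, self.half)
        return softmax(u, axis=1)

    def spatial_weights(self, x2: Tensor, i: int) -> Tensor:
        """Softmax-normalised spatial attention for group `i` half `x2`."""
        n, c, h, w = x2.shape
        t = group_norm(x2, self.gn_groups)
        u = t * self.W2[i].reshape(1, c, 1, 1) + self.b2[i].reshape(1, c, 1, 1)
        return softmax(u.reshape(n, c, h * w), axis=2).reshape(n, c, h, w)

    def forward(self, x: Tensor) -> Tensor:
        n, c, h, w = x.shape
        if c != self.channels:
            raise ValueError(f"expected {self.channels} channels, got {c}")
        outs = []
        for i in range(self.groups):
            g0 = i * 2 * self.half
            x1 = x[:, g0 : g0 + self.half]
            x2 = x[:, g0 + self.half : g0 + 2 * self.half]
            if self.channel_att:
                wts = self.channel_weights(x1, i)
                x1 = wts.reshape(n, self.half, 1, 1) * x1 + x1
            if self.spatial_att:
                wts = self.spatial_weights(x2, i)
                x2 = wts * x2 + x2
            outs.append(concat([x1, x2], axis=1))
        return concat(outs, axis=1) if len(outs) > 1 else outs[0]


class RAUNet(Module):
    """Three-level residual-attention U-Net on a (C, S, S) feature map.

    Encoder: 3 x [max-pool 3x3/2 -> A-block -> R-block], the innermost
    level carrying no R-block.  Decoder: 3 x [bilinear upsample ->
    additive same-size skip -> A-block] followed by a final R-block.
    Skip sources are the post-R-block encoder maps; the full-resolution
    skip is the module input itself.
    """

    def __init__(self, channels: int = 16, mid_channels: int = 4,
                 size: int = 56, groups: int = 2,
                 use_ablock: bool = True, use_rblock: bool = True,
                 channel_att: bool = True, spatial_att: bool = True,
                 use_skips: bool = True,
                 rng: np.random.Generator | None = None):
        super().__init__()
        if size % 8 == 0:
            sizes = [size // 2, size // 4, size // 8]
        else:  # pool with pad 1: s -> floor((s-1)/2)+1
            sizes = []
            s = size
            for _ in range(3):
                s = (s + 2 - 3) // 2 + 1
                sizes.append(s)
        self.size = size
        self.sizes = sizes
        self.use_skips = use_skips

        def ablock():
            if not use_ablock:
                return _Identity()
            return ABlock(channels, groups, channel_att, spatial_att)

        def rblock():
            return make_feature_block(channels, mid_channels, channels,
                                      (1, 1, 1), use_rblock, rng)

        self.pool = MaxPool2d(3, 2, pad=1)
        self.enc_a1, self.enc_r1 = ablock(), rblock()
        self.enc_a2, self.enc_r2 = ablock(), rblock()
        self.enc_a3 = ablock()
        self.up1 = Upsample((sizes[1], sizes[1]))
        self.dec_a1 = ablock()
        self.up2 = Upsample((sizes[0], sizes[0]))
        self.dec_a2 = ablock()
        self.up3 = Upsample((size, size))
        self.dec_a3 = ablock()
        self.out_r = rblock()

    def forward(self, x: Tensor, trace: dict | None = None) -> Tensor:
        if x.shape[2] != self.size or x.shape[3] != self.size:
            raise ValueError(f"expected {self.size}x{self.size} input, "
                             f"got {x.shape[2]}x{x.shape[3]}")
        t = trace if trace is not None else {}
        e1 = self.enc_r1(self.enc_a1(self.pool(x)))
        t["unet.enc1"] = e1.shape
        e2 = self.enc_r2(self.enc_a2(self.pool(e1)))
        t["unet.enc2"] = e2.shape
        e3 = self.enc_a3(self.pool(e2))
        t["unet.enc3"] = e3.shape
        d1 = self.up1(e3)
        if self.use_skips:
            d1 = d1 + e2
        d1 = self.dec_a1(d1)
        t["unet.dec1"] = d1.shape
        d2 = self.up2(d1)
        if self.use_skips:
            d2 = d2 + e1
        d2 = self.dec_a2(d2)
        t["unet.dec2"] = d2.shape
        d3 = self.up3(d2)
        if self.use_skips:
            d3 = d3 + x
        d3 = self.dec_a3(d3)
        out = self.out_r(d3)
        t["unet.out"] = out.shape
        return out


class RACNN(Module):
    """The full residual-attention CNN classifier.

    `input_size` must be divisible by 4 (two stride-2 stem stages); the
    canonical configuration is 224, giving the published 56x56x16
    initial feature map.  Smaller sizes scale the whole network down for
    quick experiments.
    """

    def __init__(self, n_classes: int = 4, input_size: int = 224,
                 in_channels: int = 3, stem_channels: int = 16,
                 groups: int = 2, seed: int | None = None,
                 use_rblock: bool = True, use_ablock: bool = True,
                 channel_att: bool = True, spatial_att: bool = True,
                 top_skip: bool = True, middle_layer: bool = True):
        super().__init__()
        if input_size % 4:
            raise ValueError("input_size must be divisible by 4")
        rng = np.random.default_rng(seed)
        self.input_size = input_size
        self.in_channels = in_channels
        self.top_skip = top_skip
        self.middle_layer = middle_layer
        ch = stem_channels
        s0 = input_size // 4  # feature-map size after the stem

        self.stem_conv = Conv2d(in_channels, ch, 7, stride=2, pad=3, rng=rng)
        self.stem_pool = MaxPool2d(3, 2, pad=1)
        self.rblock1 = make_feature_block(ch, ch // 4, ch, (1, 1, 1), use_rblock, rng)
        self.rblock5 = make_feature_block(ch, ch // 4, ch, (1, 1, 1), use_rblock, rng)
        self.unet = RAUNet(channels=ch, mid_channels=ch // 4, size=s0,
                           groups=groups, use_ablock=use_ablock,
                           use_rblock=use_rblock, channel_att=channel_att,
                           spatial_att=spatial_att, rng=rng)
        self.rblock2 = make_feature_block(ch, ch // 2, 2 * ch, (1, 2, 1), use_rblock, rng)
        self.rblock3 = make_feature_block(2 * ch, ch, 4 * ch, (1, 2, 1), use_rblock, rng)
        self.rblock4 = make_feature_block(4 * ch, ch, 4 * ch, (1, 2, 1), use_rblock, rng)
        self.gap = GlobalAvgPool2d()
        self.fc = Linear(4 * ch, n_classes, rng=rng)

    def forward(self, x: Tensor, return_trace: bool = False):
        if isinstance(x, np.ndarray):
            x = Tensor(x)
        if x.ndim != 4 or x.shape[1] != self.in_channels \
                or x.shape[2] != self.input_size or x.shape[3] != self.input_size:
            raise ValueError(
                f"expected (N, {self.in_channels}, {self.input_size}, "
                f"{self.input_size}) input, got {x.shape}")
        trace: dict[str, tuple] = {}
        h = self.stem_conv(x)
        trace["stem.conv"] = h.shape
        h = self.stem_pool(h)
        trace["stem.pool"] = h.shape
        f0 = self.rblock1(h)
        trace["rblock1"] = f0.shape
        parts = [self.unet(f0, trace)]
        if self.middle_layer:
            mid = self.rblock5(f0)
            trace["rblock5"] = mid.shape
            parts.append(mid)
        if self.top_skip:
            parts.append(f0)
        fused = parts[0]
        for p in parts[1:]:
            fused = fused + p
        trace["fused"] = fused.shape
        h = self.rblock2(fused)
        trace["rblock2"] = h.shape
        h = self.rblock3(h)
        trace["rblock3"] = h.shape
        h = self.rblock4(h)
        trace["rblock4"] = h.shape
        h = self.gap(h)
        trace["gap"] = h.shape
        scores = self.fc(h)
        trace["fc"] = scores.shape
        return (scores, trace) if return_trace else scores
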