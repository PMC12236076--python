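"""Backbones: the PGRNet lightweight multi-kernel network and the
ResNet18-scale baseline it replaces.

PGRBlock is a residual channel-split unit built on the partial-convolution
principle: a 3×3 convolution sees all ``C`` channels, a 5×5 convolution then
refines only the first ``C/2`` channels of that result, and a 7×7
convolution refines the first ``C/4`` channels of the 5×5 result; untouched
channel slices pass through unchanged.  The three slices
(``C/4`` from the 7×7 path, ``C/4`` untouched remainder of the 5×5 stage,
``C/2`` untouched remainder of the 3×3 stage) are concatenated back to ``C``
channels and added to the block input.

PGRNet stacks exactly five stride-2 3×3 convolutions and four PGRBlocks in
three stages::

    stage 1:  conv(3→w0, /2)  conv(w0→w1, /2)  PGRBlock(w1)
    stage 2:  conv(w1→w1, /2) PGRBlock(w1)     conv(w1→w2, /2)
    stage 3:  PGRBlock(w2)    conv(w2→w3, /2)  PGRBlock(w3)

and taps the feature pyramid at the stride-8/16/32 PGRBlock outputs
(channels ``w1, w2, w3``).
"""

from __future__ import annotations

import numpy as np

from . import nn
from .nn import Module, Conv2d, ConvNormAct, Identity, MaxPool2d, AvgPool2d

__all__ = ["PGRBlock", "PGRNet", "ResNet18Backbone", "group_conv"]


def group_conv(c_in: int, c_out: int, k: int, groups: int, stride: int = 1,
               norm: bool = True, act: str = "silu") -> ConvNormAct:
    """Grouped convolution block; parameters are 1/groups of the standard conv."""
    if c_in % groups or c_out % groups:
        raise ValueError(f"channels ({c_in}->{c_out}) not divisible by groups={groups}")
    return ConvNormAct(c_in, c_out, k, stride=stride, groups=groups, norm=norm, act=act)


class PGRBlock(Module):
    """Residual multi-kernel (3/5/7) channel-split block; preserves shape.

    Requires ``channels % 4 == 0`` so the half/quarter slices are integral.
    With zero convolution weights and normalisation disabled the block is the
    identity map.
    """

    def __init__(self, channels: int, kernel_sizes=(3, 5, 7), use_norm: bool = True,
                 activation: str = "silu"):
        super().__init__()
        if channels % 4:
            raise ValueError(f"PGRBlock needs channels divisible by 4, got {channels}")
        k3, k5, k7 = kernel_sizes
        c, half, quarter = channels, channels // 2, channels // 4
        self.channels = channels
        self.conv3 = ConvNormAct(c, c, k3, norm=use_norm, act=activation)
        self.conv5 = ConvNormAct(half, half, k5, norm=use_norm, act=activation)
        self.conv7 = ConvNormAct(quarter, quarter, k7, norm=use_norm, act=activation)

    def forward(self, x):
        c, half, quarter = self.channels, self.channels // 2, self.channels // 4
        y3 = self.conv3(x)
        # partial conv: first half refined at 5x5, remainder passes through
        y5 = self.conv5(y3[:, :half])
        rest3 = y3[:, half:]
        # first quarter of the 5x5 result refined at 7x7
        y7 = self.conv7(y5[:, :quarter])
        rest5 = y5[:, quarter:]
        out = nn.concat([y7, rest5, rest3], axis=1)
        return out + x


class PGRNet(Module):
    """Three-stage lightweight backbone; emits pyramid levels p3/p4/p5."""

    def __init__(self, widths=(64, 128, 256), stem_width: int | None = None,
                 use_norm: bool = True, activation: str = "silu"):
        super().__init__()
        w1, w2, w3 = widths
        for w in widths:
            if w % 4:
                raise ValueError(f"stage widths must be divisible by 4, got {widths}")
        w0 = stem_width or max(w1 // 2, 16)
        self.widths = (w1, w2, w3)
        a = dict(norm=use_norm, act=activation)
        # stage 1
        self.conv1 = ConvNormAct(3, w0, 3, stride=2, **a)
        self.conv2 = ConvNormAct(w0, w1, 3, stride=2, **a)
        self.block1 = PGRBlock(w1, use_norm=use_norm, activation=activation)
        # stage 2
        self.conv3 = ConvNormAct(w1, w1, 3, stride=2, **a)
        self.block2 = PGRBlock(w1, use_norm=use_norm, activation=activation)
        self.conv4 = ConvNormAct(w1, w2, 3, stride=2, **a)
        # stage 3
        self.block3 = PGRBlock(w2, use_norm=use_norm, activation=activation)
        self.conv5 = ConvNormAct(w2, w3, 3, stride=2, **a)
        self.block4 = PGRBlock(w3, use_norm=use_norm, activation=activation)

    @property
    def out_channels(self):
        return self.widths

    def forward(self, x) -> dict:
        x = self.block1(self.conv2(self.conv1(x)))      # stride 4
        p3 = self.block2(self.conv3(x))                 # stride 8
        p4 = self.block3(self.conv4(p3))                # stride 16
        p5 = self.block4(self.conv5(p4))                # stride 32
        return {"p3": p3, "p4": p4, "p5": p5}


class _BasicBlock(Module):
    """ResNet basic block, vd-style downsampling shortcut (avgpool + 1×1)."""

    def __init__(self, c_in, c_out, stride=1):
        super().__init__()
        self.conv1 = ConvNormAct(c_in, c_out, 3, stride=stride, act="relu")
        self.conv2 = ConvNormAct(c_out, c_out, 3, act="identity")
        if stride != 1 or c_in != c_out:
            layers = []
            if stride != 1:
                layers.append(AvgPool2d(stride))
            layers.append(ConvNormAct(c_in, c_out, 1, act="identity"))
            self.shortcut = nn.Sequential(*layers)
        else:
            self.shortcut = Identity()

    def forward(self, x):
        return (self.conv2(self.conv1(x)) + self.shortcut(x)).relu()


class ResNet18Backbone(Module):
    """ResNet18-scale baseline feature extractor with the deep 3-conv stem."""

    def __init__(self, widths=(64, 128, 256, 512)):
        super().__init__()
        c1, c2, c3, c4 = widths
        s = c1 // 2
        self.stem = nn.Sequential(
            ConvNormAct(3, s, 3, stride=2, act="relu"),
            ConvNormAct(s, s, 3, act="relu"),
            ConvNormAct(s, c1, 3, act="relu"),
        )
        self.pool = MaxPool2d(3, 2, 1)
        self.stage1 = nn.Sequential(_BasicBlock(c1, c1), _BasicBlock(c1, c1))
        self.stage2 = nn.Sequential(_BasicBlock(c1, c2, 2), _BasicBlock(c2, c2))
        self.stage3 = nn.Sequential(_BasicBlock(c2, c3, 2), _BasicBlock(c3, c3))
        self.stage4 = nn.Sequential(_BasicBlock(c3, c4, 2), _BasicBlock(c4, c4))
        self.widths = widths

    @property
    def out_channels(self):
        return self.widths[1:]

    def forward(self, x) -> dict:
        x = self.stage1(self.pool(self.stem(x)))
        p3 = self.stage2(x)
        p4 = self.stage3(p3)
        p5 = self.stage4(p4)
        return {"p3": p3, "p4": p4, "p5": p5}
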