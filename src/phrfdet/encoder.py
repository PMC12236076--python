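"""Hybrid encoder: intra-scale interaction (AIFI) + cross-scale fusion (CCFF).

The backbone pyramid (p3, p4, p5) is first projected to a common hidden
width.  AIFI — optionally with HiLo attention — refines the deepest level
only.  CCFF then runs a top-down path (upsample, concatenate, fuse) followed
by a bottom-up path (stride-2 conv, concatenate, fuse); each fusion block is
RepC3 in the baseline or RetC3 in the lightweight configuration.
"""

from __future__ import annotations

import numpy as np

from . import nn
from .nn import Module, ConvNormAct, UpsampleNearest2d, Tensor
from .hilo import AIFI, HiLoSpec
from .retention import RepC3, RetC3, RetBlockSpec

__all__ = ["HybridEncoder"]


class HybridEncoder(Module):
    """AIFI + CCFF over a 3-level pyramid; emits three maps at ``hidden_dim``.

    Parameters
    ----------
    in_channels : channel counts of (p3, p4, p5) from the backbone.
    hidden_dim : common width of the fusion path (256 at r18 scale).
    use_hilo : swap the AIFI attention from MHSA to HiLo.
    use_retc3 : swap every RepC3 fusion block for RetC3.
    retc3_dims : RetBlock width per fusion site (fpn p4, fpn p3, pan p4,
        pan p5) — the spatial-decay blocks may be sized per level.
    """

    def __init__(self, in_channels=(128, 256, 512), hidden_dim: int = 256,
                 num_heads: int = 8, ffn_dim: int = 1024,
                 use_hilo: bool = False, hilo: HiLoSpec | None = None,
                 use_retc3: bool = False, depth: int = 3,
                 retc3_dims=(80, 80, 80, 80), retc3_heads: int = 4,
                 retc3_ffn_ratio: float = 2.0,
                 gamma_range=(0.6, 0.98), expansion: float = 0.5):
        super().__init__()
        self.hidden_dim = hidden_dim
        self.input_proj = nn.ModuleList(
            [ConvNormAct(c, hidden_dim, 1, act="identity") for c in in_channels]
        )
        self.aifi = AIFI(hidden_dim, num_heads, ffn_dim,
                         attention="hilo" if use_hilo else "mhsa",
                         hilo=hilo or HiLoSpec(dim=hidden_dim, num_heads=num_heads))

        def fusion(i):
            if use_retc3:
                from .retention import default_gammas

                spec = RetBlockSpec(
                    dim=retc3_dims[i], heads=retc3_heads,
                    gammas=default_gammas(retc3_heads, *gamma_range),
                    ffn_ratio=retc3_ffn_ratio, depth_in_retc3=depth,
                )
                return RetC3(2 * hidden_dim, hidden_dim, spec)
            return RepC3(2 * hidden_dim, hidden_dim, depth, expansion)

        self.lateral_p5 = ConvNormAct(hidden_dim, hidden_dim, 1)
        self.fpn_p4 = fusion(0)
        self.lateral_p4 = ConvNormAct(hidden_dim, hidden_dim, 1)
        self.fpn_p3 = fusion(1)
        self.down_p3 = ConvNormAct(hidden_dim, hidden_dim, 3, stride=2)
        self.pan_p4 = fusion(2)
        self.down_p4 = ConvNormAct(hidden_dim, hidden_dim, 3, stride=2)
        self.pan_p5 = fusion(3)
        self.upsample = UpsampleNearest2d(2)

    def forward(self, pyramid: dict) -> list:
        p3 = self.input_proj[0](pyramid["p3"])
        p4 = self.input_proj[1](pyramid["p4"])
        p5 = self.input_proj[2](pyramid["p5"])
        p5 = self.aifi(p5)
        # top-down
        y5 = self.lateral_p5(p5)
        f4 = self.fpn_p4(nn.concat([self.upsample(y5), p4], axis=1))
        y4 = self.lateral_p4(f4)
        f3 = self.fpn_p3(nn.concat([self.upsample(y4), p3], axis=1))
        # bottom-up
        o4 = self.pan_p4(nn.concat([self.down_p3(f3), y4], axis=1))
        o5 = self.pan_p5(nn.concat([self.down_p4(o4), y5], axis=1))
        return [f3, o4, o5]
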