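"""Spatial-decay decomposed attention (MaSA), RetBlock, and the RetC3 /
RepC3 cross-scale fusion blocks.

MaSA models spatial interactions with an explicit distance prior: along one
axis, the attention between positions ``n`` and ``m`` is scaled by
``γ^|n−m|`` (the spatial decay mask), so nearby tokens dominate and remote
tokens are attenuated.  The two-dimensional attention is decomposed into two
one-dimensional passes — down columns with an ``H×H`` mask, then along rows
with a ``W×W`` mask — which takes the score computation from quadratic to
linear in the token count.  The mask is applied multiplicatively to the
softmax scores and the rows are renormalized, keeping each row a convex
combination.

RetBlock wraps MaSA in a transformer unit: a depthwise-convolution local
positional term, pre-norm MaSA, and a pre-norm FFN, all residual.  RetC3 is
the C3-style two-branch block carrying RetBlocks; RepC3 is the purely
convolutional baseline it replaces.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import nn
from .nn import (Module, Conv2d, ConvNormAct, Linear, LayerNorm, Identity,
                 Tensor, add_macs)

__all__ = ["RetBlockSpec", "spatial_decay_mask", "default_gammas",
           "MaSAttention", "RetBlock", "RetC3", "RepConv", "RepC3"]


def default_gammas(heads: int, lo: float = 0.6, hi: float = 0.98) -> tuple:
    """Per-head decay factors, log-spaced in [lo, hi] (stronger decay first)."""
    if heads == 1:
        return (float(hi),)
    return tuple(float(g) for g in np.exp(np.linspace(np.log(lo), np.log(hi), heads)))


@dataclass
class RetBlockSpec:
    dim: int = 80
    heads: int = 4
    gammas: tuple = ()
    ffn_ratio: float = 2.0
    depth_in_retc3: int = 3

    def __post_init__(self):
        if self.dim % self.heads:
            raise ValueError("dim must be divisible by heads")
        if not self.gammas:
            self.gammas = default_gammas(self.heads)
        if len(self.gammas) != self.heads:
            raise ValueError("need one gamma per head")
        for g in self.gammas:
            if not 0 < g <= 1:
                raise ValueError(f"gamma must lie in (0, 1], got {g}")


def spatial_decay_mask(length: int, gamma: float) -> np.ndarray:
    """Mask M[n, m] = gamma^|n−m|; symmetric, unit diagonal, entries in (0,1]."""
    if length < 1:
        raise ValueError("length must be >= 1")
    if not 0 < gamma <= 1:
        raise ValueError(f"decay gamma must lie in (0, 1], got {gamma}")
    idx = np.arange(length)
    return (gamma ** np.abs(idx[:, None] - idx[None, :])).astype(np.float32)


class MaSAttention(Module):
    """Decomposed 1-D attention with per-head spatial decay, on NCHW maps."""

    def __init__(self, spec: RetBlockSpec):
        super().__init__()
        self.spec = spec
        d = spec.dim
        self.q = Linear(d, d)
        self.k = Linear(d, d)
        self.v = Linear(d, d)
        self.out = Linear(d, d)
        self._mask_cache: dict = {}

    def _masks(self, length: int) -> np.ndarray:
        if length not in self._mask_cache:
            self._mask_cache[length] = np.stack(
                [spatial_decay_mask(length, g) for g in self.spec.gammas]
            )  # (heads, L, L)
        return self._mask_cache[length]

    def _axis_attention(self, q, k, v, mask):
        """q,k,v: (..., L, dh); mask broadcastable to the (..., L, L) scores."""
        dh = q.shape[-1]
        L = q.shape[-2]
        scores = (q @ k.transpose(*range(q.ndim - 2), q.ndim - 1, q.ndim - 2)) * (
            dh ** -0.5
        )
        add_macs(2 * int(np.prod(q.shape[:-2])) * L * L * dh)
        attn = scores.softmax(-1) * Tensor(mask)
        attn = attn / (attn.sum(axis=-1, keepdims=True) + 1e-9)
        return attn @ v

    def forward(self, x: Tensor, H: int, W: int) -> Tensor:
        """x: (B, N=H·W, dim) token grid; returns the same shape."""
        s = self.spec
        B, N, d = x.shape
        h, dh = s.heads, d // s.heads
        q = self.q(x).reshape(B, H, W, h, dh)
        k = self.k(x).reshape(B, H, W, h, dh)
        v = self.v(x).reshape(B, H, W, h, dh)
        # vertical pass: attend down each column (H×H scores per column)
        perm = (0, 3, 2, 1, 4)  # (B, h, W, H, dh)
        mh = self._masks(H)[None, :, None]
        y = self._axis_attention(q.transpose(perm), k.transpose(perm),
                                 v.transpose(perm), mh)
        # horizontal pass: attend along each row (W×W scores per row)
        y = y.transpose(0, 1, 3, 2, 4)  # (B, h, H, W, dh)
        qh = q.transpose(0, 3, 1, 2, 4)
        kh = k.transpose(0, 3, 1, 2, 4)
        mw = self._masks(W)[None, :, None]
        y = self._axis_attention(qh, kh, y, mw)
        y = y.transpose(0, 2, 3, 1, 4).reshape(B, N, d)
        return self.out(y)


class RetBlock(Module):
    """Positional term + pre-norm MaSA + pre-norm FFN, all residual.

    With every weight zeroed the block is the exact identity map.
    """

    def __init__(self, spec: RetBlockSpec):
        super().__init__()
        d = spec.dim
        self.spec = spec
        self.cpe = Conv2d(d, d, 3, padding=1, groups=d, bias=True)
        self.norm1 = LayerNorm(d)
        self.attn = MaSAttention(spec)
        self.norm2 = LayerNorm(d)
        hidden = int(d * spec.ffn_ratio)
        self.fc1 = Linear(d, hidden)
        self.fc2 = Linear(hidden, d)

    def forward(self, x: Tensor) -> Tensor:
        """x: NCHW feature map."""
        B, C, H, W = x.shape
        x = x + self.cpe(x)
        t = x.reshape(B, C, H * W).transpose(0, 2, 1)
        t = t + self.attn(self.norm1(t), H, W)
        t = t + self.fc2(self.fc1(self.norm2(t)).silu())
        return t.transpose(0, 2, 1).reshape(B, C, H, W)


class RetC3(Module):
    """C3-style fusion block whose residual branch carries RetBlocks."""

    def __init__(self, c_in: int, c_out: int, spec: RetBlockSpec | None = None):
        super().__init__()
        if c_in % 2:
            raise ValueError("RetC3 needs an even input channel count")
        self.spec = spec or RetBlockSpec()
        ch = self.spec.dim
        self.cv1 = ConvNormAct(c_in, ch, 1)
        self.cv2 = ConvNormAct(c_in, ch, 1)
        self.blocks = nn.Sequential(
            *[RetBlock(self.spec) for _ in range(self.spec.depth_in_retc3)]
        )
        self.cv3 = ConvNormAct(2 * ch, c_out, 1)

    def forward(self, x: Tensor) -> Tensor:
        a = self.blocks(self.cv1(x))
        b = self.cv2(x)
        return self.cv3(nn.concat([a, b], axis=1))


class RepConv(Module):
    """Train-time RepVGG-style conv: parallel 3×3 and 1×1 branches.

    The inference-time fusion into a single 3×3 conv is a deploy step; for
    accounting purposes the parameter/FLOP profile is reported on this
    training graph, matching the convention of the reference profiles.
    """

    def __init__(self, c_in, c_out, act="silu"):
        super().__init__()
        self.dense = ConvNormAct(c_in, c_out, 3, act="identity")
        self.pointwise = ConvNormAct(c_in, c_out, 1, act="identity")
        self.act = nn.make_activation(act)

    def forward(self, x):
        return self.act(self.dense(x) + self.pointwise(x))


class RepC3(Module):
    """Baseline fusion block: two 1×1 projections, a RepConv stack, 1×1 out."""

    def __init__(self, c_in: int, c_out: int, depth: int = 3, expansion: float = 0.5):
        super().__init__()
        ch = int(c_out * expansion)
        self.cv1 = ConvNormAct(c_in, ch, 1)
        self.cv2 = ConvNormAct(c_in, ch, 1)
        self.blocks = nn.Sequential(*[RepConv(ch, ch) for _ in range(depth)])
        self.cv3 = ConvNormAct(ch, c_out, 1) if ch != c_out else Identity()

    def forward(self, x):
        return self.cv3(self.blocks(self.cv1(x)) + self.cv2(x))
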