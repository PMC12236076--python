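"""HiLo attention and the AIFI intra-scale encoder block.

HiLo splits the ``N_h`` attention heads of width ``d`` into two branches:

* **Hi-Fi** — ``(1−a)·N_h`` heads run self-attention inside non-overlapping
  ``s×s`` windows, capturing local high-frequency detail;
* **Lo-Fi** — ``⌊a·N_h⌋`` heads keep full-resolution queries but compute keys
  and values from the ``s×s`` average-pooled token grid, capturing global
  low-frequency structure.

Each branch has its own projections sized to its head subset, so the total
projection parameter count never exceeds that of a standard ``N_h``-head
attention at width ``d`` (the swap is parameter-neutral).  The two branch
outputs are concatenated along channels; the per-branch output projections
play the role of the output projection.

AIFI applies a transformer encoder layer (attention + FFN, post-norm) with a
2-D sine/cosine positional encoding to the deepest pyramid level only;
``AIFI(attention="hilo")`` swaps the multi-head attention for HiLo.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import nn
from .nn import Module, Linear, LayerNorm, Tensor, add_macs

__all__ = ["HiLoSpec", "HiLoAttention", "MultiHeadSelfAttention", "AIFI",
           "sincos_position_embedding_2d"]


@dataclass
class HiLoSpec:
    dim: int = 256
    num_heads: int = 8
    lo_fraction: float = 0.5   # a: fraction of heads given to Lo-Fi
    window: int = 2            # s: window side and Lo-Fi pooling size

    def __post_init__(self):
        if self.dim % self.num_heads:
            raise ValueError("dim must be divisible by num_heads")
        if not 0.0 <= self.lo_fraction <= 1.0:
            raise ValueError("lo_fraction must lie in [0, 1]")
        if self.window < 1:
            raise ValueError("window must be >= 1")

    @property
    def lo_heads(self) -> int:
        return int(self.num_heads * self.lo_fraction)

    @property
    def hi_heads(self) -> int:
        return self.num_heads - self.lo_heads

    @property
    def head_dim(self) -> int:
        return self.dim // self.num_heads


def sincos_position_embedding_2d(h: int, w: int, dim: int,
                                 temperature: float = 10000.0) -> np.ndarray:
    """Standard 2-D sine/cosine positional table, shape (h*w, dim)."""
    if dim % 4:
        raise ValueError("embedding dim must be divisible by 4")
    grid_w = np.arange(w, dtype=np.float64)
    grid_h = np.arange(h, dtype=np.float64)
    ww, hh = np.meshgrid(grid_w, grid_h)  # (h, w)
    pos_dim = dim // 4
    omega = 1.0 / temperature ** (np.arange(pos_dim) / pos_dim)
    out_w = ww.reshape(-1)[:, None] * omega[None]
    out_h = hh.reshape(-1)[:, None] * omega[None]
    emb = np.concatenate(
        [np.sin(out_w), np.cos(out_w), np.sin(out_h), np.cos(out_h)], axis=1
    )
    return emb.astype(np.float32)


class MultiHeadSelfAttention(Module):
    """Vanilla multi-head attention with separate q/k/v/out projections."""

    def __init__(self, dim: int, num_heads: int = 8):
        super().__init__()
        if dim % num_heads:
            raise ValueError("dim must be divisible by num_heads")
        self.dim, self.h = dim, num_heads
        self.dh = dim // num_heads
        self.q = Linear(dim, dim)
        self.k = Linear(dim, dim)
        self.v = Linear(dim, dim)
        self.out = Linear(dim, dim)

    def forward(self, q_in: Tensor, k_in: Tensor | None = None,
                v_in: Tensor | None = None, mask: np.ndarray | None = None) -> Tensor:
        k_in = q_in if k_in is None else k_in
        v_in = k_in if v_in is None else v_in
        B, Nq, d = q_in.shape
        Nk = k_in.shape[1]
        q = self.q(q_in).reshape(B, Nq, self.h, self.dh).transpose(0, 2, 1, 3)
        k = self.k(k_in).reshape(B, Nk, self.h, self.dh).transpose(0, 2, 1, 3)
        v = self.v(v_in).reshape(B, Nk, self.h, self.dh).transpose(0, 2, 1, 3)
        attn = (q @ k.transpose(0, 1, 3, 2)) * (self.dh ** -0.5)
        add_macs(2 * B * self.h * Nq * Nk * self.dh)
        if mask is not None:
            # True entries are blocked
            attn = attn + Tensor(np.where(mask, -1e9, 0.0).astype(np.float32))
        attn = attn.softmax(-1)
        out = (attn @ v).transpose(0, 2, 1, 3).reshape(B, Nq, d)
        return self.out(out)


class HiLoAttention(Module):
    """High/low-frequency split attention on a spatial token grid."""

    def __init__(self, spec: HiLoSpec | None = None, **kwargs):
        super().__init__()
        self.spec = spec or HiLoSpec(**kwargs)
        s = self.spec
        self.hi_dim = s.hi_heads * s.head_dim
        self.lo_dim = s.lo_heads * s.head_dim
        if self.hi_dim:
            self.hi_qkv = Linear(s.dim, 3 * self.hi_dim)
            self.hi_proj = Linear(self.hi_dim, self.hi_dim)
        if self.lo_dim:
            self.lo_q = Linear(s.dim, self.lo_dim)
            self.lo_kv = Linear(s.dim, 2 * self.lo_dim)
            self.lo_proj = Linear(self.lo_dim, self.lo_dim)

    # -- helpers --------------------------------------------------------------
    def _pad_grid(self, x: Tensor, H: int, W: int):
        """Reflect-pad the (B,H,W,d) grid so H, W divide the window size."""
        s = self.spec.window
        ph = (-H) % s
        pw = (-W) % s
        if ph or pw:
            data = np.pad(x.data, [(0, 0), (0, ph), (0, pw), (0, 0)], mode="reflect")
            # gradient of the reflected rows/cols folds back onto their sources
            src = x

            def backward(g):
                if src.requires_grad:
                    core = g[:, :H, :W, :].copy()
                    if ph:
                        core[:, H - 1 - np.arange(1, ph + 1), :, :] += g[:, H:, :W, :]
                    if pw:
                        core[:, :, W - 1 - np.arange(1, pw + 1), :] += g[:, :H, W:, :]
                        if ph:
                            core[
                                :, H - 1 - np.arange(1, ph + 1)[:, None],
                                W - 1 - np.arange(1, pw + 1)[None, :], :
                            ] += g[:, H:, W:, :]
                    src._accum(core)

            x = Tensor._from_op(data, (src,), backward)
        return x, H + ph, W + pw

    def hifi(self, x: Tensor, H: int, W: int) -> Tensor:
        """Windowed attention on the Hi-Fi head subset; (B,N,d) -> (B,N,hi_dim)."""
        spec = self.spec
        s, h, dh = spec.window, spec.hi_heads, spec.head_dim
        B, N, d = x.shape
        grid = x.reshape(B, H, W, d)
        grid, Hp, Wp = self._pad_grid(grid, H, W)
        nH, nW = Hp // s, Wp // s
        qkv = self.hi_qkv(grid)  # (B,Hp,Wp,3*hi_dim)
        qkv = qkv.reshape(B, nH, s, nW, s, 3, h, dh).transpose(0, 1, 3, 5, 6, 2, 4, 7)
        qkv = qkv.reshape(B, nH * nW, 3, h, s * s, dh)
        q, k, v = qkv[:, :, 0], qkv[:, :, 1], qkv[:, :, 2]
        attn = (q @ k.transpose(0, 1, 2, 4, 3)) * (dh ** -0.5)
        add_macs(2 * B * nH * nW * h * (s * s) ** 2 * dh)
        out = (attn.softmax(-1) @ v)  # (B, nW_total, h, s*s, dh)
        out = out.reshape(B, nH, nW, h, s, s, dh).transpose(0, 1, 4, 2, 5, 3, 6)
        out = out.reshape(B, Hp, Wp, h * dh)[:, :H, :W, :].reshape(B, N, self.hi_dim)
        return self.hi_proj(out)

    def lofi(self, x: Tensor, H: int, W: int) -> Tensor:
        """Pooled-KV global attention on the Lo-Fi head subset."""
        spec = self.spec
        s, h, dh = spec.window, spec.lo_heads, spec.head_dim
        B, N, d = x.shape
        q = self.lo_q(x).reshape(B, N, h, dh).transpose(0, 2, 1, 3)
        if s > 1:
            grid = x.reshape(B, H, W, d)
            grid, Hp, Wp = self._pad_grid(grid, H, W)
            pooled = grid.reshape(B, Hp // s, s, Wp // s, s, d).mean(axis=4).mean(axis=2)
            pooled = pooled.reshape(B, (Hp // s) * (Wp // s), d)
        else:
            pooled = x
        M = pooled.shape[1]
        kv = self.lo_kv(pooled).reshape(B, M, 2, h, dh).transpose(0, 2, 3, 1, 4)
        k, v = kv[:, 0], kv[:, 1]
        attn = (q @ k.transpose(0, 1, 3, 2)) * (dh ** -0.5)
        add_macs(2 * B * h * N * M * dh)
        out = (attn.softmax(-1) @ v).transpose(0, 2, 1, 3).reshape(B, N, self.lo_dim)
        return self.lo_proj(out)

    def forward(self, x: Tensor, H: int, W: int) -> Tensor:
        parts = []
        if self.hi_dim:
            parts.append(self.hifi(x, H, W))
        if self.lo_dim:
            parts.append(self.lofi(x, H, W))
        return parts[0] if len(parts) == 1 else nn.concat(parts, axis=-1)


class _FFN(Module):
    def __init__(self, dim, hidden, act="gelu"):
        super().__init__()
        self.fc1 = Linear(dim, hidden)
        self.act = nn.make_activation(act)
        self.fc2 = Linear(hidden, dim)

    def forward(self, x):
        return self.fc2(self.act(self.fc1(x)))


class AIFI(Module):
    """Attention-based intra-scale feature interaction on the p5 level.

    Flattens the stride-32 map to tokens, adds the 2-D sin/cos positional
    table, runs one post-norm transformer layer (MHSA or HiLo attention +
    FFN), and restores the spatial layout.  Shape-preserving.
    """

    def __init__(self, dim: int = 256, num_heads: int = 8, ffn_dim: int = 1024,
                 attention: str = "mhsa", hilo: HiLoSpec | None = None,
                 act: str = "gelu"):
        super().__init__()
        self.dim = dim
        self.attention_kind = attention
        if attention == "mhsa":
            self.attn = MultiHeadSelfAttention(dim, num_heads)
        elif attention == "hilo":
            self.attn = HiLoAttention(hilo or HiLoSpec(dim=dim, num_heads=num_heads))
        else:
            raise ValueError(f"unknown attention kind {attention!r}")
        self.norm1 = LayerNorm(dim)
        self.ffn = _FFN(dim, ffn_dim, act=act)
        self.norm2 = LayerNorm(dim)

    def forward(self, p5: Tensor) -> Tensor:
        B, C, H, W = p5.shape
        x = p5.reshape(B, C, H * W).transpose(0, 2, 1)  # (B, N, C)
        pos = Tensor(sincos_position_embedding_2d(H, W, C))
        if self.attention_kind == "mhsa":
            xp = x + pos
            y = self.attn(xp, xp, x)  # queries/keys carry position, values do not
        else:
            y = self.attn(x + pos, H, W)
        x = self.norm1(x + y)
        x = self.norm2(x + self.ffn(x))
        return x.transpose(0, 2, 1).reshape(B, C, H, W)
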