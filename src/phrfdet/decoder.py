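"""Transformer decoder: uncertainty-minimal query selection, multi-scale
deformable cross-attention, iterative box refinement, optional denoising
query groups.

The encoder output pyramid is flattened into a memory sequence.  A linear
head scores every memory position and the top ``num_queries`` positions seed
the object queries (content = projected memory feature, reference box =
predicted box at that position, both detached).  Each decoder layer runs
masked self-attention, deformable cross-attention that samples the value
pyramid at learned offsets around the (detached) reference box, and an FFN;
a per-layer head refines the box in inverse-sigmoid space.  No NMS is
applied at any point.
"""

from __future__ import annotations

import numpy as np

from . import nn
from .nn import (Module, Linear, LayerNorm, Embedding, Tensor, add_macs,
                 make_activation)
from .hilo import MultiHeadSelfAttention

__all__ = ["RTDETRDecoder", "MSDeformableAttention", "inverse_sigmoid"]


def inverse_sigmoid(x: np.ndarray, eps: float = 1e-3) -> np.ndarray:
    x = np.clip(x, eps, 1 - eps)
    return np.log(x / (1 - x))


def _grid_sample_bilinear(value: Tensor, loc: Tensor, h: int, w: int) -> Tensor:
    """Bilinear sampling with zero padding outside the map.

    value: (G, dh, h, w); loc: (G, S, 2) in normalized [0,1] coords.
    Returns (G, S, dh).  Differentiable in both arguments.
    """
    G, dh, _, _ = value.shape
    S = loc.shape[1]
    vx = value.data
    x = loc.data[..., 0] * w - 0.5
    y = loc.data[..., 1] * h - 0.5
    x0 = np.floor(x).astype(np.int64)
    y0 = np.floor(y).astype(np.int64)
    fx = (x - x0).astype(np.float32)
    fy = (y - y0).astype(np.float32)
    gi = np.arange(G)[:, None]

    corners = []
    for dy, dx in ((0, 0), (0, 1), (1, 0), (1, 1)):
        xi = x0 + dx
        yi = y0 + dy
        inb = ((xi >= 0) & (xi < w) & (yi >= 0) & (yi < h)).astype(np.float32)
        xc = np.clip(xi, 0, w - 1)
        yc = np.clip(yi, 0, h - 1)
        wgt = ((fx if dx else 1 - fx) * (fy if dy else 1 - fy)) * inb
        corners.append((xc, yc, wgt, inb, dx, dy))

    out = np.zeros((G, S, dh), dtype=np.float32)
    gathered = []
    for xc, yc, wgt, inb, dx, dy in corners:
        gv = vx[gi, :, yc, xc]  # (G, S, dh)
        gathered.append(gv)
        out += wgt[..., None] * gv
    add_macs(4 * G * S * dh)

    def backward(g):
        if value.requires_grad:
            gval = np.zeros_like(vx)
            for (xc, yc, wgt, inb, dx, dy), gv in zip(corners, gathered):
                np.add.at(
                    gval.transpose(0, 2, 3, 1), (gi, yc, xc), g * wgt[..., None]
                )
            value._accum(gval)
        if loc.requires_grad:
            gx = np.zeros((G, S), dtype=np.float32)
            gy = np.zeros((G, S), dtype=np.float32)
            for (xc, yc, wgt, inb, dx, dy), gv in zip(corners, gathered):
                dot = (g * gv).sum(axis=-1)
                dwx = (1.0 if dx else -1.0) * (fy if dy else 1 - fy) * inb
                dwy = (fx if dx else 1 - fx) * (1.0 if dy else -1.0) * inb
                gx += dot * dwx
                gy += dot * dwy
            loc._accum(np.stack([gx * w, gy * h], axis=-1))

    return Tensor._from_op(out, (value, loc), backward)


class MSDeformableAttention(Module):
    """Deformable attention over a multi-level value pyramid.

    Each query predicts, per head and level, ``points`` sampling offsets
    (scaled by the reference box size) and a softmax-normalized weight; the
    output is the weighted sum of bilinearly sampled values.
    """

    def __init__(self, dim: int = 256, heads: int = 8, levels: int = 3,
                 points: int = 4):
        super().__init__()
        self.dim, self.h, self.levels, self.points = dim, heads, levels, points
        self.dh = dim // heads
        self.sampling_offsets = Linear(dim, heads * levels * points * 2)
        self.attention_weights = Linear(dim, heads * levels * points)
        self.value_proj = Linear(dim, dim)
        self.output_proj = Linear(dim, dim)

    def forward(self, query: Tensor, ref_boxes: np.ndarray, value: Tensor,
                spatial_shapes: list) -> Tensor:
        B, Q, d = query.shape
        h, L, P, dh = self.h, self.levels, self.points, self.dh
        v = self.value_proj(value)  # (B, Ltot, d)
        offsets = self.sampling_offsets(query).reshape(B, Q, h, L, P, 2)
        weights = (
            self.attention_weights(query)
            .reshape(B, Q, h, L * P)
            .softmax(-1)
            .reshape(B, Q, h, L, P)
        )
        # sampling locations around the reference box (normalized coords)
        ref = ref_boxes[:, :, None, None, None, :]  # (B,Q,1,1,1,4), constant
        loc = offsets * Tensor((ref[..., 2:] * 0.5 / P).astype(np.float32)) + Tensor(
            ref[..., :2].astype(np.float32)
        )  # (B,Q,h,L,P,2)
        starts = np.cumsum([0] + [hh * ww for hh, ww in spatial_shapes])[:-1]
        per_level = []
        for li, (hh, ww) in enumerate(spatial_shapes):
            vl = (
                v[:, starts[li] : starts[li] + hh * ww, :]
                .reshape(B, hh, ww, h, dh)
                .transpose(0, 3, 4, 1, 2)
                .reshape(B * h, dh, hh, ww)
            )
            ll = (
                loc[:, :, :, li]
                .transpose(0, 2, 1, 3, 4)
                .reshape(B * h, Q * P, 2)
            )
            sampled = _grid_sample_bilinear(vl, ll, hh, ww)  # (B*h, Q*P, dh)
            per_level.append(sampled.reshape(B, h, Q, P, dh))
        stacked = nn.stack(per_level, axis=3)  # (B,h,Q,L,P,dh)
        w_t = weights.transpose(0, 2, 1, 3, 4)  # (B,h,Q,L,P)
        out = (stacked * w_t.reshape(B, h, Q, L, P, 1)).sum(axis=(3, 4))
        add_macs(B * h * Q * L * P * dh)
        out = out.transpose(0, 2, 1, 3).reshape(B, Q, d)
        return self.output_proj(out)


class _MLP(Module):
    def __init__(self, dims, act="relu"):
        super().__init__()
        self.fcs = nn.ModuleList(
            [Linear(a, b) for a, b in zip(dims[:-1], dims[1:])]
        )
        self.act = make_activation(act)

    def forward(self, x):
        n = len(self.fcs)
        for i, fc in enumerate(self.fcs):
            x = fc(x)
            if i < n - 1:
                x = self.act(x)
        return x


class DecoderLayer(Module):
    def __init__(self, dim=256, heads=8, levels=3, points=4, ffn_dim=1024):
        super().__init__()
        self.self_attn = MultiHeadSelfAttention(dim, heads)
        self.norm1 = LayerNorm(dim)
        self.cross_attn = MSDeformableAttention(dim, heads, levels, points)
        self.norm2 = LayerNorm(dim)
        self.fc1 = Linear(dim, ffn_dim)
        self.fc2 = Linear(ffn_dim, dim)
        self.norm3 = LayerNorm(dim)

    def forward(self, tgt, query_pos, ref_boxes, value, spatial_shapes,
                attn_mask=None):
        q = tgt + query_pos
        tgt = self.norm1(tgt + self.self_attn(q, q, tgt, mask=attn_mask))
        tgt = self.norm2(
            tgt + self.cross_attn(tgt + query_pos, ref_boxes, value, spatial_shapes)
        )
        tgt = self.norm3(tgt + self.fc2(self.fc1(tgt).relu()))
        return tgt


class RTDETRDecoder(Module):
    """Denoising decoder with uncertainty-minimal query selection."""

    def __init__(self, num_classes: int = 5, dim: int = 256,
                 num_queries: int = 300, num_layers: int = 3, heads: int = 8,
                 points: int = 4, ffn_dim: int = 1024, levels: int = 3):
        super().__init__()
        self.num_classes, self.dim = num_classes, dim
        self.num_queries, self.num_layers = num_queries, num_layers
        self.enc_output = Linear(dim, dim)
        self.enc_norm = LayerNorm(dim)
        self.enc_score_head = Linear(dim, num_classes)
        self.enc_bbox_head = _MLP([dim, dim, dim, 4])
        self.query_pos_head = _MLP([4, 2 * dim, dim])
        self.layers = nn.ModuleList(
            [DecoderLayer(dim, heads, levels, points, ffn_dim) for _ in range(num_layers)]
        )
        self.score_heads = nn.ModuleList(
            [Linear(dim, num_classes) for _ in range(num_layers)]
        )
        self.bbox_heads = nn.ModuleList(
            [_MLP([dim, dim, dim, 4]) for _ in range(num_layers)]
        )
        self.denoising_class_embed = Embedding(num_classes + 1, dim)
        self._anchor_cache: dict = {}

    # -- anchors --------------------------------------------------------------
    def _anchors(self, spatial_shapes, grid_size: float = 0.05):
        key = tuple(spatial_shapes)
        if key not in self._anchor_cache:
            anchors = []
            for lvl, (h, w) in enumerate(spatial_shapes):
                gy, gx = np.meshgrid(np.arange(h), np.arange(w), indexing="ij")
                cxy = np.stack([(gx + 0.5) / w, (gy + 0.5) / h], axis=-1)
                wh = np.full((h, w, 2), grid_size * 2.0**lvl)
                anchors.append(
                    np.concatenate([cxy, wh], axis=-1).reshape(-1, 4)
                )
            anchors = np.concatenate(anchors, axis=0)
            valid = ((anchors > 0.01) & (anchors < 0.99)).all(-1, keepdims=True)
            # invalid border anchors are pushed to a saturating logit
            anchors = np.where(valid, inverse_sigmoid(anchors), 30.0)
            self._anchor_cache[key] = (anchors.astype(np.float32), valid)
        return self._anchor_cache[key]

    def forward(self, feats: list, denoising: dict | None = None) -> dict:
        """feats: encoder pyramid [f3, f4, f5] as NCHW tensors."""
        B = feats[0].shape[0]
        spatial_shapes = [(f.shape[2], f.shape[3]) for f in feats]
        memory = nn.concat(
            [f.reshape(f.shape[0], f.shape[1], -1).transpose(0, 2, 1) for f in feats],
            axis=1,
        )  # (B, Ltot, d)
        anchors, valid = self._anchors(spatial_shapes)
        masked = memory * Tensor(valid.astype(np.float32))
        out_mem = self.enc_norm(self.enc_output(masked))
        enc_logits = self.enc_score_head(out_mem)  # (B, Ltot, nc)

        # uncertainty-minimal selection: keep the positions with the highest
        # peak class score; the box head only runs on the selected subset
        conf = enc_logits.data.max(axis=-1)  # (B, Ltot)
        Q = self.num_queries
        topk = np.argsort(-conf, axis=1)[:, :Q]  # (B, Q)
        bi = np.arange(B)[:, None]
        sel_mem = out_mem[bi, topk]  # (B,Q,d)
        ref_logit = self.enc_bbox_head(sel_mem) + Tensor(anchors[topk])
        ref_boxes = Tensor._expit(ref_logit.data)
        tgt = sel_mem.detach()
        enc_topk_logits = enc_logits[bi, topk]
        enc_topk_boxes = ref_logit.sigmoid()

        attn_mask = None
        dn_meta = None
        if denoising is not None:
            dn_tgt = denoising["content"]           # (B, n_dn, d) Tensor
            dn_boxes = denoising["boxes"]           # (B, n_dn, 4) numpy cxcywh
            n_dn = dn_tgt.shape[1]
            tgt = nn.concat([dn_tgt, tgt], axis=1)
            ref_boxes = np.concatenate([dn_boxes, ref_boxes], axis=1)
            attn_mask = denoising["attn_mask"]
            dn_meta = {"n_dn": n_dn, "groups": denoising["groups"]}

        dec_logits, dec_boxes = [], []
        for layer, score_head, bbox_head in zip(
            self.layers, self.score_heads, self.bbox_heads
        ):
            query_pos = self.query_pos_head(Tensor(ref_boxes.astype(np.float32)))
            tgt = layer(tgt, query_pos, ref_boxes, memory, spatial_shapes,
                        attn_mask=attn_mask)
            delta = bbox_head(tgt)
            boxes = (delta + Tensor(inverse_sigmoid(ref_boxes))).sigmoid()
            dec_logits.append(score_head(tgt))
            dec_boxes.append(boxes)
            ref_boxes = boxes.data.copy()  # detached iterative refinement

        return {
            "logits": dec_logits,        # list over layers: (B, n_dn+Q, nc)
            "boxes": dec_boxes,          # cxcywh in [0,1]
            "enc_logits": enc_topk_logits,
            "enc_boxes": enc_topk_boxes,
            "dn_meta": dn_meta,
        }
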