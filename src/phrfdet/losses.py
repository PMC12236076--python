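"""IoU-family bounding-box regression losses.

Implements the ladder IoU → GIoU → WIoU v1 → WIoU v3 → Focaler-WIoUv3 used by
the detector's box-regression objective:

* ``L_IoU = 1 − IoU``; GIoU subtracts the normalized empty area of the
  smallest enclosing box.
* WIoU v1 multiplies ``L_IoU`` by the center-distance factor
  ``R_WIoU = exp(((cx−cx')² + (cy−cy')²) / (W_g² + H_g²))`` where
  ``(W_g, H_g)`` are the enclosing-box dimensions, treated as constants with
  respect to the gradient.
* WIoU v3 scales v1 by the non-monotonic focusing coefficient
  ``r = β / (δ·α^(β−δ))`` with the outlier degree
  ``β = L_IoU / mean(L_IoU)`` normalized by a running mean of the IoU loss.
* Focaler-IoU remaps IoU through the piecewise-linear interval map with
  thresholds ``(d, u)``, and the composite loss is
  ``L = L_WIoUv3 + IoU − IoU_focaler``.

All functions operate on corner-form boxes ``(x1, y1, x2, y2)``, accept either
autodiff :class:`~phrfdet.nn.Tensor` inputs (for training) or plain
array-likes (returned as numpy), and broadcast over leading dimensions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .nn.tensor import Tensor, as_tensor

__all__ = [
    "FocalerParams", "WIoUParams", "WIoUState",
    "iou", "giou_loss", "wiou_v1_loss", "wiou_v3_loss",
    "focaler_iou", "focaler_wiou_v3_loss", "detection_box_objective",
    "pairwise_iou", "pairwise_giou",
    "cxcywh_to_xyxy", "xyxy_to_cxcywh",
]

_EPS = 1e-9


@dataclass
class FocalerParams:
    """Interval thresholds of the Focaler IoU remap; requires 0 <= d < u <= 1."""

    d: float = 0.0
    u: float = 0.95

    def __post_init__(self):
        if not (0.0 <= self.d < self.u <= 1.0):
            raise ValueError(f"require 0 <= d < u <= 1, got d={self.d}, u={self.u}")


@dataclass
class WIoUParams:
    """Focusing constants of WIoU v3 (values from the WIoU reference setting)."""

    alpha: float = 1.9
    delta: float = 3.0
    momentum: float = 0.01

    def __post_init__(self):
        if not self.alpha > 1:
            raise ValueError("alpha must exceed 1")
        if not self.delta > 0:
            raise ValueError("delta must be positive")
        if not 0 < self.momentum <= 1:
            raise ValueError("momentum must lie in (0, 1]")


@dataclass
class WIoUState:
    """Exponential moving average of the IoU loss, read by the outlier degree.

    Before the first update the mean is undefined and β falls back to 1
    (warm-up convention), making v3 start as v1.
    """

    running_mean: float = 0.0
    initialized: bool = False

    def update(self, mean_liou: float, momentum: float) -> None:
        if not self.initialized:
            self.running_mean = float(mean_liou)
            self.initialized = True
        else:
            self.running_mean = (1 - momentum) * self.running_mean + momentum * float(
                mean_liou
            )


# ---------------------------------------------------------------------------
# box format conversions (pure numpy or Tensor, broadcastable)

def cxcywh_to_xyxy(b):
    t = isinstance(b, Tensor)
    cx, cy, w, h = (b[..., 0], b[..., 1], b[..., 2], b[..., 3])
    halves = (cx - w * 0.5, cy - h * 0.5, cx + w * 0.5, cy + h * 0.5)
    if t:
        from .nn.tensor import stack

        return stack(halves, axis=-1)
    return np.stack(halves, axis=-1)


def xyxy_to_cxcywh(b):
    t = isinstance(b, Tensor)
    x1, y1, x2, y2 = (b[..., 0], b[..., 1], b[..., 2], b[..., 3])
    parts = ((x1 + x2) * 0.5, (y1 + y2) * 0.5, x2 - x1, y2 - y1)
    if t:
        from .nn.tensor import stack

        return stack(parts, axis=-1)
    return np.stack(parts, axis=-1)


def _dispatch(pred, gt):
    """Return (pred, gt, unwrap): Tensors plus whether to return numpy."""
    wrap = isinstance(pred, Tensor) or isinstance(gt, Tensor)
    return as_tensor(pred), as_tensor(gt), not wrap


def _ret(x: Tensor, unwrap: bool):
    if not unwrap:
        return x
    out = x.data
    return float(out) if out.ndim == 0 else out


def _iou_parts(pred: Tensor, gt: Tensor):
    px1, py1, px2, py2 = pred[..., 0], pred[..., 1], pred[..., 2], pred[..., 3]
    gx1, gy1, gx2, gy2 = gt[..., 0], gt[..., 1], gt[..., 2], gt[..., 3]
    iw = px2.minimum(gx2) - px1.maximum(gx1)
    ih = py2.minimum(gy2) - py1.maximum(gy1)
    inter = iw.clip(0, np.inf) * ih.clip(0, np.inf)
    area_p = (px2 - px1) * (py2 - py1)
    area_g = (gx2 - gx1) * (gy2 - gy1)
    union = area_p + area_g - inter
    iou_val = inter / (union + _EPS)
    # smallest enclosing box
    ex1, ey1 = px1.minimum(gx1), py1.minimum(gy1)
    ex2, ey2 = px2.maximum(gx2), py2.maximum(gy2)
    return iou_val, union, (ex1, ey1, ex2, ey2)


def iou(pred, gt):
    """Intersection over union in [0, 1]; zero-union pairs give 0."""
    p, g, unwrap = _dispatch(pred, gt)
    val, _, _ = _iou_parts(p, g)
    return _ret(val, unwrap)


def giou_loss(pred, gt):
    """1 − GIoU, in [0, 2)."""
    p, g, unwrap = _dispatch(pred, gt)
    val, union, (ex1, ey1, ex2, ey2) = _iou_parts(p, g)
    enclose = (ex2 - ex1) * (ey2 - ey1)
    giou = val - (enclose - union) / (enclose + _EPS)
    return _ret(1.0 - giou, unwrap)


def wiou_v1_loss(pred, gt):
    """R_WIoU · L_IoU with a gradient-detached enclosing-box normalizer."""
    p, g, unwrap = _dispatch(pred, gt)
    val, _, (ex1, ey1, ex2, ey2) = _iou_parts(p, g)
    pcx = (p[..., 0] + p[..., 2]) * 0.5
    pcy = (p[..., 1] + p[..., 3]) * 0.5
    gcx = (g[..., 0] + g[..., 2]) * 0.5
    gcy = (g[..., 1] + g[..., 3]) * 0.5
    d2 = (pcx - gcx) ** 2 + (pcy - gcy) ** 2
    wg = (ex2 - ex1).detach()
    hg = (ey2 - ey1).detach()
    denom = wg**2 + hg**2
    r_wiou = (d2 / (denom + _EPS)).exp()
    return _ret(r_wiou * (1.0 - val), unwrap)


def _focusing_coefficient(liou_detached: np.ndarray, state: WIoUState,
                          params: WIoUParams) -> np.ndarray:
    """r = β / (δ·α^(β−δ)); β uses the detached loss over the running mean."""
    if state.initialized and state.running_mean > 0:
        beta = liou_detached / state.running_mean
    else:
        beta = np.ones_like(liou_detached)
    return beta / (params.delta * params.alpha ** (beta - params.delta))


def wiou_v3_loss(pred, gt, state: WIoUState, params: WIoUParams | None = None,
                 update_state: bool = True):
    """WIoU v1 scaled by the non-monotonic focusing coefficient r.

    The focusing coefficient is computed from detached quantities, so the
    gradient path is that of v1 times a constant.  ``state`` is updated with
    the batch-mean IoU loss by exponential moving average.
    """
    params = params or WIoUParams()
    p, g, unwrap = _dispatch(pred, gt)
    val, _, _ = _iou_parts(p, g)
    liou_det = np.atleast_1d(1.0 - val.data)
    r = _focusing_coefficient(liou_det, state, params).reshape(val.shape)
    out = Tensor(r.astype(np.float32)) * wiou_v1_loss(p, g)
    if update_state:
        state.update(float(liou_det.mean()), params.momentum)
    return _ret(out, unwrap)


def focaler_iou(iou_value, params: FocalerParams | None = None):
    """Piecewise-linear interval remap: 0 below d, (IoU−d)/(u−d) on [d,u], 1 above."""
    params = params or FocalerParams()
    wrap = isinstance(iou_value, Tensor)
    v = as_tensor(iou_value)
    out = ((v - params.d) * (1.0 / (params.u - params.d))).clip(0.0, 1.0)
    return _ret(out, not wrap)


def focaler_wiou_v3_loss(pred, gt, state: WIoUState,
                         wparams: WIoUParams | None = None,
                         fparams: FocalerParams | None = None,
                         update_state: bool = True):
    """Composite loss  L = L_WIoUv3 + IoU − IoU_focaler.

    At (d=0, u=1) the additive correction vanishes and the loss equals
    WIoU v3 exactly.
    """
    wparams = wparams or WIoUParams()
    fparams = fparams or FocalerParams()
    p, g, unwrap = _dispatch(pred, gt)
    val, _, _ = _iou_parts(p, g)
    lv3 = wiou_v3_loss(p, g, state, wparams, update_state=update_state)
    # grouping the additive correction keeps the (d=0, u=1) identity exact
    out = lv3 + (val - focaler_iou(val, fparams))
    return _ret(out, unwrap)


def detection_box_objective(pred_boxes, matched_gt_boxes, state: WIoUState,
                            wparams: WIoUParams | None = None,
                            fparams: FocalerParams | None = None,
                            weight_l1: float = 5.0, weight_iou: float = 2.0,
                            use_focaler_wiou: bool = True):
    """Box-regression term of the detection objective after matching.

    Keeps the standard RT-DETR weighting — an L1 term on normalized
    center-form coordinates (weight 5) plus an IoU-family term (weight 2) —
    and swaps the IoU-family term from GIoU to Focaler-WIoUv3.  Inputs are
    corner-form matched pairs; an empty match set yields zero loss.
    """
    p = as_tensor(pred_boxes)
    g = as_tensor(matched_gt_boxes)
    n = int(np.prod(p.shape[:-1]))
    if n == 0:
        return Tensor(0.0)
    if use_focaler_wiou:
        term = focaler_wiou_v3_loss(p, g, state, wparams, fparams)
    else:
        term = giou_loss(p, g)
    l1 = (xyxy_to_cxcywh(p) - xyxy_to_cxcywh(g)).abs().sum()
    return (weight_l1 / n) * l1 + (weight_iou / n) * term.sum()


# ---------------------------------------------------------------------------
# pairwise numpy variants (matching costs, metrics)

def pairwise_iou(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """IoU matrix (N, M) between corner-form box arrays (N,4) and (M,4)."""
    a = np.asarray(a, dtype=np.float64).reshape(-1, 4)
    b = np.asarray(b, dtype=np.float64).reshape(-1, 4)
    iw = np.minimum(a[:, None, 2], b[None, :, 2]) - np.maximum(a[:, None, 0], b[None, :, 0])
    ih = np.minimum(a[:, None, 3], b[None, :, 3]) - np.maximum(a[:, None, 1], b[None, :, 1])
    inter = np.clip(iw, 0, None) * np.clip(ih, 0, None)
    area_a = (a[:, 2] - a[:, 0]) * (a[:, 3] - a[:, 1])
    area_b = (b[:, 2] - b[:, 0]) * (b[:, 3] - b[:, 1])
    union = area_a[:, None] + area_b[None, :] - inter
    return inter / np.maximum(union, _EPS)


def pairwise_giou(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """GIoU matrix (N, M); in (−1, 1]."""
    a = np.asarray(a, dtype=np.float64).reshape(-1, 4)
    b = np.asarray(b, dtype=np.float64).reshape(-1, 4)
    iou_m = pairwise_iou(a, b)
    ew = np.maximum(a[:, None, 2], b[None, :, 2]) - np.minimum(a[:, None, 0], b[None, :, 0])
    eh = np.maximum(a[:, None, 3], b[None, :, 3]) - np.minimum(a[:, None, 1], b[None, :, 1])
    enclose = ew * eh
    area_a = (a[:, 2] - a[:, 0]) * (a[:, 3] - a[:, 1])
    area_b = (b[:, 2] - b[:, 0]) * (b[:, 3] - b[:, 1])
    iw = np.minimum(a[:, None, 2], b[None, :, 2]) - np.maximum(a[:, None, 0], b[None, :, 0])
    ih = np.minimum(a[:, None, 3], b[None, :, 3]) - np.maximum(a[:, None, 1], b[None, :, 1])
    inter = np.clip(iw, 0, None) * np.clip(ih, 0, None)
    union = area_a[:, None] + area_b[None, :] - inter
    return iou_m - (enclose - union) / np.maximum(enclose, _EPS)
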