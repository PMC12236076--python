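"""Training harness: Hungarian matching, the detection objective, denoising
query groups, and a small-scale overfit ("smoke") training loop.

The objective follows the RT-DETR recipe — sigmoid focal classification,
an L1 term on normalized center-form boxes (weight 5) and an IoU-family term
(weight 2) — with the IoU-family term switched between GIoU and
Focaler-WIoUv3 by the model variant.  Matching costs keep the standard GIoU
form regardless of the training loss.  Auxiliary losses are applied to every
decoder layer and to the encoder's selected queries; denoising groups add
noised copies of the ground truth with a fixed assignment, masked off from
the matching queries.
"""

from __future__ import annotations

import numpy as np
from PIL import Image
from scipy.optimize import linear_sum_assignment

from . import nn
from .nn import Tensor, Adam
from .losses import (FocalerParams, WIoUParams, WIoUState, cxcywh_to_xyxy,
                     giou_loss, focaler_wiou_v3_loss, pairwise_giou)
from .metrics import GroundTruth, evaluate
from .model import PHRFRTDETR, predict

__all__ = ["hungarian_match", "detection_loss", "build_denoising",
           "smoke_train", "prepare_batch"]


def hungarian_match(logits: np.ndarray, boxes: np.ndarray, gt_boxes: np.ndarray,
                    gt_labels: np.ndarray, w_class: float = 2.0,
                    w_l1: float = 5.0, w_giou: float = 2.0):
    """One-to-one assignment between queries and ground truths (per image).

    Cost = w_class·(−score of the gt class) + w_l1·L1(cxcywh) +
    w_giou·(1 − GIoU); solved exactly with the Hungarian algorithm.
    Returns (query_idx, gt_idx).
    """
    if len(gt_boxes) == 0:
        return np.empty(0, dtype=int), np.empty(0, dtype=int)
    prob = 1.0 / (1.0 + np.exp(-logits))  # (Q, nc)
    cost_class = -prob[:, gt_labels]
    cost_l1 = np.abs(boxes[:, None, :] - gt_boxes[None, :, :]).sum(-1)
    giou = pairwise_giou(_cxcywh_to_xyxy_np(boxes), _cxcywh_to_xyxy_np(gt_boxes))
    cost = w_class * cost_class + w_l1 * cost_l1 + w_giou * (1.0 - giou)
    qi, gi = linear_sum_assignment(cost)
    return qi, gi


def _cxcywh_to_xyxy_np(b: np.ndarray) -> np.ndarray:
    out = np.empty_like(b)
    out[..., 0] = b[..., 0] - b[..., 2] / 2
    out[..., 1] = b[..., 1] - b[..., 3] / 2
    out[..., 2] = b[..., 0] + b[..., 2] / 2
    out[..., 3] = b[..., 1] + b[..., 3] / 2
    return out


def _focal_loss(logits: Tensor, target_onehot: np.ndarray, alpha: float = 0.25,
                gamma: float = 2.0) -> Tensor:
    """Sigmoid focal loss, summed (caller normalizes)."""
    t = Tensor(target_onehot.astype(np.float32))
    p = logits.sigmoid()
    eps = 1e-8
    pos = (p + eps).log() * ((1.0 - p) ** gamma) * t * (-alpha)
    neg = (1.0 - p + eps).log() * (p**gamma) * (1.0 - t) * (-(1.0 - alpha))
    return (pos + neg).sum()


def _layer_loss(logits: Tensor, boxes: Tensor, targets: list, model,
                wiou_state: WIoUState, matches=None):
    """Classification + box loss of one prediction set; returns (loss, matches)."""
    cfg = model.config
    B, Q, nc = logits.shape
    onehot = np.zeros((B, Q, nc), dtype=np.float32)
    pred_rows, gt_rows = [], []
    out_matches = []
    for b, (gt_boxes, gt_labels) in enumerate(targets):
        if matches is None:
            qi, gi = hungarian_match(logits.data[b], boxes.data[b],
                                     gt_boxes, gt_labels)
        else:
            qi, gi = matches[b]
        out_matches.append((qi, gi))
        if len(qi) == 0:
            continue
        onehot[b, qi, gt_labels[gi]] = 1.0
        pred_rows.append((b, qi))
        gt_rows.append((gt_boxes[gi], gt_labels[gi]))
    num_gt = max(sum(len(t[0]) for t in targets), 1)
    loss = _focal_loss(logits, onehot) * (1.0 / num_gt)
    if pred_rows:
        mb = nn.concat([boxes[b][qi] for (b, qi) in pred_rows], axis=0)
        gb = np.concatenate([g[0] for g in gt_rows], axis=0).astype(np.float32)
        l1 = (mb - Tensor(gb)).abs().sum()
        pred_xyxy = cxcywh_to_xyxy(mb)
        gt_xyxy = Tensor(_cxcywh_to_xyxy_np(gb))
        if model.uses_focaler_wiou:
            term = focaler_wiou_v3_loss(
                pred_xyxy, gt_xyxy, wiou_state,
                WIoUParams(cfg.wiou_alpha, cfg.wiou_delta, cfg.wiou_momentum),
                FocalerParams(cfg.focaler_d, cfg.focaler_u),
            )
        else:
            term = giou_loss(pred_xyxy, gt_xyxy)
        loss = loss + (5.0 / num_gt) * l1 + (2.0 / num_gt) * term.sum()
    return loss, out_matches


def detection_loss(outputs: dict, targets: list, model: PHRFRTDETR,
                   wiou_state: WIoUState) -> Tensor:
    """Full objective over decoder layers, encoder queries and denoising part.

    ``targets``: per image (gt_boxes cxcywh normalized (G,4), gt_labels (G,)).
    """
    dn_meta = outputs.get("dn_meta")
    n_dn = dn_meta["n_dn"] if dn_meta else 0
    total = Tensor(0.0)
    for logits, boxes in zip(outputs["logits"], outputs["boxes"]):
        match_part, _ = _layer_loss(logits[:, n_dn:], boxes[:, n_dn:], targets,
                                    model, wiou_state)
        total = total + match_part
        if n_dn:
            dn_matches = _denoising_matches(dn_meta, targets)
            dn_part, _ = _layer_loss(logits[:, :n_dn], boxes[:, :n_dn], targets,
                                     model, wiou_state, matches=dn_matches)
            total = total + dn_part * (1.0 / dn_meta["groups"])
    enc_part, _ = _layer_loss(outputs["enc_logits"], outputs["enc_boxes"],
                              targets, model, wiou_state)
    return total + enc_part


# ---------------------------------------------------------------------------
# denoising groups

def _denoising_matches(dn_meta, targets):
    """Fixed assignment of denoising queries to their source ground truths."""
    g, m = dn_meta["groups"], dn_meta["max_gt"]
    out = []
    for gt_boxes, _ in targets:
        n = len(gt_boxes)
        qi = np.concatenate([grp * m + np.arange(n) for grp in range(g)]) if n else np.empty(0, int)
        gi = np.concatenate([np.arange(n) for _ in range(g)]) if n else np.empty(0, int)
        out.append((qi.astype(int), gi.astype(int)))
    return out


def build_denoising(targets: list, model: PHRFRTDETR, rng: np.random.Generator,
                    groups: int = 4, box_noise: float = 0.4,
                    label_noise: float = 0.3) -> dict | None:
    """Noised ground-truth query groups with a blockwise attention mask."""
    nc = model.config.num_classes
    max_gt = max((len(t[0]) for t in targets), default=0)
    if max_gt == 0:
        return None
    B = len(targets)
    n_dn = groups * max_gt
    boxes = np.zeros((B, n_dn, 4), dtype=np.float32)
    labels = np.full((B, n_dn), nc, dtype=int)  # padding uses the extra class
    for b, (gt_boxes, gt_labels) in enumerate(targets):
        n = len(gt_boxes)
        for grp in range(groups):
            s = grp * max_gt
            if n == 0:
                continue
            noise = (rng.random((n, 2)) * 2 - 1) * box_noise
            wh = gt_boxes[:, 2:]
            cxy = gt_boxes[:, :2] + noise * wh / 2
            scale = 1.0 + (rng.random((n, 2)) * 2 - 1) * box_noise
            nwh = np.clip(wh * scale, 1e-3, 1.0)
            boxes[b, s:s + n, :2] = np.clip(cxy, 0.0, 1.0)
            boxes[b, s:s + n, 2:] = nwh
            lab = gt_labels.copy()
            flip = rng.random(n) < label_noise
            lab[flip] = rng.integers(0, nc, flip.sum())
            labels[b, s:s + n] = lab
    content = model.decoder.denoising_class_embed(labels)  # (B, n_dn, d)
    Q = model.config.num_queries
    N = n_dn + Q
    mask = np.zeros((N, N), dtype=bool)
    mask[n_dn:, :n_dn] = True  # matching queries never see denoising ones
    for gi_ in range(groups):
        for gj in range(groups):
            if gi_ != gj:
                mask[gi_ * max_gt:(gi_ + 1) * max_gt,
                     gj * max_gt:(gj + 1) * max_gt] = True
    return {"content": content, "boxes": boxes, "attn_mask": mask,
            "groups": groups, "max_gt": max_gt}


# ---------------------------------------------------------------------------
# data preparation and the smoke loop

def prepare_batch(scenes: list, image_size: int):
    """Resize scenes to the model input; returns (images (B,3,S,S), targets)."""
    imgs, targets = [], []
    for img, recs in scenes:
        if img.shape[0] != image_size:
            img = np.asarray(
                Image.fromarray(img).resize((image_size, image_size),
                                            Image.BILINEAR)
            )
        imgs.append(img.astype(np.float32).transpose(2, 0, 1) / 255.0)
        gt_boxes = np.array([r.box for r in recs], dtype=np.float32).reshape(-1, 4)
        gt_labels = np.array([r.class_id for r in recs], dtype=int)
        targets.append((gt_boxes, gt_labels))
    return np.stack(imgs), targets


def smoke_train(model: PHRFRTDETR, scenes: list, epochs: int = 100,
                batch_size: int = 4, lr: float = 3e-4, seed: int = 0,
                image_size: int = 160, denoising_groups: int = 4,
                eval_score_threshold: float = 0.3, verbose: bool = False):
    """Overfit a small synthetic set and evaluate on the training images.

    Runs the full objective (classification + L1 + the variant's IoU-family
    loss); aborts with a diagnostic on NaN loss.  Returns
    (DetectionMetrics, per-epoch mean losses).
    """
    rng = np.random.default_rng(seed)
    model.train()
    opt = Adam(model.parameters(), lr=lr, clip_norm=10.0)
    state = WIoUState()
    images, targets = prepare_batch(scenes, image_size)
    n = len(scenes)
    history = []
    for epoch in range(epochs):
        order = rng.permutation(n)
        losses = []
        for s in range(0, n, batch_size):
            idx = order[s:s + batch_size]
            batch_t = [targets[i] for i in idx]
            dn = (build_denoising(batch_t, model, rng, groups=denoising_groups)
                  if denoising_groups else None)
            out = model(Tensor(images[idx]), denoising=dn)
            if out["dn_meta"] is not None:
                out["dn_meta"]["max_gt"] = dn["max_gt"]
            loss = detection_loss(out, batch_t, model, state)
            if not np.isfinite(loss.item()):
                raise RuntimeError(
                    f"non-finite loss at epoch {epoch}: {loss.item()!r}"
                )
            opt.zero_grad()
            loss.backward()
            opt.step()
            losses.append(loss.item())
        history.append(float(np.mean(losses)))
        if verbose and (epoch % 5 == 0 or epoch == epochs - 1):
            print(f"epoch {epoch:3d}  loss {history[-1]:.3f}")
    # evaluate on the training images (overfit check)
    gts = []
    for i, (_, recs) in enumerate(scenes):
        for r in recs:
            x1, y1, x2, y2 = r.xyxy
            gts.append(GroundTruth(str(i), r.class_id,
                                   np.array([x1, y1, x2, y2]) * image_size))
    det_lists = predict(model, images, score_threshold=eval_score_threshold,
                        image_ids=[str(i) for i in range(n)])
    dets = [d for lst in det_lists for d in lst]
    metrics = evaluate(dets, gts, num_classes=model.config.num_classes)
    return metrics, history
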