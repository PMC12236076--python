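"""Detection accuracy metrics: precision, recall, AP/mAP, F1, confusion matrix.

Definitions follow the standard detector-evaluation formulas: precision
``TP/(TP+FP)``, recall ``TP/(TP+FN)``, AP as the area under the
precision–recall curve (101-point COCO interpolation by default, continuous
trapezoid as an option), mAP as the mean of per-class APs, and F1 as the
harmonic mean ``2PR/(P+R)``.

Matching is greedy in descending score order, one-to-one per image and class:
a detection claims the unclaimed ground truth of highest IoU above the
threshold; ties break toward higher IoU, then lower detection index.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .losses import pairwise_iou

__all__ = [
    "Detection", "GroundTruth", "DetectionMetrics",
    "average_precision", "evaluate", "confusion_matrix", "f1_score",
]


@dataclass
class Detection:
    """One predicted object: corner-form box, class id, confidence."""

    image_id: str
    class_id: int
    score: float
    box: np.ndarray  # (4,) xyxy

    def __post_init__(self):
        self.box = np.asarray(self.box, dtype=np.float64).reshape(4)
        if not 0.0 <= self.score <= 1.0:
            raise ValueError(f"confidence {self.score} outside [0, 1]")


@dataclass
class GroundTruth:
    image_id: str
    class_id: int
    box: np.ndarray

    def __post_init__(self):
        self.box = np.asarray(self.box, dtype=np.float64).reshape(4)


@dataclass
class DetectionMetrics:
    precision: float
    recall: float
    f1: float
    per_class_ap50: dict
    map50: float
    map50_95: float
    ap_mode: str = "coco101"
    confusion: np.ndarray | None = None


def f1_score(p: float, r: float) -> float:
    if p + r == 0:
        return 0.0
    return 2.0 * p * r / (p + r)


def _match_ranked(dets: list[Detection], gts: list[GroundTruth], iou_thr: float):
    """TP/FP flags for score-ranked detections of a single class.

    Returns (flags, n_gt): flags[i] is True when the i-th ranked detection is
    a true positive at this IoU threshold.

    Score ties break on content (image id, then box coordinates), so the
    ranking — and every derived metric — is invariant to the input order of
    the detection list.
    """
    order = sorted(
        range(len(dets)),
        key=lambda i: (-dets[i].score, dets[i].image_id, tuple(dets[i].box)),
    )
    gts_by_img: dict[str, list[int]] = {}
    for j, g in enumerate(gts):
        gts_by_img.setdefault(g.image_id, []).append(j)
    claimed: set[int] = set()
    flags = np.zeros(len(dets), dtype=bool)
    for rank, i in enumerate(order):
        d = dets[i]
        cand = [j for j in gts_by_img.get(d.image_id, []) if j not in claimed]
        if not cand:
            continue
        ious = pairwise_iou(d.box[None], np.stack([gts[j].box for j in cand]))[0]
        best = int(np.argmax(ious))
        if ious[best] >= iou_thr:
            claimed.add(cand[best])
            flags[rank] = True
    return flags, len(gts)


def average_precision(dets: list[Detection], gts: list[GroundTruth],
                      iou_thr: float = 0.5, mode: str = "coco101") -> float:
    """AP for a single class at one IoU threshold.

    ``mode='coco101'`` integrates max-precision-to-the-right at 101 recall
    points; ``mode='continuous'`` integrates the raw P(R) staircase.
    """
    if not gts:
        return float("nan")
    if not dets:
        return 0.0
    flags, n_gt = _match_ranked(dets, gts, iou_thr)
    if not flags.any():
        return 0.0
    tp = np.cumsum(flags)
    fp = np.cumsum(~flags)
    recall = tp / n_gt
    precision = tp / np.maximum(tp + fp, 1)
    if mode == "coco101":
        # precision envelope sampled at 101 recall points
        mrec = np.concatenate([[0.0], recall, [1.0]])
        mpre = np.concatenate([[1.0], precision, [0.0]])
        mpre = np.maximum.accumulate(mpre[::-1])[::-1]
        rq = np.linspace(0, 1, 101)
        idx = np.searchsorted(mrec, rq, side="left")
        return float(mpre[np.minimum(idx, len(mpre) - 1)].mean())
    if mode == "continuous":
        mrec = np.concatenate([[0.0], recall])
        mpre = np.concatenate([[precision[0] if len(precision) else 0.0], precision])
        mpre = np.maximum.accumulate(mpre[::-1])[::-1]
        return float(np.sum(np.diff(mrec) * mpre[1:]))
    raise ValueError(f"unknown AP mode {mode!r}")


def _best_f1_point(dets: list[Detection], gts: list[GroundTruth], iou_thr: float):
    """(P, R, F1) at the score cut maximizing F1 along the ranked curve."""
    if not gts or not dets:
        return 0.0, 0.0, 0.0
    flags, n_gt = _match_ranked(dets, gts, iou_thr)
    tp = np.cumsum(flags)
    fp = np.cumsum(~flags)
    recall = tp / n_gt
    precision = tp / np.maximum(tp + fp, 1)
    f1 = np.where(precision + recall > 0, 2 * precision * recall
                  / np.maximum(precision + recall, 1e-12), 0.0)
    k = int(np.argmax(f1))
    return float(precision[k]), float(recall[k]), float(f1[k])


def evaluate(dets: list[Detection], gts: list[GroundTruth],
             iou_thresholds=None, num_classes: int = 5,
             ap_mode: str = "coco101") -> DetectionMetrics:
    """Full metric report over a detection / ground-truth pair of lists.

    mAP50:95 averages AP over IoU thresholds 0.5:0.05:0.95; classes with no
    ground truth are excluded from the mean.  P/R/F1 are taken at the
    operating point maximizing F1 at IoU 0.5, macro-averaged over classes.
    """
    if iou_thresholds is None:
        iou_thresholds = np.arange(0.5, 0.96, 0.05)
    by_class_d: dict[int, list[Detection]] = {c: [] for c in range(num_classes)}
    by_class_g: dict[int, list[GroundTruth]] = {c: [] for c in range(num_classes)}
    for d in dets:
        if 0 <= d.class_id < num_classes:
            by_class_d[d.class_id].append(d)
    for g in gts:
        by_class_g[g.class_id].append(g)

    per_class_ap50 = {}
    ap_all = {thr: [] for thr in iou_thresholds}
    prf = []
    for c in range(num_classes):
        if not by_class_g[c]:
            continue
        per_class_ap50[c] = average_precision(by_class_d[c], by_class_g[c], 0.5, ap_mode)
        for thr in iou_thresholds:
            ap_all[thr].append(
                average_precision(by_class_d[c], by_class_g[c], float(thr), ap_mode)
            )
        prf.append(_best_f1_point(by_class_d[c], by_class_g[c], 0.5))
    if not per_class_ap50:
        return DetectionMetrics(0.0, 0.0, 0.0, {}, 0.0, 0.0, ap_mode)
    map50 = float(np.mean(list(per_class_ap50.values())))
    map50_95 = float(np.mean([np.mean(v) for v in ap_all.values()]))
    p = float(np.mean([x[0] for x in prf]))
    r = float(np.mean([x[1] for x in prf]))
    return DetectionMetrics(p, r, f1_score(p, r), per_class_ap50, map50, map50_95,
                            ap_mode)


def confusion_matrix(dets: list[Detection], gts: list[GroundTruth],
                     iou_thr: float = 0.45, conf_thr: float = 0.25,
                     num_classes: int = 5, normalize: bool = False) -> np.ndarray:
    """(num_classes+1)² counts; last row/column is background.

    Entry [i, j] counts ground truths of class j claimed by detections of
    class i; unmatched ground truths land in the background row, unmatched
    detections in the background column.
    """
    n = num_classes + 1
    m = np.zeros((n, n), dtype=np.float64)
    dets = [d for d in dets if d.score >= conf_thr]
    imgs = {d.image_id for d in dets} | {g.image_id for g in gts}
    for img in sorted(imgs):
        di = sorted(
            [d for d in dets if d.image_id == img], key=lambda d: (-d.score,)
        )
        gi = [g for g in gts if g.image_id == img]
        claimed = set()
        matched_det = set()
        for k, d in enumerate(di):
            if not gi:
                break
            ious = pairwise_iou(d.box[None], np.stack([g.box for g in gi]))[0]
            ious = np.where([j in claimed for j in range(len(gi))], -1.0, ious)
            best = int(np.argmax(ious))
            if ious[best] >= iou_thr:
                claimed.add(best)
                matched_det.add(k)
                m[d.class_id, gi[best].class_id] += 1
        for k, d in enumerate(di):
            if k not in matched_det:
                m[d.class_id, num_classes] += 1  # false positive on background
        for j, g in enumerate(gi):
            if j not in claimed:
                m[num_classes, g.class_id] += 1  # missed ground truth
    if normalize:
        col = m.sum(axis=0, keepdims=True)
        m = np.divide(m, col, out=np.zeros_like(m), where=col > 0)
    return m
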