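"""Training-set augmentation: random cropping, rotation, blurring.

All operations transform the annotation boxes consistently with the image;
after cropping, boxes whose visible area falls below a minimum fraction of
their original area are dropped.  Images are uint8 ``(H, W, 3)`` arrays,
records are :class:`~phrfdet.data.annotations.AnnotationRecord`.
"""

from __future__ import annotations

import zlib

import numpy as np
from PIL import Image
from scipy import ndimage

from .annotations import AnnotationRecord

__all__ = ["rotate90", "rotate", "blur", "random_crop", "augment"]

MIN_VISIBLE_FRACTION = 0.3


def _clip_box(cx, cy, w, h):
    """Clip a normalized center-form box to [0,1]; returns None if empty."""
    x1, y1 = max(cx - w / 2, 0.0), max(cy - h / 2, 0.0)
    x2, y2 = min(cx + w / 2, 1.0), min(cy + h / 2, 1.0)
    if x2 - x1 <= 1e-6 or y2 - y1 <= 1e-6:
        return None
    return ((x1 + x2) / 2, (y1 + y2) / 2, x2 - x1, y2 - y1)


def rotate90(image: np.ndarray, records, k: int = 1):
    """Exact rotation by k·90°; (cx,cy,w,h) → (cy, 1−cx, h, w) per turn."""
    out_img = np.rot90(image, k=k % 4, axes=(0, 1)).copy()
    out_rec = []
    for r in records:
        cx, cy, w, h = r.box
        for _ in range(k % 4):
            cx, cy, w, h = cy, 1.0 - cx, h, w
        out_rec.append(AnnotationRecord(r.image_id, r.class_id, (cx, cy, w, h)))
    return out_img, out_rec


def rotate(image: np.ndarray, records, angle_deg: float):
    """Rotation by an arbitrary angle about the image center (no reshape).

    Boxes are mapped by rotating their corners and taking the axis-aligned
    hull, then clipped; fully rotated-out boxes are dropped.
    """
    out_img = ndimage.rotate(image, angle_deg, axes=(1, 0), reshape=False,
                             order=1, mode="nearest")
    t = np.deg2rad(angle_deg)
    rot = np.array([[np.cos(t), -np.sin(t)], [np.sin(t), np.cos(t)]])
    h_img, w_img = image.shape[:2]
    aspect = np.array([w_img, h_img], dtype=np.float64)
    out_rec = []
    for r in records:
        cx, cy, w, h = r.box
        corners = np.array(
            [[cx - w / 2, cy - h / 2], [cx + w / 2, cy - h / 2],
             [cx - w / 2, cy + h / 2], [cx + w / 2, cy + h / 2]]
        )
        pix = (corners - 0.5) * aspect
        new = (pix @ rot.T) / aspect + 0.5
        x1, y1 = new.min(axis=0)
        x2, y2 = new.max(axis=0)
        clipped = _clip_box((x1 + x2) / 2, (y1 + y2) / 2, x2 - x1, y2 - y1)
        if clipped is None:
            continue
        if clipped[2] * clipped[3] < MIN_VISIBLE_FRACTION * w * h:
            continue
        out_rec.append(AnnotationRecord(r.image_id, r.class_id, clipped))
    return out_img, out_rec


def blur(image: np.ndarray, records, sigma: float = 1.0):
    """Gaussian blur; annotations are untouched."""
    out = ndimage.gaussian_filter(image.astype(np.float32),
                                  sigma=(sigma, sigma, 0))
    return np.clip(out, 0, 255).astype(np.uint8), list(records)


def random_crop(image: np.ndarray, records, rng: np.random.Generator,
                scale=(0.6, 1.0), min_visible: float = MIN_VISIBLE_FRACTION):
    """Random sub-window crop, resized back to the original resolution.

    Boxes are re-expressed in crop coordinates and dropped when less than
    ``min_visible`` of their original area survives the crop.
    """
    h_img, w_img = image.shape[:2]
    s = rng.uniform(*scale)
    cw, ch = max(int(w_img * s), 8), max(int(h_img * s), 8)
    x0 = int(rng.integers(0, w_img - cw + 1))
    y0 = int(rng.integers(0, h_img - ch + 1))
    crop = image[y0:y0 + ch, x0:x0 + cw]
    out_img = np.asarray(
        Image.fromarray(crop).resize((w_img, h_img), Image.BILINEAR)
    )
    out_rec = []
    for r in records:
        cx, cy, w, h = r.box
        ncx = (cx * w_img - x0) / cw
        ncy = (cy * h_img - y0) / ch
        nw = w * w_img / cw
        nh = h * h_img / ch
        clipped = _clip_box(ncx, ncy, nw, nh)
        if clipped is None:
            continue
        visible = (clipped[2] * clipped[3]) / (nw * nh)
        if visible < min_visible:
            continue
        out_rec.append(AnnotationRecord(r.image_id, r.class_id, clipped))
    return out_img, out_rec


def augment_split(scenes_by_id: dict, split, multiplier: int = 2,
                  ops=("random_crop", "rotate", "blur"), seed: int = 0) -> dict:
    """Expand the *training* partition of a split by augmentation.

    ``scenes_by_id`` maps image id to ``(image, records)``; ``split`` is a
    :class:`~phrfdet.data.splits.DatasetSplit`.  Only ids in ``split.train``
    are augmented — partitioning precedes augmentation, so no derived image
    can leak into validation or test.  Augmented entries carry a provenance
    id ``"<source>#aug<k>"``.

    Returns ``{"train": [...], "val": [...], "test": [...]}`` of
    ``(id, image, records)`` triples.
    """
    out = {"train": [], "val": [], "test": []}
    for name in ("val", "test"):
        for i in getattr(split, name):
            img, recs = scenes_by_id[i]
            out[name].append((i, img, recs))
    for i in split.train:
        img, recs = scenes_by_id[i]
        out["train"].append((i, img, recs))
        for k in range(multiplier - 1):
            # stable per-(image, copy) sub-seed; string hash() is salted
            sub = zlib.crc32(f"{i}:{k}:{seed}".encode()) & 0x7FFFFFFF
            aug_img, aug_recs = augment(img, recs, ops=ops, seed=sub)
            out["train"].append((f"{i}#aug{k}", aug_img, aug_recs))
    return out


def augment(image: np.ndarray, records, ops=("random_crop", "rotate", "blur"),
            seed: int = 0):
    """Seeded augmentation chain over the requested operation set."""
    rng = np.random.default_rng(seed)
    img, rec = image, list(records)
    if "random_crop" in ops and rng.random() < 0.8:
        img, rec = random_crop(img, rec, rng)
    if "rotate" in ops:
        if rng.random() < 0.5:
            img, rec = rotate90(img, rec, k=int(rng.integers(1, 4)))
        else:
            img, rec = rotate(img, rec, float(rng.uniform(-25, 25)))
    if "blur" in ops and rng.random() < 0.5:
        img, rec = blur(img, rec, sigma=float(rng.uniform(0.5, 2.0)))
    return img, rec
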