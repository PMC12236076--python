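"""Seeded procedural generator of weed-like field scenes.

The generator emulates the statistical shape of near-ground weed photographs
— a textured soil background with five visually distinct plant classes in
single-target, multi-target, and mutual-occlusion layouts — without
attempting photo-realism.  Each plant is a rosette of elliptical lobes whose
count, elongation and hue are class-specific, so a trivial colour/shape
classifier can separate the classes and a detector has a learnable signal.
Output is deterministic per (spec, seed): a uint8 RGB image plus tight-box
annotation records.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .annotations import AnnotationRecord

__all__ = ["SceneSpec", "ClassStyle", "generate_scene", "generate_dataset"]


@dataclass
class ClassStyle:
    """Visual parameters of one weed class."""

    n_lobes: int
    elongation: float
    rgb: tuple
    center_dark: float = 0.55


# rosette morphology and hue per class, ordered by class id:
# beggartick, crabgrass, galinsoga_quadriradiata, goosegrass, tropic ageratum
DEFAULT_STYLES = (
    ClassStyle(5, 2.2, (45, 95, 40)),
    ClassStyle(7, 5.0, (100, 145, 50)),
    ClassStyle(4, 1.3, (60, 130, 65)),
    ClassStyle(9, 6.5, (135, 155, 95)),
    ClassStyle(6, 1.1, (70, 110, 100)),
)

SOIL_RGB = (118, 92, 66)


@dataclass
class SceneSpec:
    image_size: int = 640
    n_targets: int = 3
    occlusion: bool = False
    seed: int = 0
    classes: tuple = tuple(range(5))
    radius_range: tuple = (0.10, 0.18)  # plant radius as fraction of image
    styles: tuple = DEFAULT_STYLES

    def __post_init__(self):
        if self.n_targets < 1:
            raise ValueError("n_targets must be >= 1")
        max_pack = int(2.5 / (np.pi * self.radius_range[0] ** 2))
        if self.n_targets > max_pack:
            raise ValueError(
                f"{self.n_targets} targets cannot be packed at radius "
                f">= {self.radius_range[0]}"
            )


def _soil(size: int, rng: np.random.Generator) -> np.ndarray:
    base = np.array(SOIL_RGB, dtype=np.float32)
    img = np.ones((size, size, 3), dtype=np.float32) * base
    # low-frequency moisture blotches + fine grain
    blotch = ndimage.gaussian_filter(rng.standard_normal((size, size)),
                                     sigma=size / 16)
    blotch = blotch / (np.abs(blotch).max() + 1e-9)
    grain = rng.standard_normal((size, size)) * 0.06
    gain = 1.0 + 0.18 * blotch + grain
    img *= gain[..., None]
    return img


def _plant_mask(size: int, cx: float, cy: float, radius: float,
                style: ClassStyle, rng: np.random.Generator) -> np.ndarray:
    """Boolean rosette mask on the full image grid."""
    yy, xx = np.mgrid[0:size, 0:size].astype(np.float32)
    xx = xx - cx * size
    yy = yy - cy * size
    mask = np.zeros((size, size), dtype=bool)
    r_pix = radius * size
    phase = rng.uniform(0, 2 * np.pi)
    for k in range(style.n_lobes):
        theta = phase + 2 * np.pi * k / style.n_lobes + rng.normal(0, 0.12)
        lc = 0.55 * r_pix
        a = 0.52 * r_pix * rng.uniform(0.85, 1.15)       # along-lobe semi-axis
        b = max(a / style.elongation, 1.5)               # across-lobe
        ox = xx - lc * np.cos(theta)
        oy = yy - lc * np.sin(theta)
        u = ox * np.cos(theta) + oy * np.sin(theta)
        v = -ox * np.sin(theta) + oy * np.cos(theta)
        mask |= (u / a) ** 2 + (v / b) ** 2 <= 1.0
    return mask


def generate_scene(spec: SceneSpec):
    """Render one scene; returns (uint8 RGB image, annotation records)."""
    rng = np.random.default_rng(spec.seed)
    size = spec.image_size
    img = _soil(size, rng)
    records = []
    centers = []
    margin = spec.radius_range[1]
    image_id = f"scene_{spec.seed:06d}"
    for i in range(spec.n_targets):
        radius = rng.uniform(*spec.radius_range)
        if spec.occlusion and i == 1:
            # guarantee at least one overlapping pair
            px, py, pr = centers[0]
            d = 0.55 * (pr + radius)
            ang = rng.uniform(0, 2 * np.pi)
            cx = float(np.clip(px + d * np.cos(ang), margin, 1 - margin))
            cy = float(np.clip(py + d * np.sin(ang), margin, 1 - margin))
        else:
            for _ in range(200):
                cx = rng.uniform(margin, 1 - margin)
                cy = rng.uniform(margin, 1 - margin)
                if spec.occlusion or all(
                    (cx - x) ** 2 + (cy - y) ** 2 > (0.9 * (radius + r)) ** 2
                    for x, y, r in centers
                ):
                    break
        centers.append((cx, cy, radius))
        cls = int(rng.choice(spec.classes))
        style = spec.styles[cls]
        mask = _plant_mask(size, cx, cy, radius, style, rng)
        if not mask.any():
            continue
        # colour the plant: class hue, darker center, per-pixel lighting
        yy, xx = np.nonzero(mask)
        dist = np.sqrt((xx - cx * size) ** 2 + (yy - cy * size) ** 2)
        dist = dist / (dist.max() + 1e-9)
        shade = style.center_dark + (1 - style.center_dark) * dist
        light = 1.0 + 0.2 * rng.standard_normal(len(xx))
        colour = np.array(style.rgb, dtype=np.float32)
        img[yy, xx] = colour * (shade * light)[:, None]
        x1, x2 = xx.min() / size, (xx.max() + 1) / size
        y1, y2 = yy.min() / size, (yy.max() + 1) / size
        records.append(
            AnnotationRecord(image_id, cls,
                             ((x1 + x2) / 2, (y1 + y2) / 2, x2 - x1, y2 - y1))
        )
    gain = rng.uniform(0.8, 1.2)  # global illumination jitter
    out = np.clip(img * gain, 0, 255).astype(np.uint8)
    return out, records


def generate_dataset(n: int, scenario: str = "multi", seed: int = 0,
                     image_size: int = 640):
    """A list of (image, records) scenes for one scenario preset.

    Scenarios mirror the field layouts: ``single`` (one plant), ``multi``
    (a small community), ``occlusion`` (guaranteed overlapping pair).
    """
    rng = np.random.default_rng(seed)
    scenes = []
    for i in range(n):
        sub = int(rng.integers(0, 2**31 - 1))
        if scenario == "single":
            spec = SceneSpec(image_size, 1, False, sub)
        elif scenario == "multi":
            spec = SceneSpec(image_size, int(rng.integers(2, 5)), False, sub)
        elif scenario == "occlusion":
            spec = SceneSpec(image_size, int(rng.integers(2, 4)), True, sub)
        else:
            raise ValueError(f"unknown scenario {scenario!r}")
        scenes.append(generate_scene(spec))
    return scenes
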