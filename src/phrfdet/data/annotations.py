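"""Annotation records and the YOLO-text ↔ VOC-XML round trip.

A record stores one labelled object: a class id (0–4, the five upland-rice
weed species) and a normalized center-form box ``(cx, cy, w, h)`` in
``[0,1]``.  The text format holds one ``class cx cy w h`` line per object;
the XML format names classes with words and stores pixel corner coordinates
(top-left and bottom-right, 0-based), so the two round-trip losslessly up to
pixel rounding.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
from lxml import etree

__all__ = ["AnnotationRecord", "CLASS_NAMES", "read_yolo_txt", "write_yolo_txt",
           "to_voc_xml", "from_voc_xml"]

CLASS_NAMES = ("beggartick", "crabgrass", "galinsoga_quadriradiata",
               "goosegrass", "tropic_ageratum_herb")


@dataclass
class AnnotationRecord:
    image_id: str
    class_id: int
    box: tuple  # (cx, cy, w, h), normalized

    def __post_init__(self):
        cx, cy, w, h = self.box
        self.box = (float(cx), float(cy), float(w), float(h))
        if not 0 <= self.class_id < len(CLASS_NAMES):
            raise ValueError(f"class id {self.class_id} outside 0..{len(CLASS_NAMES)-1}")
        if w < 0 or h < 0:
            raise ValueError(f"negative box size {(w, h)}")
        for lo, hi in ((cx - w / 2, cx + w / 2), (cy - h / 2, cy + h / 2)):
            if lo < -1e-6 or hi > 1 + 1e-6:
                raise ValueError(f"box {self.box} extends outside [0,1]")

    @property
    def xyxy(self) -> tuple:
        """Normalized corner form."""
        cx, cy, w, h = self.box
        return (cx - w / 2, cy - h / 2, cx + w / 2, cy + h / 2)

    def pixel_corners(self, width: int, height: int) -> tuple:
        x1, y1, x2, y2 = self.xyxy
        return (int(round(x1 * width)), int(round(y1 * height)),
                int(round(x2 * width)), int(round(y2 * height)))


def read_yolo_txt(path) -> list[AnnotationRecord]:
    """Parse one record per ``class cx cy w h`` line; malformed lines raise
    with their line number."""
    path = Path(path)
    image_id = path.stem
    records = []
    for ln, line in enumerate(path.read_text().splitlines(), start=1):
        line = line.strip()
        if not line:
            continue
        parts = line.split()
        if len(parts) != 5:
            raise ValueError(f"{path}:{ln}: expected 5 fields, got {len(parts)}")
        try:
            cls = int(parts[0])
            vals = tuple(float(p) for p in parts[1:])
        except ValueError as e:
            raise ValueError(f"{path}:{ln}: {e}") from None
        try:
            records.append(AnnotationRecord(image_id, cls, vals))
        except ValueError as e:
            raise ValueError(f"{path}:{ln}: {e}") from None
    return records


def write_yolo_txt(records, path, precision: int = 6) -> None:
    lines = [
        f"{r.class_id} " + " ".join(f"{v:.{precision}f}" for v in r.box)
        for r in records
    ]
    Path(path).write_text("\n".join(lines) + ("\n" if lines else ""))


def to_voc_xml(records, image_size, image_name: str | None = None) -> bytes:
    """Serialize records as a VOC-style XML document (pixel corner boxes)."""
    width, height = image_size
    root = etree.Element("annotation")
    etree.SubElement(root, "filename").text = (
        image_name or (records[0].image_id if records else "image")
    )
    size = etree.SubElement(root, "size")
    etree.SubElement(size, "width").text = str(width)
    etree.SubElement(size, "height").text = str(height)
    etree.SubElement(size, "depth").text = "3"
    for r in records:
        if not 0 <= r.class_id < len(CLASS_NAMES):
            raise ValueError(f"unknown class id {r.class_id}")
        obj = etree.SubElement(root, "object")
        etree.SubElement(obj, "name").text = CLASS_NAMES[r.class_id]
        box = etree.SubElement(obj, "bndbox")
        x1, y1, x2, y2 = r.pixel_corners(width, height)
        etree.SubElement(box, "xmin").text = str(x1)
        etree.SubElement(box, "ymin").text = str(y1)
        etree.SubElement(box, "xmax").text = str(x2)
        etree.SubElement(box, "ymax").text = str(y2)
    return etree.tostring(root, pretty_print=True)


def from_voc_xml(source) -> tuple[list[AnnotationRecord], tuple]:
    """Inverse of :func:`to_voc_xml`; returns (records, (width, height))."""
    if isinstance(source, (str, Path)) and Path(str(source)).exists():
        tree = etree.parse(str(source))
        root = tree.getroot()
    else:
        root = etree.fromstring(source)
    width = int(root.findtext("size/width"))
    height = int(root.findtext("size/height"))
    image_id = Path(root.findtext("filename") or "image").stem
    name_to_id = {n: i for i, n in enumerate(CLASS_NAMES)}
    records = []
    for obj in root.findall("object"):
        name = obj.findtext("name")
        if name not in name_to_id:
            raise ValueError(f"unknown class name {name!r}")
        x1 = float(obj.findtext("bndbox/xmin"))
        y1 = float(obj.findtext("bndbox/ymin"))
        x2 = float(obj.findtext("bndbox/xmax"))
        y2 = float(obj.findtext("bndbox/ymax"))
        box = ((x1 + x2) / 2 / width, (y1 + y2) / 2 / height,
               (x2 - x1) / width, (y2 - y1) / height)
        records.append(AnnotationRecord(image_id, name_to_id[name], box))
    return records, (width, height)
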