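"""Domain types and annotation I/O for wheat-ear bounding boxes.

Three dialects are supported:

* ``gw_csv`` — Global-Wheat-style CSV with columns ``image_id, width,
  height, bbox, source`` where ``bbox`` is a bracketed 4-float list
  ``"[xmin, ymin, w, h]"``.
* ``coco_json`` — COCO detection JSON (``images`` / ``annotations`` /
  ``categories``; bbox = ``[x, y, w, h]``).
* ``voc_xml`` — Pascal VOC XML, one file per image, with 1-based inclusive
  ``xmin/ymin/xmax/ymax`` corners (converted on read).

Internally all coordinates use the COCO convention: 0-based, half-open
``[xmin, xmin + width)`` with x = column, y = row and the origin at the
top-left pixel.  Boxes extending past the declared image bounds are clipped
on read; boxes with no remaining area are dropped with a logged warning.
"""

from __future__ import annotations

import json
import logging
import re
import xml.etree.ElementTree as ET
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

DIALECTS = ("gw_csv", "coco_json", "voc_xml")

GW_CSV_COLUMNS = ["image_id", "width", "height", "bbox", "source"]


class AnnotationError(ValueError):
    """Raised when an annotation file cannot be parsed."""


@dataclass
class BoundingBox:
    """Axis-aligned box in pixel coordinates, 0-based half-open.

    ``confidence`` is only present on detections; ground-truth boxes carry
    ``None`` (never a defaulted 1.0).
    """

    xmin: float
    ymin: float
    width: float
    height: float
    confidence: float | None = None
    label: str | None = None

    def __post_init__(self) -> None:
        if not (self.width > 0 and self.height > 0):
            raise ValueError(f"box must have positive size, got {self.width}x{self.height}")
        if self.xmin < 0 or self.ymin < 0:
            raise ValueError(f"box origin must be non-negative, got ({self.xmin}, {self.ymin})")
        if self.confidence is not None and not (0.0 <= self.confidence <= 1.0):
            raise ValueError(f"confidence must lie in [0, 1], got {self.confidence}")

    @property
    def xmax(self) -> float:
        return self.xmin + self.width

    @property
    def ymax(self) -> float:
        return self.ymin + self.height

    @property
    def area(self) -> float:
        return self.width * self.height

    def clipped(self, rows: int, cols: int) -> "BoundingBox | None":
        """Clip to an image grid; ``None`` when nothing remains."""
        x0 = max(self.xmin, 0.0)
        y0 = max(self.ymin, 0.0)
        x1 = min(self.xmax, float(cols))
        y1 = min(self.ymax, float(rows))
        if x1 <= x0 or y1 <= y0:
            return None
        return replace(self, xmin=x0, ymin=y0, width=x1 - x0, height=y1 - y0)

    def as_tuple(self) -> tuple[float, float, float, float]:
        return (self.xmin, self.ymin, self.width, self.height)


@dataclass
class AnnotatedImage:
    """An image (or a descriptor of one) plus its ground-truth boxes.

    ``pixels`` may be ``None`` when only the annotation record is known
    (annotation files carry sizes, not rasters); ``shape`` is always the
    (rows, cols) pixel-grid size and every box lies inside it.
    """

    image_id: str
    shape: tuple[int, int]
    boxes: list[BoundingBox] = field(default_factory=list)
    pixels: np.ndarray | None = None

    def __post_init__(self) -> None:
        rows, cols = self.shape
        if rows <= 0 or cols <= 0:
            raise ValueError(f"image shape must be positive, got {self.shape}")
        if self.pixels is not None:
            if self.pixels.shape != (rows, cols, 3):
                raise ValueError(
                    f"pixels shape {self.pixels.shape} does not match declared {(rows, cols, 3)}"
                )
            if self.pixels.dtype != np.uint8:
                raise ValueError("pixels must be uint8 RGB")

    @property
    def n_boxes(self) -> int:
        return len(self.boxes)


@dataclass
class DetectionSet:
    """Scored detections for one image; sorted by descending confidence."""

    image_id: str
    boxes: list[BoundingBox] = field(default_factory=list)

    def __post_init__(self) -> None:
        for b in self.boxes:
            if b.confidence is None:
                raise ValueError("every detection needs a confidence")

    def sorted(self) -> "DetectionSet":
        """Descending confidence; ties broken by larger area, then input order."""
        order = sorted(
            range(len(self.boxes)),
            key=lambda i: (-self.boxes[i].confidence, -self.boxes[i].area, i),
        )
        return DetectionSet(self.image_id, [self.boxes[i] for i in order])


# ---------------------------------------------------------------------------
# reading


def _clip_boxes(image_id: str, shape: tuple[int, int], boxes: Iterable[BoundingBox]) -> list[BoundingBox]:
    rows, cols = shape
    kept: list[BoundingBox] = []
    for b in boxes:
        c = b.clipped(rows, cols)
        if c is None:
            logger.warning("dropping zero-area box %s in image %s after clipping", b.as_tuple(), image_id)
        else:
            kept.append(c)
    return kept


_BBOX_CELL = re.compile(r"[-+0-9.eE]+")


def parse_gw_bbox(cell: str) -> tuple[float, float, float, float]:
    """Parse a Global-Wheat bbox cell like ``"[977.0, 73.0, 130.0, 58.0]"``.

    Tolerant of extra whitespace and of integer-valued entries.
    """
    nums = _BBOX_CELL.findall(str(cell))
    if len(nums) != 4:
        raise AnnotationError(f"bbox cell {cell!r} does not contain 4 numbers")
    x, y, w, h = (float(v) for v in nums)
    return x, y, w, h


def _read_gw_csv(path: Path) -> list[AnnotatedImage]:
    try:
        df = pd.read_csv(path)
    except Exception as exc:  # noqa: BLE001 - re-raise with file context
        raise AnnotationError(f"{path}: cannot parse as gw_csv: {exc}") from exc
    required = {"image_id", "width", "height"}
    if not required.issubset(df.columns):
        raise AnnotationError(f"{path}: gw_csv needs columns {sorted(required)}, found {list(df.columns)}")
    images: dict[str, AnnotatedImage] = {}
    for idx, row in df.iterrows():
        image_id = str(row["image_id"])
        shape = (int(row["height"]), int(row["width"]))
        if image_id not in images:
            images[image_id] = AnnotatedImage(image_id, shape)
        elif images[image_id].shape != shape:
            raise AnnotationError(f"{path}: record {idx}: conflicting sizes for image {image_id}")
        cell = row.get("bbox")
        if cell is None or (isinstance(cell, float) and np.isnan(cell)) or str(cell).strip() in ("", "[]"):
            continue  # image declared with no boxes
        try:
            x, y, w, h = parse_gw_bbox(cell)
            box = BoundingBox(max(x, 0.0), max(y, 0.0), w, h)
        except (AnnotationError, ValueError) as exc:
            raise AnnotationError(f"{path}: record {idx}: {exc}") from exc
        images[image_id].boxes.extend(_clip_boxes(image_id, shape, [box]))
    return list(images.values())


def _read_coco_json(path: Path) -> list[AnnotatedImage]:
    try:
        blob = json.loads(path.read_text())
    except json.JSONDecodeError as exc:
        raise AnnotationError(f"{path}: invalid JSON at line {exc.lineno}: {exc.msg}") from exc
    if not isinstance(blob, dict) or "images" not in blob:
        raise AnnotationError(f"{path}: not a COCO annotation file (missing 'images')")
    images: dict[object, AnnotatedImage] = {}
    for rec in blob.get("images", []):
        image_id = str(rec.get("file_name", rec["id"]))
        images[rec["id"]] = AnnotatedImage(image_id, (int(rec["height"]), int(rec["width"])))
    for i, ann in enumerate(blob.get("annotations", [])):
        if ann["image_id"] not in images:
            raise AnnotationError(f"{path}: annotation {i} references unknown image id {ann['image_id']}")
        img = images[ann["image_id"]]
        x, y, w, h = (float(v) for v in ann["bbox"])
        try:
            box = BoundingBox(max(x, 0.0), max(y, 0.0), w, h, confidence=ann.get("score"))
        except ValueError as exc:
            raise AnnotationError(f"{path}: annotation {i}: {exc}") from exc
        img.boxes.extend(_clip_boxes(img.image_id, img.shape, [box]))
    return list(images.values())


def _read_voc_xml(path: Path) -> list[AnnotatedImage]:
    paths = sorted(path.glob("*.xml")) if path.is_dir() else [path]
    if not paths:
        raise AnnotationError(f"{path}: no VOC XML files found")
    out = []
    for p in paths:
        try:
            root = ET.parse(p).getroot()
        except ET.ParseError as exc:
            raise AnnotationError(f"{p}: invalid XML: {exc}") from exc
        image_id = root.findtext("filename") or p.stem
        size = root.find("size")
        if size is None:
            raise AnnotationError(f"{p}: missing <size> element")
        shape = (int(float(size.findtext("height"))), int(float(size.findtext("width"))))
        img = AnnotatedImage(image_id, shape)
        for obj in root.iter("object"):
            bb = obj.find("bndbox")
            if bb is None:
                raise AnnotationError(f"{p}: <object> without <bndbox>")
            # VOC corners are 1-based inclusive
            xmin = float(bb.findtext("xmin")) - 1.0
            ymin = float(bb.findtext("ymin")) - 1.0
            xmax = float(bb.findtext("xmax"))
            ymax = float(bb.findtext("ymax"))
            box = BoundingBox(max(xmin, 0.0), max(ymin, 0.0), xmax - max(xmin, 0.0),
                              ymax - max(ymin, 0.0), label=obj.findtext("name"))
            img.boxes.extend(_clip_boxes(image_id, shape, [box]))
        out.append(img)
    return out


def read_annotations(path: str | Path, dialect: str) -> list[AnnotatedImage]:
    """Read annotations under one of the supported dialects.

    Returns one :class:`AnnotatedImage` descriptor per image (pixels not
    loaded).  Boxes are clipped to the declared image bounds; boxes left
    with zero area are dropped with a warning.
    """
    path = Path(path)
    if dialect == "gw_csv":
        return _read_gw_csv(path)
    if dialect == "coco_json":
        return _read_coco_json(path)
    if dialect == "voc_xml":
        return _read_voc_xml(path)
    raise ValueError(f"unknown dialect {dialect!r}; expected one of {DIALECTS}")


# ---------------------------------------------------------------------------
# writing


def _fmt(v: float) -> str:
    return repr(float(v))


def _write_gw_csv(images: Sequence[AnnotatedImage], path: Path) -> None:
    rows = []
    for img in images:
        if not img.boxes:
            rows.append({"image_id": img.image_id, "width": img.shape[1],
                         "height": img.shape[0], "bbox": "[]", "source": "wheatear"})
        for b in img.boxes:
            cell = f"[{_fmt(b.xmin)}, {_fmt(b.ymin)}, {_fmt(b.width)}, {_fmt(b.height)}]"
            rows.append({"image_id": img.image_id, "width": img.shape[1],
                         "height": img.shape[0], "bbox": cell, "source": "wheatear"})
    pd.DataFrame(rows, columns=GW_CSV_COLUMNS).to_csv(path, index=False)


def _write_coco_json(images: Sequence[AnnotatedImage], path: Path) -> None:
    blob = {
        "images": [
            {"id": i, "file_name": img.image_id, "width": img.shape[1], "height": img.shape[0]}
            for i, img in enumerate(images)
        ],
        "annotations": [],
        "categories": [{"id": 1, "name": "wheat ear"}],
    }
    k = 0
    for i, img in enumerate(images):
        for b in img.boxes:
            ann = {"id": k, "image_id": i, "category_id": 1,
                   "bbox": [b.xmin, b.ymin, b.width, b.height], "area": b.area, "iscrowd": 0}
            if b.confidence is not None:
                ann["score"] = b.confidence
            blob["annotations"].append(ann)
            k += 1
    path.write_text(json.dumps(blob, indent=1))


def _write_voc_xml(images: Sequence[AnnotatedImage], path: Path) -> None:
    path.mkdir(parents=True, exist_ok=True)
    for img in images:
        root = ET.Element("annotation")
        ET.SubElement(root, "filename").text = img.image_id
        size = ET.SubElement(root, "size")
        ET.SubElement(size, "width").text = str(img.shape[1])
        ET.SubElement(size, "height").text = str(img.shape[0])
        ET.SubElement(size, "depth").text = "3"
        for b in img.boxes:
            obj = ET.SubElement(root, "object")
            ET.SubElement(obj, "name").text = b.label or "wheat ear"
            bb = ET.SubElement(obj, "bndbox")
            ET.SubElement(bb, "xmin").text = _fmt(b.xmin + 1.0)
            ET.SubElement(bb, "ymin").text = _fmt(b.ymin + 1.0)
            ET.SubElement(bb, "xmax").text = _fmt(b.xmax)
            ET.SubElement(bb, "ymax").text = _fmt(b.ymax)
        stem = Path(img.image_id).stem
        ET.ElementTree(root).write(path / f"{stem}.xml")


def write_annotations(images: Sequence[AnnotatedImage], path: str | Path, dialect: str) -> None:
    """Write annotations so that :func:`read_annotations` round-trips exactly.

    For ``voc_xml`` the path is a directory (one XML file per image).
    """
    path = Path(path)
    if dialect == "gw_csv":
        _write_gw_csv(images, path)
    elif dialect == "coco_json":
        _write_coco_json(images, path)
    elif dialect == "voc_xml":
        _write_voc_xml(images, path)
    else:
        raise ValueError(f"unknown dialect {dialect!r}; expected one of {DIALECTS}")


# ---------------------------------------------------------------------------
# detection result files (COCO results JSON / gw-csv + score column)


def write_detections(dets: Sequence[DetectionSet], path: str | Path, dialect: str = "coco_json") -> None:
    """Write detection results: COCO results JSON or gw-style CSV with score."""
    path = Path(path)
    if dialect == "coco_json":
        recs = [
            {"image_id": d.image_id, "bbox": [b.xmin, b.ymin, b.width, b.height], "score": b.confidence}
            for d in dets
            for b in d.boxes
        ]
        path.write_text(json.dumps(recs, indent=1))
    elif dialect == "gw_csv":
        rows = [
            {"image_id": d.image_id,
             "bbox": f"[{_fmt(b.xmin)}, {_fmt(b.ymin)}, {_fmt(b.width)}, {_fmt(b.height)}]",
             "score": b.confidence}
            for d in dets
            for b in d.boxes
        ]
        pd.DataFrame(rows, columns=["image_id", "bbox", "score"]).to_csv(path, index=False)
    else:
        raise ValueError(f"unsupported detection dialect {dialect!r}")


def read_detections(path: str | Path, dialect: str = "coco_json") -> list[DetectionSet]:
    path = Path(path)
    per_image: dict[str, list[BoundingBox]] = {}
    if dialect == "coco_json":
        try:
            recs = json.loads(path.read_text())
        except json.JSONDecodeError as exc:
            raise AnnotationError(f"{path}: invalid JSON: {exc}") from exc
        for i, rec in enumerate(recs):
            try:
                x, y, w, h = (float(v) for v in rec["bbox"])
                box = BoundingBox(x, y, w, h, confidence=float(rec["score"]))
            except (KeyError, ValueError) as exc:
                raise AnnotationError(f"{path}: record {i}: {exc}") from exc
            per_image.setdefault(str(rec["image_id"]), []).append(box)
    elif dialect == "gw_csv":
        df = pd.read_csv(path)
        for i, row in df.iterrows():
            x, y, w, h = parse_gw_bbox(row["bbox"])
            per_image.setdefault(str(row["image_id"]), []).append(
                BoundingBox(x, y, w, h, confidence=float(row["score"]))
            )
    else:
        raise ValueError(f"unsupported detection dialect {dialect!r}")
    return [DetectionSet(image_id, boxes).sorted() for image_id, boxes in per_image.items()]
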