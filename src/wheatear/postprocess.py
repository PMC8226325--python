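"""Detection post-processing: confidence filtering and greedy NMS.

An anchor-based detector emits many overlapping candidate boxes per ear.
The pipeline keeps candidates whose confidence is strictly above the
threshold (default 0.5), then removes duplicates by greedy non-maximum
suppression: accept the highest-confidence box, delete every remaining box
whose IoU with it is strictly above the IoU threshold, repeat.  Confidence
ties are broken by larger area, then input order, so results are
deterministic.  Single class ("wheat ear"), per-image only.
"""

from __future__ import annotations

from dataclasses import dataclass

from .annotations import BoundingBox, DetectionSet


@dataclass
class NMSConfig:
    confidence_threshold: float = 0.5
    iou_threshold: float = 0.5

    def __post_init__(self) -> None:
        for name in ("confidence_threshold", "iou_threshold"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must lie in [0, 1], got {v}")


def iou(a: BoundingBox, b: BoundingBox) -> float:
    """Intersection over union of two half-open boxes; symmetric, in [0, 1]."""
    ix = min(a.xmax, b.xmax) - max(a.xmin, b.xmin)
    iy = min(a.ymax, b.ymax) - max(a.ymin, b.ymin)
    if ix <= 0 or iy <= 0:
        return 0.0
    inter = ix * iy
    return inter / (a.area + b.area - inter)


def confidence_filter(dets: DetectionSet, threshold: float = 0.5) -> DetectionSet:
    """Keep boxes with confidence strictly above ``threshold``, sorted."""
    kept = [b for b in dets.boxes if b.confidence > threshold]
    return DetectionSet(dets.image_id, kept).sorted()


def nms(dets: DetectionSet, config: NMSConfig | None = None) -> DetectionSet:
    """Confidence filter followed by greedy descending-confidence NMS."""
    config = config or NMSConfig()
    pool = confidence_filter(dets, config.confidence_threshold).boxes
    survivors: list[BoundingBox] = []
    while pool:
        best = pool.pop(0)  # pool is sorted: head is the current maximum
        survivors.append(best)
        pool = [b for b in pool if iou(best, b) <= config.iou_threshold]
    return DetectionSet(dets.image_id, survivors)
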