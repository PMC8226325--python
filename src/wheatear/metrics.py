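"""Counting evaluation: accuracy P, false-detection rate O, FPS.

For one evaluation over truth boxes and detections:

    P = N_cor / N_real        (counting accuracy)
    O = N_err / N_num         (false-detection rate)

where N_real is the number of ground-truth ears, N_num the number of
detections, N_cor the detections matched one-to-one to a truth box and
N_err = N_num - N_cor.  "Correct" is operationalized the standard
detection-benchmark way: walk detections in descending confidence and match
each to its best-IoU still-unmatched truth box when that IoU >= the matching
threshold (inclusive, default 0.5; note NMS uses strict >).  Zero
denominators yield ``None`` rather than 0 — an evaluation with no truth or
no detections is undefined, not perfect.

Throughput is reported as FPS = 1 / T with T the mean per-image inference
time; it is hardware-dependent and never asserted against.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

from .annotations import AnnotatedImage, BoundingBox, DetectionSet
from .postprocess import iou

MATCH_IOU_DEFAULT = 0.5


@dataclass
class MatchResult:
    """One-to-one pairing of detections to truth boxes."""

    pairs: list[tuple[int, int]]        # (detection index, truth index)
    unmatched_detections: list[int]
    unmatched_truth: list[int]


@dataclass
class CountReport:
    """Counting outcome of one evaluation; see module docstring for P and O."""

    n_cor: int
    n_err: int
    n_real: int
    n_num: int

    def __post_init__(self) -> None:
        if self.n_cor + self.n_err != self.n_num:
            raise ValueError("n_cor + n_err must equal n_num")
        if self.n_cor > self.n_real:
            raise ValueError("cannot match more detections than truth boxes")

    @property
    def p(self) -> float | None:
        """Counting accuracy N_cor / N_real; None when no truth boxes."""
        return self.n_cor / self.n_real if self.n_real > 0 else None

    @property
    def o(self) -> float | None:
        """False-detection rate N_err / N_num; None when no detections."""
        return self.n_err / self.n_num if self.n_num > 0 else None

    @property
    def missed(self) -> int:
        return self.n_real - self.n_cor

    @property
    def missed_rate(self) -> float | None:
        return self.missed / self.n_real if self.n_real > 0 else None

    def to_dict(self) -> dict:
        return {"n_cor": self.n_cor, "n_err": self.n_err, "n_real": self.n_real,
                "n_num": self.n_num, "p": self.p, "o": self.o,
                "missed": self.missed, "missed_rate": self.missed_rate}


@dataclass
class TimingReport:
    t_per_image: float  # seconds

    @property
    def fps(self) -> float:
        return 1.0 / self.t_per_image


def match_detections(truth: Sequence[BoundingBox], dets: DetectionSet,
                     iou_threshold: float = MATCH_IOU_DEFAULT) -> MatchResult:
    """Greedy one-to-one matching in descending confidence order."""
    ordered = dets.sorted()
    # indices back into the caller's order
    order = sorted(range(len(dets.boxes)),
                   key=lambda i: (-dets.boxes[i].confidence, -dets.boxes[i].area, i))
    matched_truth: set[int] = set()
    pairs: list[tuple[int, int]] = []
    unmatched: list[int] = []
    for det_idx, box in zip(order, ordered.boxes):
        best_j, best_iou = -1, 0.0
        for j, t in enumerate(truth):
            if j in matched_truth:
                continue
            v = iou(box, t)
            if v > best_iou:
                best_j, best_iou = j, v
        if best_j >= 0 and best_iou >= iou_threshold:
            matched_truth.add(best_j)
            pairs.append((det_idx, best_j))
        else:
            unmatched.append(det_idx)
    unmatched_truth = [j for j in range(len(truth)) if j not in matched_truth]
    return MatchResult(pairs, unmatched, unmatched_truth)


def count_report(truth: Sequence[BoundingBox], dets: DetectionSet,
                 iou_threshold: float = MATCH_IOU_DEFAULT) -> CountReport:
    """Evaluate counting accuracy and false-detection rate for one image."""
    m = match_detections(truth, dets, iou_threshold)
    n_cor = len(m.pairs)
    n_num = len(dets.boxes)
    return CountReport(n_cor=n_cor, n_err=n_num - n_cor, n_real=len(truth), n_num=n_num)


def pooled_count_report(truths: Sequence[Sequence[BoundingBox]],
                        dets: Sequence[DetectionSet],
                        iou_threshold: float = MATCH_IOU_DEFAULT) -> CountReport:
    """Pool counts over many images before forming P and O (default mode).

    Per-image averaging is available by mapping :func:`count_report` over
    images and averaging the defined ratios.
    """
    if len(truths) != len(dets):
        raise ValueError("need one detection set per truth list")
    reports = [count_report(t, d, iou_threshold) for t, d in zip(truths, dets)]
    return CountReport(n_cor=sum(r.n_cor for r in reports),
                       n_err=sum(r.n_err for r in reports),
                       n_real=sum(r.n_real for r in reports),
                       n_num=sum(r.n_num for r in reports))


def stratified_missed_rate(truth: Sequence[AnnotatedImage],
                           dets: Mapping[str, DetectionSet],
                           strata: Mapping[str, str],
                           iou_threshold: float = MATCH_IOU_DEFAULT) -> dict[str, float | None]:
    """Missed-detection rate per occlusion stratum.

    ``strata`` maps every image id to a caller-supplied label (e.g.
    ear-on-ear overlap / leaf cover / edge truncation); the toolkit never
    auto-classifies occlusion.  Rate = unmatched truth boxes / truth boxes,
    pooled within each stratum; an empty stratum reports ``None``.
    """
    for img in truth:
        if img.image_id not in strata:
            raise ValueError(f"image {img.image_id!r} has no stratum label")
        if img.image_id not in dets:
            raise ValueError(f"image {img.image_id!r} has no detection set")
    missed: dict[str, int] = {}
    total: dict[str, int] = {}
    for img in truth:
        label = strata[img.image_id]
        m = match_detections(img.boxes, dets[img.image_id], iou_threshold)
        missed[label] = missed.get(label, 0) + len(m.unmatched_truth)
        total[label] = total.get(label, 0) + len(img.boxes)
    return {label: (missed[label] / total[label] if total[label] > 0 else None)
            for label in total}


def timing_report(times: Sequence[float]) -> TimingReport:
    """Mean per-image time and its reciprocal FPS."""
    if len(times) == 0:
        raise ValueError("need at least one timing sample")
    if any(t <= 0 for t in times):
        raise ValueError("times must be positive")
    return TimingReport(t_per_image=sum(times) / len(times))
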