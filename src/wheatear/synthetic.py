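"""Seeded generator of wheat-field-like annotated scenes.

Real wheat-canopy images show dozens of mutually overlapping grain spikes
("ears") against cluttered vegetation.  This module emulates the geometry of
such scenes — dense elliptical blobs with awn-like striping, exact per-blob
bounding boxes, a controllable fraction of mutually overlapping ears — so
that augmentation and evaluation code can be exercised without any dataset
download.  It makes no attempt at photorealism: only box geometry and local
texture matter downstream.

Two independent RNG streams are derived from the seed: a *geometry* stream
(placement, sizes, orientations) and a *texture* stream (background clutter,
blob intensities).  Because the geometry stream draws the same number of
variates regardless of canvas size, scaling the canvas and all pixel ranges
by a power of two scales every output box exactly.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .annotations import AnnotatedImage, BoundingBox, DetectionSet

logger = logging.getLogger(__name__)


class GenerationError(RuntimeError):
    """Raised when blob placement is infeasible within the retry budget."""


# rejection-sampling budget, per spec'd cap: 100 attempts per requested ear
_MAX_ATTEMPTS_PER_EAR = 100


@dataclass
class SceneSpec:
    """Parameters of one synthetic scene.

    ``overlap_fraction`` is the target fraction of ears whose box intersects
    at least one other ear's box; the realized fraction is within ±0.15 of
    the target for ``n_ears >= 20``.
    """

    image_size: tuple[int, int] = (128, 128)  # (rows, cols)
    n_ears: int = 30
    ear_length_range: tuple[float, float] = (14.0, 26.0)
    ear_width_range: tuple[float, float] = (5.0, 9.0)
    overlap_fraction: float = 0.5
    background: str = "clutter"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_ears < 0:
            raise ValueError("n_ears must be >= 0")
        for lo, hi in (self.ear_length_range, self.ear_width_range):
            if not (0 < lo <= hi):
                raise ValueError("size ranges must be positive with min <= max")
        if not (0.0 <= self.overlap_fraction <= 1.0):
            raise ValueError("overlap_fraction must lie in [0, 1]")
        if self.background not in ("plain", "clutter"):
            raise ValueError(f"unknown background {self.background!r}")


@dataclass
class _Rect:
    """Unvalidated rectangle; may extend past the canvas before clipping."""

    xmin: float
    ymin: float
    xmax: float
    ymax: float

    def clip(self, rows: int, cols: int) -> "_Rect | None":
        x0, y0 = max(self.xmin, 0.0), max(self.ymin, 0.0)
        x1, y1 = min(self.xmax, float(cols)), min(self.ymax, float(rows))
        if x1 <= x0 or y1 <= y0:
            return None
        return _Rect(x0, y0, x1, y1)

    def to_box(self) -> BoundingBox:
        return BoundingBox(self.xmin, self.ymin, self.xmax - self.xmin, self.ymax - self.ymin)


@dataclass
class _Ear:
    cx: float  # center column
    cy: float  # center row
    a: float   # semi-major (length/2)
    b: float   # semi-minor (width/2)
    theta: float
    box: _Rect = field(init=False)

    def __post_init__(self) -> None:
        # tight axis-aligned bbox of the rotated ellipse
        ex = np.sqrt((self.a * np.cos(self.theta)) ** 2 + (self.b * np.sin(self.theta)) ** 2)
        ey = np.sqrt((self.a * np.sin(self.theta)) ** 2 + (self.b * np.cos(self.theta)) ** 2)
        self.box = _Rect(self.cx - ex, self.cy - ey, self.cx + ex, self.cy + ey)


def _rects_intersect(a: _Rect, b: _Rect) -> bool:
    return a.xmin < b.xmax and b.xmin < a.xmax and a.ymin < b.ymax and b.ymin < a.ymax


def _boxes_intersect(a: BoundingBox, b: BoundingBox) -> bool:
    return a.xmin < b.xmax and b.xmin < a.xmax and a.ymin < b.ymax and b.ymin < a.ymax


def _clip_ear_rect(rect: _Rect, rows: int, cols: int) -> _Rect:
    c = rect.clip(rows, cols)
    if c is None:
        raise GenerationError("ear fell entirely outside the canvas")
    return c


def overlap_fraction(boxes: list[BoundingBox]) -> float:
    """Realized fraction of boxes intersecting >= 1 other box (brute force)."""
    n = len(boxes)
    if n == 0:
        return 0.0
    hit = [False] * n
    for i in range(n):
        for j in range(i + 1, n):
            if _boxes_intersect(boxes[i], boxes[j]):
                hit[i] = hit[j] = True
    return sum(hit) / n


def _sample_ear(geo: np.random.Generator, spec: SceneSpec, rows: int, cols: int,
                center: tuple[float, float] | None = None) -> _Ear:
    llo, lhi = spec.ear_length_range
    wlo, whi = spec.ear_width_range
    length = llo + geo.random() * (lhi - llo)
    width = wlo + geo.random() * (whi - wlo)
    theta = geo.random() * np.pi
    if center is None:
        # inset margin keeps most of the blob on-canvas; fractions scale with size
        cx = (0.05 + 0.9 * geo.random()) * cols
        cy = (0.05 + 0.9 * geo.random()) * rows
    else:
        cx, cy = center
    return _Ear(cx, cy, length / 2.0, width / 2.0, theta)


def _render_ear(canvas: np.ndarray, ear: _Ear, intensity: float, phase: float) -> None:
    rows, cols = canvas.shape
    r0 = max(int(np.floor(ear.box.ymin)), 0)
    r1 = min(int(np.ceil(ear.box.ymax)) + 1, rows)
    c0 = max(int(np.floor(ear.box.xmin)), 0)
    c1 = min(int(np.ceil(ear.box.xmax)) + 1, cols)
    if r0 >= r1 or c0 >= c1:
        return
    rr, cc = np.meshgrid(np.arange(r0, r1), np.arange(c0, c1), indexing="ij")
    # pixel centers
    dx = cc + 0.5 - ear.cx
    dy = rr + 0.5 - ear.cy
    u = (dx * np.cos(ear.theta) + dy * np.sin(ear.theta)) / ear.a   # major-axis coord
    v = (-dx * np.sin(ear.theta) + dy * np.cos(ear.theta)) / ear.b
    inside = u * u + v * v <= 1.0
    # awn-like striping along the spike axis
    stripes = 0.75 + 0.25 * np.cos(6.0 * np.pi * u + phase)
    patch = canvas[r0:r1, c0:c1]
    vals = intensity * stripes
    patch[inside] = np.maximum(patch[inside], vals[inside])


def generate_scene(spec: SceneSpec) -> AnnotatedImage:
    """Render a synthetic wheat scene with exact ground-truth boxes.

    Overlap is produced by placing a share of the ears in adjacent pairs and
    the remainder by rejection sampling against all previously placed boxes;
    placement failing ``100 * n_ears`` attempts raises
    :class:`GenerationError`.  Identical spec (including seed) gives
    bit-identical pixels and boxes.
    """
    rows, cols = spec.image_size
    geo_ss, tex_ss = np.random.SeedSequence(spec.seed).spawn(2)
    geo = np.random.default_rng(geo_ss)
    tex = np.random.default_rng(tex_ss)

    n = spec.n_ears
    n_pairs = int(round(spec.overlap_fraction * n / 2.0))
    budget = _MAX_ATTEMPTS_PER_EAR * max(n, 1)

    ears: list[_Ear] = []
    # overlapping pairs first: anchor placed freely, partner forced to intersect
    for _ in range(n_pairs):
        anchor = _sample_ear(geo, spec, rows, cols)
        ears.append(anchor)
        while True:
            budget -= 1
            if budget < 0:
                raise GenerationError(f"could not place {n} ears on a {rows}x{cols} canvas")
            tx = (geo.random() - 0.5) * 1.6
            ty = (geo.random() - 0.5) * 1.6
            partner = _sample_ear(geo, spec, rows, cols, center=(anchor.cx, anchor.cy))
            half_w_a = (anchor.box.xmax - anchor.box.xmin) / 2
            half_h_a = (anchor.box.ymax - anchor.box.ymin) / 2
            half_w_p = (partner.box.xmax - partner.box.xmin) / 2
            half_h_p = (partner.box.ymax - partner.box.ymin) / 2
            partner = _Ear(
                anchor.cx + tx * (half_w_a + half_w_p),
                anchor.cy + ty * (half_h_a + half_h_p),
                partner.a, partner.b, partner.theta,
            )
            pa = _clip_ear_rect(anchor.box, rows, cols)
            pb = partner.box.clip(rows, cols)
            if pb is not None and _rects_intersect(pa, pb):
                ears.append(partner)
                break
    # isolated ears: reject any placement touching an existing box
    for _ in range(n - 2 * n_pairs):
        while True:
            budget -= 1
            if budget < 0:
                raise GenerationError(f"could not place {n} ears on a {rows}x{cols} canvas")
            ear = _sample_ear(geo, spec, rows, cols)
            cand = ear.box.clip(rows, cols)
            if cand is None:
                continue
            if not any(_rects_intersect(cand, _clip_ear_rect(e.box, rows, cols)) for e in ears):
                ears.append(ear)
                break

    # texture stream: background then per-ear intensities/phases
    if spec.background == "clutter":
        noise = tex.random((rows, cols))
        smooth = ndimage.gaussian_filter(noise, sigma=2.0)
        lo, hi = smooth.min(), smooth.max()
        canvas = 20.0 + 90.0 * (smooth - lo) / max(hi - lo, 1e-12)
    else:
        canvas = np.full((rows, cols), 40.0)
    for ear in ears:
        intensity = 150.0 + 85.0 * tex.random()
        phase = 2.0 * np.pi * tex.random()
        _render_ear(canvas, ear, intensity, phase)

    pixels = np.clip(canvas, 0, 240).astype(np.uint8)
    pixels = np.repeat(pixels[:, :, None], 3, axis=2)
    boxes = [_clip_ear_rect(e.box, rows, cols).to_box() for e in ears]
    return AnnotatedImage(f"scene_{spec.seed:06d}", (rows, cols), boxes, pixels)


def generate_detections(truth: AnnotatedImage, miss_rate: float = 0.0,
                        false_rate: float = 0.0, jitter: float = 0.0,
                        seed: int = 0) -> DetectionSet:
    """Simulate detector output for a ground-truth scene.

    Each truth box is independently dropped with probability ``miss_rate``;
    survivors have every edge perturbed by at most ``jitter`` pixels and get
    a confidence drawn uniformly on (0.5, 1].  False positives are added at
    ``false_rate`` per true box, at random locations disjoint from every
    truth box, with the same confidence law.
    """
    for name, rate in (("miss_rate", miss_rate), ("false_rate", false_rate)):
        if not (0.0 <= rate <= 1.0):
            raise ValueError(f"{name} must lie in [0, 1], got {rate}")
    rows, cols = truth.shape
    rng = np.random.default_rng(seed)
    out: list[BoundingBox] = []

    for box in truth.boxes:
        if rng.random() < miss_rate:
            continue
        if jitter > 0:
            dx0, dy0, dx1, dy1 = rng.uniform(-jitter, jitter, size=4)
        else:
            dx0 = dy0 = dx1 = dy1 = 0.0
        x0 = min(max(box.xmin + dx0, 0.0), cols - 1.0)
        y0 = min(max(box.ymin + dy0, 0.0), rows - 1.0)
        x1 = min(max(box.xmax + dx1, x0 + 1.0), float(cols))
        y1 = min(max(box.ymax + dy1, y0 + 1.0), float(rows))
        conf = 1.0 - 0.5 * rng.random()  # uniform on (0.5, 1]
        out.append(BoundingBox(x0, y0, x1 - x0, y1 - y0, confidence=conf))

    if truth.boxes and false_rate > 0:
        n_fp = int(rng.binomial(len(truth.boxes), false_rate))
        sizes = [(b.width, b.height) for b in truth.boxes]
        for _ in range(n_fp):
            w, h = sizes[int(rng.integers(len(sizes)))]
            for _attempt in range(200):
                x0 = rng.random() * max(cols - w, 1.0)
                y0 = rng.random() * max(rows - h, 1.0)
                cand = BoundingBox(x0, y0, min(w, cols - x0), min(h, rows - y0))
                if not any(_boxes_intersect(cand, t) for t in truth.boxes):
                    conf = 1.0 - 0.5 * rng.random()
                    out.append(BoundingBox(cand.xmin, cand.ymin, cand.width,
                                           cand.height, confidence=conf))
                    break
            else:
                logger.warning("no ear-free location found for a false positive; skipped")

    return DetectionSet(truth.image_id, out).sorted()
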