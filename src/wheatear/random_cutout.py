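"""Random-Cutout occlusion augmentation, with Cutout and Random-Erasing baselines.

Random-Cutout simulates the occlusion seen in real wheat canopies by erasing
rectangles whose *placement* follows ear density (centers sampled from the
occlusion probability map) and whose *size* adapts to the ears in the image:

* number of rectangles  N = max(1, floor(N_total / 4)),
* height  H ~ Uniform[H_min/4, H_max/4],
* width   W ~ Uniform[W_min/4, W_max/4],

where N_total is the number of annotated ears and H_min/H_max (W_min/W_max)
are the smallest/largest box height (width) in the image.  Divisors are
configurable; 4 is the default for both.  Ground-truth boxes are returned
unchanged — erased ears must keep supervising the detector, exactly as real
occlusion leaves the ear present but hidden.

The fixed-size, position-uniform Cutout and the noise-filled Random-Erasing
baselines are provided for comparison; both ignore the annotations entirely.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, replace

import numpy as np

from .annotations import AnnotatedImage, BoundingBox
from .probability_map import ProbabilityMap, build_probability_map, normalize_to_distribution

logger = logging.getLogger(__name__)

FILLS = ("white", "random_noise", "mean")


@dataclass
class EraseRectangle:
    """One erase operation: a center pixel plus a (possibly fractional) size.

    The realized pixel extent is the half-open window of height ``height``
    and width ``width`` centered on ``center``, clipped to the image grid.
    """

    center: tuple[int, int]  # (row, col)
    height: float
    width: float
    fill: str = "white"

    def __post_init__(self) -> None:
        if self.height <= 0 or self.width <= 0:
            raise ValueError("erase rectangle must have positive size")
        if self.fill not in FILLS:
            raise ValueError(f"fill must be one of {FILLS}")

    def extent(self, image_shape: tuple[int, int]) -> tuple[int, int, int, int]:
        """Clipped pixel extent (r0, r1, c0, c1), half-open."""
        rows, cols = image_shape
        cr, cc = self.center
        r0 = max(math.ceil(cr - self.height / 2), 0)
        r1 = min(math.ceil(cr + self.height / 2), rows)
        c0 = max(math.ceil(cc - self.width / 2), 0)
        c1 = min(math.ceil(cc + self.width / 2), cols)
        return r0, r1, c0, c1


@dataclass
class CutoutConfig:
    """Random-Cutout parameters.

    ``n_rect_divisor`` sets N = N_total / divisor; ``size_divisor`` sets the
    per-image size bounds [min/divisor, max/divisor].
    """

    n_rect_divisor: int = 4
    size_divisor: int = 4
    fill: str = "white"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_rect_divisor < 1 or self.size_divisor < 1:
            raise ValueError("divisors must be >= 1")
        if self.fill not in FILLS:
            raise ValueError(f"fill must be one of {FILLS}")


def propose_centers(pmap: ProbabilityMap, n: int, seed: int, *, replace: bool = False) -> np.ndarray:
    """Sample ``n`` center pixels with probability proportional to the map.

    Returns an (n, 2) array of (row, col) coordinates.  Default is sampling
    without replacement (centers are distinct); ``replace=True`` gives plain
    multinomial draws, useful for distributional checks.
    """
    if n < 0:
        raise ValueError("n must be >= 0")
    npix = pmap.values.size
    if not replace and n > npix:
        raise ValueError(f"cannot draw {n} distinct centers from {npix} pixels")
    rng = np.random.default_rng(seed)
    p = normalize_to_distribution(pmap).ravel()
    flat = rng.choice(npix, size=n, replace=replace, p=p, shuffle=False)
    return np.stack(np.unravel_index(flat, pmap.shape), axis=1)


def sample_rectangle_size(boxes: list[BoundingBox], size_divisor: int,
                          rng: np.random.Generator) -> tuple[float, float]:
    """Draw one (H, W): uniform between min/divisor and max/divisor of the
    per-image box heights and widths, floored at 1 pixel."""
    if not boxes:
        raise ValueError("cannot size an erase rectangle without boxes")
    heights = [b.height for b in boxes]
    widths = [b.width for b in boxes]
    h_lo, h_hi = min(heights) / size_divisor, max(heights) / size_divisor
    w_lo, w_hi = min(widths) / size_divisor, max(widths) / size_divisor
    h = h_lo + rng.random() * (h_hi - h_lo)
    w = w_lo + rng.random() * (w_hi - w_lo)
    return max(h, 1.0), max(w, 1.0)


def _fill_value(pixels: np.ndarray, fill: str, rng: np.random.Generator,
                window: tuple[int, int, int, int]) -> np.ndarray:
    r0, r1, c0, c1 = window
    shape = (r1 - r0, c1 - c0, pixels.shape[2])
    if fill == "white":
        return np.full(shape, 255, dtype=np.uint8)
    if fill == "random_noise":
        return rng.integers(0, 256, size=shape, dtype=np.int64).astype(np.uint8)
    mean = pixels.mean(axis=(0, 1))
    return np.broadcast_to(np.round(mean).astype(np.uint8), shape).copy()


def apply_random_cutout(image: AnnotatedImage,
                        config: CutoutConfig | None = None) -> tuple[AnnotatedImage, list[EraseRectangle]]:
    """Erase density-guided, size-adaptive rectangles from a scene.

    Centers are drawn without replacement from the normalized occlusion
    probability map; each rectangle gets an independent (H, W).  Draw order
    is fixed (all centers first, then sizes in center order) so a seed fully
    determines the output.  Annotations are returned unchanged.  An image
    with no ears is returned as-is with a logged notice.
    """
    config = config or CutoutConfig()
    if image.pixels is None:
        raise ValueError("augmentation needs pixel data")
    if not image.boxes:
        logger.info("image %s has no ears; augmentation skipped", image.image_id)
        return image, []

    n_total = len(image.boxes)
    n_rect = max(1, n_total // config.n_rect_divisor)
    pmap = build_probability_map(image.shape, image.boxes)

    seeds = np.random.SeedSequence(config.seed).spawn(2)
    centers = propose_centers(pmap, n_rect, seed=seeds[0])
    rng = np.random.default_rng(seeds[1])

    pixels = image.pixels.copy()
    rects: list[EraseRectangle] = []
    for cr, cc in centers:
        h, w = sample_rectangle_size(image.boxes, config.size_divisor, rng)
        rect = EraseRectangle((int(cr), int(cc)), h, w, config.fill)
        r0, r1, c0, c1 = rect.extent(image.shape)
        pixels[r0:r1, c0:c1] = _fill_value(image.pixels, config.fill, rng, (r0, r1, c0, c1))
        rects.append(rect)

    boxes = [replace(b) for b in image.boxes]  # same values, fresh objects
    return AnnotatedImage(image.image_id, image.shape, boxes, pixels), rects


def apply_cutout_baseline(image: AnnotatedImage, n: int, size: int, seed: int) -> AnnotatedImage:
    """Classic Cutout: ``n`` fixed-size white squares at uniform positions."""
    if size <= 0:
        raise ValueError("size must be positive")
    if image.pixels is None:
        raise ValueError("augmentation needs pixel data")
    rng = np.random.default_rng(seed)
    rows, cols = image.shape
    pixels = image.pixels.copy()
    for _ in range(n):
        cr = int(rng.integers(rows))
        cc = int(rng.integers(cols))
        rect = EraseRectangle((cr, cc), float(size), float(size), "white")
        r0, r1, c0, c1 = rect.extent(image.shape)
        pixels[r0:r1, c0:c1] = 255
    return AnnotatedImage(image.image_id, image.shape, [replace(b) for b in image.boxes], pixels)


def apply_random_erasing_baseline(image: AnnotatedImage, n: int,
                                  size_range: tuple[float, float],
                                  aspect_range: tuple[float, float],
                                  seed: int) -> AnnotatedImage:
    """Random Erasing: ``n`` noise-filled rectangles of sampled scale/aspect."""
    s_lo, s_hi = size_range
    a_lo, a_hi = aspect_range
    if not (0 < s_lo <= s_hi) or not (0 < a_lo <= a_hi):
        raise ValueError("size and aspect ranges must be positive with min <= max")
    if image.pixels is None:
        raise ValueError("augmentation needs pixel data")
    rng = np.random.default_rng(seed)
    rows, cols = image.shape
    pixels = image.pixels.copy()
    for _ in range(n):
        cr = int(rng.integers(rows))
        cc = int(rng.integers(cols))
        s = rng.uniform(s_lo, s_hi)
        a = rng.uniform(a_lo, a_hi)
        h = max(s * math.sqrt(a), 1.0)
        w = max(s / math.sqrt(a), 1.0)
        rect = EraseRectangle((cr, cc), h, w, "random_noise")
        r0, r1, c0, c1 = rect.extent(image.shape)
        pixels[r0:r1, c0:c1] = rng.integers(0, 256, size=(r1 - r0, c1 - c0, 3), dtype=np.int64).astype(np.uint8)
    return AnnotatedImage(image.image_id, image.shape, [replace(b) for b in image.boxes], pixels)
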