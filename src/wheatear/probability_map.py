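"""Per-pixel occlusion-placement probability from box density.

In a wheat canopy, occlusion happens mostly where ears crowd together, but
leaves and stems occlude ears in sparse regions too.  The placement map
encodes both: every pixel starts at a floor of 0.001, and each annotated ear
box covering a pixel adds 0.003, i.e.

    I_i = 0.001 + 0.003 * n_i

where ``n_i`` is the number of ground-truth boxes whose half-open extent
contains pixel ``i``.  The map is piecewise constant on regions of equal
box-overlap count and is used (after normalization) to bias where simulated
occlusion rectangles are placed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .annotations import BoundingBox

BACKGROUND_FLOOR = 0.001
PER_EAR_INCREMENT = 0.003


@dataclass
class ProbabilityMap:
    """Non-negative per-pixel placement weights aligned to the image grid."""

    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 2 or self.values.size == 0:
            raise ValueError("probability map must be a non-empty 2-D array")
        if np.any(self.values < BACKGROUND_FLOOR):
            raise ValueError(f"map values must respect the {BACKGROUND_FLOOR} background floor")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape


def _pixel_slices(box: BoundingBox) -> tuple[slice, slice]:
    # integer pixel (r, c) lies in the half-open box iff ceil(lo) <= coord < hi
    r0, r1 = math.ceil(box.ymin), math.ceil(box.ymax)
    c0, c1 = math.ceil(box.xmin), math.ceil(box.xmax)
    return slice(r0, r1), slice(c0, c1)


def build_probability_map(image_size: tuple[int, int], boxes: Sequence[BoundingBox]) -> ProbabilityMap:
    """Build the occlusion-placement map for an image.

    Boxes are assumed clipped to the grid.  Membership uses the half-open
    convention, so adjacent boxes never double-count a shared edge.
    """
    rows, cols = image_size
    counts = np.zeros((rows, cols), dtype=np.int64)
    for box in boxes:
        rs, cs = _pixel_slices(box)
        counts[rs, cs] += 1
    return ProbabilityMap(BACKGROUND_FLOOR + PER_EAR_INCREMENT * counts)


def normalize_to_distribution(pmap: ProbabilityMap) -> np.ndarray:
    """Rescale the map to a proper distribution (sums to 1, ordering kept)."""
    total = pmap.values.sum()
    return pmap.values / total
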