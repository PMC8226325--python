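"""Independent brute-force references used by the tests.

Everything here deliberately avoids the code paths it checks: probability
maps by per-pixel membership predicates, CBAM by scalar Python loops, NMS by
exhaustive rescanning, matching by maximum-cardinality assignment.
"""

from __future__ import annotations

import numpy as np
from scipy.optimize import linear_sum_assignment

from wheatear.annotations import BoundingBox, DetectionSet


def brute_probability_map(image_size: tuple[int, int], boxes) -> np.ndarray:
    """0.001 + 0.003*n_i with n_i counted by the half-open membership predicate."""
    rows, cols = image_size
    rr, cc = np.meshgrid(np.arange(rows), np.arange(cols), indexing="ij")
    counts = np.zeros((rows, cols), dtype=np.int64)
    for b in boxes:
        counts += ((cc >= b.xmin) & (cc < b.xmax) & (rr >= b.ymin) & (rr < b.ymax)).astype(np.int64)
    return 0.001 + 0.003 * counts


def brute_probability_map_scalar(image_size: tuple[int, int], boxes) -> np.ndarray:
    """Pure-Python per-pixel loop; for small grids only."""
    rows, cols = image_size
    out = np.empty((rows, cols))
    for r in range(rows):
        for c in range(cols):
            n = sum(1 for b in boxes if b.xmin <= c < b.xmax and b.ymin <= r < b.ymax)
            out[r, c] = 0.001 + 0.003 * n
    return out


# ---------------------------------------------------------------------------
# CBAM scalar loops


def _sigmoid_scalar(x: float) -> float:
    if x >= 0:
        return 1.0 / (1.0 + np.exp(-x))
    e = np.exp(x)
    return e / (1.0 + e)


def _mlp_scalar(x: np.ndarray, w0: np.ndarray, w1: np.ndarray) -> np.ndarray:
    hidden = []
    for i in range(w0.shape[0]):
        s = 0.0
        for j in range(w0.shape[1]):
            s += w0[i, j] * x[j]
        hidden.append(max(s, 0.0))
    out = []
    for i in range(w1.shape[0]):
        s = 0.0
        for j in range(w1.shape[1]):
            s += w1[i, j] * hidden[j]
        out.append(s)
    return np.array(out)


def channel_attention_scalar(f: np.ndarray, w0: np.ndarray, w1: np.ndarray) -> np.ndarray:
    W, H, C = f.shape
    avg = np.array([sum(f[x, y, c] for x in range(W) for y in range(H)) / (W * H) for c in range(C)])
    mx = np.array([max(f[x, y, c] for x in range(W) for y in range(H)) for c in range(C)])
    pre = _mlp_scalar(avg, w0, w1) + _mlp_scalar(mx, w0, w1)
    return np.array([_sigmoid_scalar(v) for v in pre])


def spatial_attention_scalar(f: np.ndarray, kernel: np.ndarray, bias: float) -> np.ndarray:
    W, H, C = f.shape
    avg = f.mean(axis=2)
    mx = f.max(axis=2)
    stack = [avg, mx]
    out = np.empty((W, H))
    k = kernel.shape[0] // 2
    for x in range(W):
        for y in range(H):
            s = bias
            for i in range(kernel.shape[0]):
                for j in range(kernel.shape[1]):
                    xi, yj = x + i - k, y + j - k
                    if 0 <= xi < W and 0 <= yj < H:
                        for d in range(2):
                            s += stack[d][xi, yj] * kernel[i, j, d]
            out[x, y] = _sigmoid_scalar(s)
    return out


def refine_scalar(f: np.ndarray, w0: np.ndarray, w1: np.ndarray,
                  kernel: np.ndarray, bias: float) -> np.ndarray:
    mc = channel_attention_scalar(f, w0, w1)
    f_dot = np.empty_like(f)
    W, H, C = f.shape
    for x in range(W):
        for y in range(H):
            for c in range(C):
                f_dot[x, y, c] = f[x, y, c] * mc[c]
    ms = spatial_attention_scalar(f_dot, kernel, bias)
    out = np.empty_like(f)
    for x in range(W):
        for y in range(H):
            for c in range(C):
                out[x, y, c] = f_dot[x, y, c] * ms[x, y]
    return out


# ---------------------------------------------------------------------------
# detection oracles


def iou_ref(a: BoundingBox, b: BoundingBox) -> float:
    ix = max(0.0, min(a.xmin + a.width, b.xmin + b.width) - max(a.xmin, b.xmin))
    iy = max(0.0, min(a.ymin + a.height, b.ymin + b.height) - max(a.ymin, b.ymin))
    inter = ix * iy
    union = a.width * a.height + b.width * b.height - inter
    return inter / union if union > 0 else 0.0


def brute_nms(dets: DetectionSet, conf_threshold: float, iou_threshold: float) -> list[BoundingBox]:
    """Exhaustive reference: rescan all remaining boxes at every step."""
    boxes = [(i, b) for i, b in enumerate(dets.boxes) if b.confidence > conf_threshold]
    survivors: list[BoundingBox] = []
    alive = list(boxes)
    while alive:
        best = min(alive, key=lambda ib: (-ib[1].confidence, -ib[1].width * ib[1].height, ib[0]))
        survivors.append(best[1])
        alive = [(i, b) for i, b in alive
                 if (i, b) != best and iou_ref(best[1], b) <= iou_threshold]
    return survivors


def max_cardinality_matching(truth, det_boxes, iou_threshold: float) -> int:
    """Maximum number of one-to-one (det, truth) pairs with IoU >= threshold."""
    if not truth or not det_boxes:
        return 0
    eligible = np.zeros((len(det_boxes), len(truth)), dtype=float)
    for i, d in enumerate(det_boxes):
        for j, t in enumerate(truth):
            if iou_ref(d, t) >= iou_threshold:
                eligible[i, j] = 1.0
    ri, ci = linear_sum_assignment(-eligible)
    return int(eligible[ri, ci].sum())


def random_boxes(rng: np.random.Generator, n: int, rows: int, cols: int,
                 max_side: float = 30.0, confidence: bool = False) -> list[BoundingBox]:
    out = []
    for _ in range(n):
        w = 1.0 + rng.random() * (max_side - 1.0)
        h = 1.0 + rng.random() * (max_side - 1.0)
        x = rng.random() * max(cols - w, 0.5)
        y = rng.random() * max(rows - h, 0.5)
        conf = float(rng.random()) if confidence else None
        out.append(BoundingBox(x, y, min(w, cols - x), min(h, rows - y), confidence=conf))
    return out
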