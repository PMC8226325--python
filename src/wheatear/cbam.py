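"""Numeric reference for the convolutional block attention module (CBAM).

CBAM refines a feature map F ∈ R^{W×H×C} in two multiplicative stages:

* channel attention  M_c(F) = sigmoid(MLP(AvgPool(F)) + MLP(MaxPool(F))),
  where the pools are global over the spatial axes and the two descriptors
  share one two-layer perceptron W_1 · ReLU(W_0 · x) with bottleneck C/r;
* spatial attention  M_s(F) = sigmoid(f7x7([AvgPool_c(F); MaxPool_c(F)])),
  where the pools run along the channel axis and f7x7 is a 7×7 convolution
  over the two stacked descriptors (zero padding keeps the W×H size);
* refinement  F' = M_c(F) ⊗ F,  F'' = M_s(F') ⊗ F'.

This is a pure-numpy forward pass: weights are supplied inputs (for example
exported from a trained detector), nothing is learned here.  The MLP carries
no bias, matching the published form; the spatial convolution's scalar bias
defaults to 0.  Axis order is (W, H, C) throughout.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

SPATIAL_KERNEL_SIZE = 7


def _sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x, dtype=np.float64)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    e = np.exp(x[~pos])
    out[~pos] = e / (1.0 + e)
    return out


def _check_feature_map(f: np.ndarray) -> np.ndarray:
    f = np.asarray(f, dtype=np.float64)
    if f.ndim != 3 or f.shape[2] < 1:
        raise ValueError(f"feature map must be (W, H, C) with C >= 1, got shape {f.shape}")
    if not np.all(np.isfinite(f)):
        raise ValueError("feature map must be finite")
    return f


@dataclass
class ChannelMLPWeights:
    """Shared two-layer perceptron of the channel-attention branch.

    ``w0`` maps C -> C/r, ``w1`` maps C/r -> C; ``r`` is the bottleneck
    reduction ratio (literature default 16) and must divide C.
    """

    w0: np.ndarray
    w1: np.ndarray
    r: int = 16

    def __post_init__(self) -> None:
        self.w0 = np.asarray(self.w0, dtype=np.float64)
        self.w1 = np.asarray(self.w1, dtype=np.float64)
        if self.w0.ndim != 2 or self.w1.ndim != 2:
            raise ValueError("w0 and w1 must be matrices")
        hidden, c = self.w0.shape
        if self.w1.shape != (c, hidden):
            raise ValueError(f"w1 shape {self.w1.shape} does not match w0 {self.w0.shape}")
        if self.r < 1 or c % self.r != 0 or hidden != c // self.r:
            raise ValueError(f"hidden size {hidden} must equal C/r = {c}/{self.r}")

    @property
    def channels(self) -> int:
        return self.w0.shape[1]

    @classmethod
    def random(cls, channels: int, r: int = 16, seed: int = 0) -> "ChannelMLPWeights":
        rng = np.random.default_rng(seed)
        hidden = channels // r
        scale0 = 1.0 / np.sqrt(channels)
        scale1 = 1.0 / np.sqrt(max(hidden, 1))
        return cls(rng.normal(0, scale0, (hidden, channels)),
                   rng.normal(0, scale1, (channels, hidden)), r=r)


@dataclass
class SpatialConvWeights:
    """7×7 convolution over the two stacked spatial descriptors."""

    kernel: np.ndarray
    bias: float = 0.0

    def __post_init__(self) -> None:
        self.kernel = np.asarray(self.kernel, dtype=np.float64)
        if self.kernel.shape != (SPATIAL_KERNEL_SIZE, SPATIAL_KERNEL_SIZE, 2):
            raise ValueError(f"kernel must be 7x7x2, got {self.kernel.shape}")

    @classmethod
    def random(cls, seed: int = 0) -> "SpatialConvWeights":
        rng = np.random.default_rng(seed)
        return cls(rng.normal(0, 1.0 / 7.0, (SPATIAL_KERNEL_SIZE, SPATIAL_KERNEL_SIZE, 2)), bias=0.0)


def _mlp(x: np.ndarray, w: ChannelMLPWeights) -> np.ndarray:
    return w.w1 @ np.maximum(w.w0 @ x, 0.0)


def channel_attention(f: np.ndarray, weights: ChannelMLPWeights) -> np.ndarray:
    """Channel gate M_c ∈ (0,1)^C from globally pooled descriptors."""
    f = _check_feature_map(f)
    if f.shape[2] != weights.channels:
        raise ValueError(f"feature map has {f.shape[2]} channels, weights expect {weights.channels}")
    f_avg = f.mean(axis=(0, 1))
    f_max = f.max(axis=(0, 1))
    return _sigmoid(_mlp(f_avg, weights) + _mlp(f_max, weights))


def spatial_attention(f: np.ndarray, weights: SpatialConvWeights) -> np.ndarray:
    """Spatial gate M_s ∈ (0,1)^{W×H} from channel-pooled descriptors."""
    f = _check_feature_map(f)
    stack = np.stack([f.mean(axis=2), f.max(axis=2)], axis=2)
    acc = np.zeros(f.shape[:2], dtype=np.float64)
    for d in range(2):
        # cross-correlation with zero padding, output size preserved
        acc += ndimage.correlate(stack[:, :, d], weights.kernel[:, :, d],
                                 mode="constant", cval=0.0)
    return _sigmoid(acc + weights.bias)


def refine(f: np.ndarray, cw: ChannelMLPWeights, sw: SpatialConvWeights) -> np.ndarray:
    """Two-stage refinement F'' = M_s(M_c(F) ⊗ F) ⊗ (M_c(F) ⊗ F)."""
    f = _check_feature_map(f)
    mc = channel_attention(f, cw)
    f_dot = f * mc[None, None, :]
    ms = spatial_attention(f_dot, sw)
    return f_dot * ms[:, :, None]


def save_weights(path, cw: ChannelMLPWeights, sw: SpatialConvWeights) -> None:
    """Persist weights as a flat named-array archive (numpy .npz)."""
    np.savez(path, w0=cw.w0, w1=cw.w1, r=np.int64(cw.r),
             kernel=sw.kernel, bias=np.float64(sw.bias))


def load_weights(path) -> tuple[ChannelMLPWeights, SpatialConvWeights]:
    with np.load(path) as z:
        cw = ChannelMLPWeights(z["w0"], z["w1"], r=int(z["r"]))
        sw = SpatialConvWeights(z["kernel"], bias=float(z["bias"]))
    return cw, sw
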