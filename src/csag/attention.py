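"""Channel attention, spatial attention, and the fusion that produces the
single-channel attention map used by the attention-guided filter.

The channel gate follows the CBAM recipe: global average/max pooling per
channel, a shared two-layer perceptron with reduction ratio ``rho``, summed
logits, sigmoid.  The spatial gate pools along the channel axis (mean and
max), concatenates the two maps and applies a ``k_s`` x ``k_s`` convolution
followed by a sigmoid.

The fusion applies channel-then-spatial gating to the filtered map F and
the low-resolution guide Gl independently, projects each gated stack to a
single channel by the channel mean, sums, rectifies, convolves (3x3, 1->1)
and squashes with a sigmoid.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import nn
from .nn import Tensor, as_tensor

__all__ = [
    "ChannelAttention",
    "SpatialAttention",
    "AttentionFusion",
    "ChannelAttentionState",
    "SpatialAttentionState",
    "AttentionMap",
    "channel_attention",
    "spatial_attention",
    "csfag_attention_fusion",
]


# ---------------------------------------------------------------------------
# state records (numpy-facing)
# ---------------------------------------------------------------------------

@dataclass
class ChannelAttentionState:
    pooled_avg: np.ndarray   # (C,)
    pooled_max: np.ndarray   # (C,)
    logits: np.ndarray       # (C,)
    weights: np.ndarray      # (C,), strictly in (0,1)


@dataclass
class SpatialAttentionState:
    pooled_avg: np.ndarray   # (1,H,W)
    pooled_max: np.ndarray   # (1,H,W)
    logits: np.ndarray       # (1,H,W)
    weights: np.ndarray      # (1,H,W), strictly in (0,1)
    kernel_size: int


@dataclass
class AttentionMap:
    values: np.ndarray       # (1,h,w), strictly in (0,1)
    pre_sum: np.ndarray      # A0
    rectified: np.ndarray    # A1
    conv_logits: np.ndarray  # A2


def _check_input(x: np.ndarray) -> np.ndarray:
    x = np.asarray(x, dtype=np.float64)
    if x.ndim != 3:
        raise ValueError(f"expected a (C,H,W) feature map, got shape {x.shape}")
    if x.shape[1] == 0 or x.shape[2] == 0:
        raise ValueError("feature map has empty spatial extent")
    if not np.all(np.isfinite(x)):
        raise ValueError("feature map contains non-finite values")
    return x


# ---------------------------------------------------------------------------
# modules (autodiff-facing, operate on (N,C,H,W) tensors)
# ---------------------------------------------------------------------------

class ChannelAttention(nn.Module):
    def __init__(self, channels: int, ratio: int = 16,
                 rng: np.random.Generator | None = None, dtype=np.float32):
        super().__init__()
        if channels < 1:
            raise ValueError("channels must be >= 1")
        if ratio < 1:
            raise ValueError("reduction ratio must be >= 1")
        rng = rng if rng is not None else np.random.default_rng(0)
        hidden = max(channels // ratio, 1)
        self.channels, self.ratio, self.hidden = channels, ratio, hidden
        self.fc1 = nn.Linear(channels, hidden, rng=rng, dtype=dtype)
        self.fc2 = nn.Linear(hidden, channels, rng=rng, dtype=dtype)

    def _mlp(self, v: Tensor) -> Tensor:
        return self.fc2(self.fc1(v).relu())

    def gate(self, x: Tensor) -> Tensor:
        """Per-channel weights, shape (N,C)."""
        x = as_tensor(x)
        avg = x.mean(axis=(2, 3))
        mx = x.max(axis=3).max(axis=2)
        logits = self._mlp(avg) + self._mlp(mx)
        return logits.sigmoid()

    def forward(self, x: Tensor) -> Tensor:
        x = as_tensor(x)
        n, c = x.shape[0], x.shape[1]
        g = self.gate(x)
        return x * g.reshape(n, c, 1, 1)


class SpatialAttention(nn.Module):
    def __init__(self, kernel_size: int = 7,
                 rng: np.random.Generator | None = None, dtype=np.float32):
        super().__init__()
        if kernel_size % 2 == 0:
            raise ValueError("spatial attention kernel size must be odd")
        rng = rng if rng is not None else np.random.default_rng(0)
        self.kernel_size = kernel_size
        self.conv = nn.Conv2d(2, 1, kernel_size, rng=rng, dtype=dtype)

    def gate(self, x: Tensor) -> Tensor:
        """Per-pixel weights, shape (N,1,H,W)."""
        x = as_tensor(x)
        avg = x.mean(axis=1, keepdims=True)
        mx = x.max(axis=1, keepdims=True)
        logits = self.conv(nn.concat([avg, mx], axis=1))
        return logits.sigmoid()

    def forward(self, x: Tensor) -> Tensor:
        return as_tensor(x) * self.gate(x)


class AttentionFusion(nn.Module):
    """Fuses attention over (F, Gl) into one map in (0,1), shape (N,1,h,w)."""

    def __init__(self, channels: int, ratio: int = 16, kernel_size: int = 7,
                 rng: np.random.Generator | None = None, dtype=np.float32):
        super().__init__()
        rng = rng if rng is not None else np.random.default_rng(0)
        self.ca_f = ChannelAttention(channels, ratio, rng=rng, dtype=dtype)
        self.sa_f = SpatialAttention(kernel_size, rng=rng, dtype=dtype)
        self.ca_g = ChannelAttention(channels, ratio, rng=rng, dtype=dtype)
        self.sa_g = SpatialAttention(kernel_size, rng=rng, dtype=dtype)
        self.fuse = nn.Conv2d(1, 1, 3, rng=rng, dtype=dtype)

    def forward(self, f: Tensor, gl: Tensor, return_intermediates: bool = False):
        f, gl = as_tensor(f), as_tensor(gl)
        if f.shape != gl.shape:
            raise ValueError(f"F and Gl must share a shape, got {f.shape} vs {gl.shape}")
        fsa = self.sa_f(self.ca_f(f)).mean(axis=1, keepdims=True)
        gsa = self.sa_g(self.ca_g(gl)).mean(axis=1, keepdims=True)
        a0 = fsa + gsa
        a1 = a0.relu()
        a2 = self.fuse(a1)
        a = a2.sigmoid()
        if return_intermediates:
            return a, {"A0": a0, "A1": a1, "A2": a2}
        return a


# ---------------------------------------------------------------------------
# functional (numpy-facing) wrappers
# ---------------------------------------------------------------------------

def channel_attention(x: np.ndarray, rho: int = 16,
                      module: ChannelAttention | None = None,
                      rng: np.random.Generator | None = None):
    """Channel gate of a (C,H,W) map. Returns (state, gated array)."""
    x = _check_input(x)
    c = x.shape[0]
    if module is None:
        module = ChannelAttention(c, rho, rng=rng, dtype=np.float64)
    elif module.channels != c:
        raise ValueError("attention module channel count does not match input")
    xt = Tensor(x[None])
    avg = x.mean(axis=(1, 2))
    mx = x.max(axis=(1, 2))
    logits = module._mlp(Tensor(avg[None])).data[0] + module._mlp(Tensor(mx[None])).data[0]
    weights = 1.0 / (1.0 + np.exp(-logits))
    gated = module(xt).data[0]
    return ChannelAttentionState(avg, mx, logits, weights), gated


def spatial_attention(x: np.ndarray, k_s: int = 7,
                      module: SpatialAttention | None = None,
                      rng: np.random.Generator | None = None):
    """Spatial gate of a (C,H,W) map. Returns (state, gated array)."""
    x = _check_input(x)
    if module is None:
        module = SpatialAttention(k_s, rng=rng, dtype=np.float64)
    elif module.kernel_size != k_s:
        raise ValueError("module kernel size does not match k_s")
    xt = Tensor(x[None])
    avg = x.mean(axis=0, keepdims=True)
    mx = x.max(axis=0, keepdims=True)
    logits = module.conv(Tensor(np.stack([avg[0], mx[0]])[None])).data[0]
    weights = 1.0 / (1.0 + np.exp(-logits))
    gated = module(xt).data[0]
    return SpatialAttentionState(avg, mx, logits, weights, k_s), gated


def csfag_attention_fusion(f: np.ndarray, gl: np.ndarray,
                           module: AttentionFusion | None = None,
                           rho: int = 16, k_s: int = 7,
                           rng: np.random.Generator | None = None) -> AttentionMap:
    """Fused attention map over (F, Gl), both (C,h,w)."""
    f, gl = _check_input(f), _check_input(gl)
    if f.shape != gl.shape:
        raise ValueError(f"F and Gl must share a shape, got {f.shape} vs {gl.shape}")
    if module is None:
        module = AttentionFusion(f.shape[0], rho, k_s, rng=rng, dtype=np.float64)
    a, inter = module(Tensor(f[None]), Tensor(gl[None]), return_intermediates=True)
    return AttentionMap(
        values=a.data[0],
        pre_sum=inter["A0"].data[0],
        rectified=inter["A1"].data[0],
        conv_logits=inter["A2"].data[0],
    )
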