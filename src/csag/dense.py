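"""Densely connected bottleneck.

Block ``i`` receives the channel concatenation of the stem and all previous
block outputs (``c0 + (i-1)*n`` channels), applies two Conv3x3+BN+ReLU
layers and emits ``n`` channels (the growth rate).  After ``D`` blocks the
stem and every block output are concatenated (``c0 + D*n`` channels) and a
1x1 transition convolution maps to the configured output width.  ``D = 1``
degenerates to a plain two-convolution layer when ``n`` equals the plain
bottleneck width.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import nn
from .nn import Tensor, as_tensor

__all__ = ["DenseConfig", "DenseBlock", "DenseBottleneck", "dense_block_forward", "bottleneck_forward"]


@dataclass
class DenseConfig:
    in_channels: int
    growth: int
    out_channels: int
    blocks: int = 3  # D

    def __post_init__(self):
        if self.blocks < 1:
            raise ValueError("D must be >= 1")
        if self.growth < 1 or self.in_channels < 1 or self.out_channels < 1:
            raise ValueError("channel counts must be >= 1")

    def block_input_channels(self, i: int) -> int:
        """Channels entering block i (1-based): c0 + (i-1)*n."""
        return self.in_channels + (i - 1) * self.growth

    def concat_channels(self) -> int:
        return self.in_channels + self.blocks * self.growth


class DenseBlock(nn.Module):
    """Concat inputs (newest first) -> Conv3x3+BN+ReLU twice -> n channels."""

    def __init__(self, cin: int, growth: int, rng: np.random.Generator, dtype=np.float32):
        super().__init__()
        self.conv1 = nn.Conv2d(cin, growth, 3, rng=rng, dtype=dtype)
        self.bn1 = nn.BatchNorm2d(growth, dtype=dtype)
        self.conv2 = nn.Conv2d(growth, growth, 3, rng=rng, dtype=dtype)
        self.bn2 = nn.BatchNorm2d(growth, dtype=dtype)

    def forward(self, inputs) -> Tensor:
        if isinstance(inputs, (list, tuple)):
            if not inputs:
                raise ValueError("dense block needs at least one input")
            shapes = {t.shape[-2:] for t in map(as_tensor, inputs)}
            if len(shapes) != 1:
                raise ValueError(f"dense block inputs disagree spatially: {shapes}")
            x = nn.concat(list(inputs), axis=1) if len(inputs) > 1 else as_tensor(inputs[0])
        else:
            x = as_tensor(inputs)
        h = self.bn1(self.conv1(x)).relu()
        return self.bn2(self.conv2(h)).relu()


class DenseBottleneck(nn.Module):
    def __init__(self, cfg: DenseConfig, rng: np.random.Generator | None = None, dtype=np.float32):
        super().__init__()
        rng = rng if rng is not None else np.random.default_rng(0)
        self.cfg = cfg
        self.blocks = []
        for i in range(1, cfg.blocks + 1):
            blk = DenseBlock(cfg.block_input_channels(i), cfg.growth, rng, dtype)
            setattr(self, f"block{i}", blk)
            self.blocks.append(blk)
        self.transition = nn.Conv2d(cfg.concat_channels(), cfg.out_channels, 1, rng=rng, dtype=dtype)
        self.transition_bn = nn.BatchNorm2d(cfg.out_channels, dtype=dtype)

    def forward(self, x: Tensor) -> Tensor:
        x = as_tensor(x)
        if x.shape[1] != self.cfg.in_channels:
            raise ValueError(f"expected {self.cfg.in_channels} input channels, got {x.shape[1]}")
        feats = [x]  # newest first
        for blk in self.blocks:
            feats.insert(0, blk(feats))
        return self.transition_bn(self.transition(nn.concat(feats, axis=1))).relu()


# ------------------------------------------------------------------ numpy API

def dense_block_forward(inputs, block: DenseBlock) -> np.ndarray:
    """Run one dense block on a list of (C,H,W) arrays (newest first)."""
    tensors = [Tensor(np.asarray(x, dtype=np.float64)[None]) for x in inputs]
    return block(tensors).data[0]


def bottleneck_forward(x: np.ndarray, module: DenseBottleneck) -> np.ndarray:
    return module(Tensor(np.asarray(x, dtype=np.float64)[None])).data[0]
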