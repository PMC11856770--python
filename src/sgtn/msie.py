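"""Multi-scale spatial-spectral information extraction (MSIE) block.

Four parallel branches over an s x s x c feature map, every convolution with
64 filters and a ReLU, merged by element-wise summation:

* branch 1 — 1x1 conv, then 3x3 average pooling (stride 1, size-preserving,
  border means over valid cells only);
* branch 2 — 1x1 conv alone (nonlinear spectral mixing);
* branch 3 — 1x1 conv, then 1x3 and 3x1 factorized kernels applied in
  parallel and summed (cheap edge detectors in both orientations);
* branch 4 — 1x1 conv, then a serial 1x3 -> 3x1 chain whose intermediate and
  final maps are summed (the composed pair acts like a factorized 3x3).

The factorized 1x3/3x1 pairs replace full 3x3 kernels at a third of the
parameters.  A plain two-layer 3x3 convolution stack with the same output
contract is provided as the ablation substitute.
"""

from __future__ import annotations

import numpy as np

from .layers import Module, Conv2d
from .nn import Tensor, avgpool3x3_same

__all__ = ["MSIEBlock", "StandardConvBlock", "FILTERS"]

FILTERS = 64


class MSIEBlock(Module):
    def __init__(self, in_channels: int, rng: np.random.Generator,
                 filters: int = FILTERS):
        if in_channels < 1:
            raise ValueError("in_channels must be >= 1")
        f = filters
        self.b1_1x1 = Conv2d(in_channels, f, (1, 1), rng)
        self.b2_1x1 = Conv2d(in_channels, f, (1, 1), rng)
        self.b3_1x1 = Conv2d(in_channels, f, (1, 1), rng)
        self.b3_1x3 = Conv2d(f, f, (1, 3), rng)
        self.b3_3x1 = Conv2d(f, f, (3, 1), rng)
        self.b4_1x1 = Conv2d(in_channels, f, (1, 1), rng)
        self.b4_1x3 = Conv2d(f, f, (1, 3), rng)
        self.b4_3x1 = Conv2d(f, f, (3, 1), rng)
        self.in_channels = in_channels
        self.filters = f

    def __call__(self, x: Tensor) -> Tensor:
        """(N, s, s, c) -> (N, s, s, filters); spatial size preserved."""
        if x.shape[-1] != self.in_channels:
            raise ValueError(
                f"expected {self.in_channels} input channels, got {x.shape[-1]}")
        b1 = avgpool3x3_same(self.b1_1x1(x).relu())
        b2 = self.b2_1x1(x).relu()
        t3 = self.b3_1x1(x).relu()
        b3 = self.b3_1x3(t3).relu() + self.b3_3x1(t3).relu()
        t4 = self.b4_1x1(x).relu()
        u = self.b4_1x3(t4).relu()
        v = self.b4_3x1(u).relu()
        b4 = u + v
        return b1 + b2 + b3 + b4


class StandardConvBlock(Module):
    """Two size-preserving 3x3 convolutions with ReLU (MSIE ablation)."""

    def __init__(self, in_channels: int, rng: np.random.Generator,
                 filters: int = FILTERS):
        self.conv1 = Conv2d(in_channels, filters, (3, 3), rng)
        self.conv2 = Conv2d(filters, filters, (3, 3), rng)
        self.in_channels = in_channels
        self.filters = filters

    def __call__(self, x: Tensor) -> Tensor:
        if x.shape[-1] != self.in_channels:
            raise ValueError(
                f"expected {self.in_channels} input channels, got {x.shape[-1]}")
        return self.conv2(self.conv1(x).relu()).relu()
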