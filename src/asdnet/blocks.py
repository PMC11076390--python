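"""Building blocks of the segmentation network.

* :class:`SCSEGate` — concurrent spatial & channel squeeze-and-excitation:
  a channel gate (global average pool -> bottleneck MLP -> sigmoid) and a
  spatial gate (1x1 conv -> sigmoid) each rescale the input, and the two
  gated copies are summed.
* :class:`ASCOBlock` — two stages of asymmetric convolution (parallel
  3x3 + 3x1 + 1x3 kernels whose responses are summed before a single
  batch norm and ReLU), followed by an scSE gate.  The branch sum is
  algebraically equal to one 3x3 convolution with the small kernels
  zero-padded into the 3x3 grid (see :func:`fuse_asymmetric_kernels`).
* :class:`DDECBlock` — a dense block whose last 3x3 convolution is
  dilated, a 1x1 projection of the concatenated features, and an scSE
  gate.  Dense connectivity feeds every layer the concatenation of the
  block input and all previous layer outputs.
* :class:`ASPPBridge` — atrous spatial pyramid pooling: parallel 1x1,
  dilated 3x3 convolutions at several rates, and an image-level pooling
  branch, concatenated and projected.

All blocks use same-padding stride-1 convolutions, so spatial dimensions
are preserved exactly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import nn
from .nn import functional as F
from .nn import (BatchNorm2d, Conv2d, Linear, Module, Tensor, as_tensor,
                 relu, sigmoid)


@dataclass(frozen=True)
class BlockConfig:
    """Hyperparameters of the network's building blocks.

    The dense-block depth, growth rule and final-layer dilation, the scSE
    reduction ratio and the ASPP rates are not dictated by the block
    definitions themselves; they are pinned here so they are auditable
    and serialisable.
    """

    scse_reduction: int = 2
    ddec_layers: int = 4
    ddec_growth_divisor: int = 4  # growth = out_channels / divisor
    ddec_dilation: int = 2
    aspp_rates: tuple[int, ...] = (6, 12, 18)

    def __post_init__(self):
        if self.scse_reduction < 1:
            raise ValueError("scse_reduction must be >= 1")
        if self.ddec_layers < 2:
            raise ValueError("ddec_layers must be >= 2")
        if self.ddec_dilation < 1:
            raise ValueError("ddec_dilation must be >= 1")


class SCSEGate(Module):
    """Concurrent spatial and channel squeeze-and-excitation.

    Output = x * sigmoid(MLP(avgpool(x)))  [channel gate, broadcast over
    space] + x * sigmoid(conv1x1(x))  [spatial gate, broadcast over
    channels].  Each gate lies in (0, 1), so |output| <= 2|input|
    elementwise.
    """

    def __init__(self, channels: int, rng: np.random.Generator, reduction: int = 2):
        super().__init__()
        if channels % reduction:
            raise ValueError(
                f"channels ({channels}) must be divisible by reduction ({reduction})")
        self.channels = channels
        self.fc_squeeze = Linear(channels, channels // reduction, rng)
        self.fc_excite = Linear(channels // reduction, channels, rng)
        self.spatial = Conv2d(channels, 1, 1, rng)

    def forward(self, x: Tensor) -> Tensor:
        x = as_tensor(x)
        n, c, h, w = x.data.shape
        if c != self.channels:
            raise ValueError(f"expected {self.channels} channels, got {c}")
        z = F.global_avg_pool(x).reshape(n, c)
        gate_c = sigmoid(self.fc_excite(relu(self.fc_squeeze(z)))).reshape(n, c, 1, 1)
        y_cse = x * gate_c
        y_sse = x * sigmoid(self.spatial(x))
        return y_cse + y_sse


def scse_gate(x, channels: int, rng=None, reduction: int = 2) -> Tensor:
    """Functional convenience: apply a freshly initialised scSE gate."""
    rng = rng if rng is not None else np.random.default_rng(0)
    return SCSEGate(channels, rng, reduction)(as_tensor(x))


def fuse_asymmetric_kernels(k33, k31, k13, b33=0.0, b31=0.0, b13=0.0):
    """Collapse parallel 3x3 / 3x1 / 1x3 kernels into one 3x3 kernel.

    The small kernels are zero-padded into the centre column / row of the
    3x3 grid and the biases are summed, so convolving with the fused
    kernel reproduces the sum of the three branch convolutions exactly.
    Kernels may carry leading (out, in) axes; only the trailing two are
    checked.
    """
    k33 = np.asarray(k33, dtype=np.float64)
    k31 = np.asarray(k31, dtype=np.float64)
    k13 = np.asarray(k13, dtype=np.float64)
    if k33.shape[-2:] != (3, 3):
        raise ValueError(f"k33 must end in (3, 3), got {k33.shape}")
    if k31.shape[-2:] != (3, 1):
        raise ValueError(f"k31 must end in (3, 1), got {k31.shape}")
    if k13.shape[-2:] != (1, 3):
        raise ValueError(f"k13 must end in (1, 3), got {k13.shape}")
    fused = k33.copy()
    fused[..., :, 1:2] += k31
    fused[..., 1:2, :] += k13
    b_fused = np.asarray(b33) + np.asarray(b31) + np.asarray(b13)
    return fused, b_fused


class AsymmetricConvUnit(Module):
    """One asymmetric-convolution stage: ReLU(BN(conv3x3 + conv3x1 + conv1x3)).

    A single batch norm is applied to the branch sum (not per branch).
    """

    def __init__(self, in_channels: int, out_channels: int, rng: np.random.Generator):
        super().__init__()
        self.conv33 = Conv2d(in_channels, out_channels, 3, rng)
        self.conv31 = Conv2d(in_channels, out_channels, (3, 1), rng)
        self.conv13 = Conv2d(in_channels, out_channels, (1, 3), rng)
        self.bn = BatchNorm2d(out_channels)

    def branch_sum(self, x: Tensor) -> Tensor:
        """The pre-BN response; equals a single fused 3x3 convolution."""
        x = as_tensor(x)
        if x.data.shape[2] < 3 or x.data.shape[3] < 3:
            raise ValueError("asymmetric convolution needs spatial dims >= 3")
        return self.conv33(x) + self.conv31(x) + self.conv13(x)

    def forward(self, x: Tensor) -> Tensor:
        return relu(self.bn(self.branch_sum(x)))


class ASCOBlock(Module):
    """Adaptive spatial-channel convolution optimisation block:
    two asymmetric-convolution stages followed by an scSE gate."""

    def __init__(self, in_channels: int, out_channels: int,
                 rng: np.random.Generator, config: BlockConfig = BlockConfig()):
        super().__init__()
        self.unit1 = AsymmetricConvUnit(in_channels, out_channels, rng)
        self.unit2 = AsymmetricConvUnit(out_channels, out_channels, rng)
        self.scse = SCSEGate(out_channels, rng, config.scse_reduction)

    def forward(self, x: Tensor) -> Tensor:
        y1 = self.unit1(x)
        y2 = self.unit2(y1)
        return self.scse(y2)


class DDECBlock(Module):
    """Dense dilated enhancement convolution block.

    ``L`` dense layers (pre-activation BN -> ReLU -> conv3x3, each seeing
    the concatenation of the block input and all previous layer outputs);
    the final layer's convolution is dilated to enlarge the receptive
    field without extra parameters.  The concatenated features pass a 1x1
    projection and an scSE gate.
    """

    def __init__(self, in_channels: int, out_channels: int,
                 rng: np.random.Generator, config: BlockConfig = BlockConfig()):
        super().__init__()
        self.config = config
        growth = max(out_channels // config.ddec_growth_divisor, 1)
        self.growth = growth
        self.dense_layers: list[tuple[BatchNorm2d, Conv2d]] = []
        ch = in_channels
        for i in range(config.ddec_layers):
            dilation = config.ddec_dilation if i == config.ddec_layers - 1 else 1
            bn = BatchNorm2d(ch)
            conv = Conv2d(ch, growth, 3, rng, dilation=dilation)
            setattr(self, f"bn{i}", bn)
            setattr(self, f"conv{i}", conv)
            self.dense_layers.append((bn, conv))
            ch += growth
        self.proj = Conv2d(ch, out_channels, 1, rng)
        self.scse = SCSEGate(out_channels, rng, config.scse_reduction)

    def forward(self, x: Tensor) -> Tensor:
        x = as_tensor(x)
        h, w = x.data.shape[2], x.data.shape[3]
        if h < 1 or w < 1:
            raise ValueError(
                f"spatial extent {h}x{w} too small for the dilated kernel")
        features = x
        for bn, conv in self.dense_layers:
            out = conv(relu(bn(features)))
            features = nn.concat([features, out], axis=1)
        return self.scse(self.proj(features))


class ASPPBridge(Module):
    """Atrous spatial pyramid pooling between encoder and decoder.

    Parallel branches: 1x1 conv, dilated 3x3 convs at the configured
    rates, and global-average-pool -> 1x1 -> upsample; each branch is
    conv -> BN -> ReLU.  Branch outputs are concatenated and projected by
    a 1x1 conv.
    """

    def __init__(self, in_channels: int, out_channels: int,
                 rng: np.random.Generator, config: BlockConfig = BlockConfig()):
        super().__init__()
        self.rates = tuple(config.aspp_rates)
        self.conv1 = Conv2d(in_channels, out_channels, 1, rng)
        self.bn1 = BatchNorm2d(out_channels)
        self.dilated: list[tuple[Conv2d, BatchNorm2d]] = []
        for i, rate in enumerate(self.rates):
            conv = Conv2d(in_channels, out_channels, 3, rng, dilation=rate)
            bn = BatchNorm2d(out_channels)
            setattr(self, f"dconv{i}", conv)
            setattr(self, f"dbn{i}", bn)
            self.dilated.append((conv, bn))
        self.pool_conv = Conv2d(in_channels, out_channels, 1, rng)
        self.pool_bn = BatchNorm2d(out_channels)
        n_branches = 2 + len(self.rates)
        self.proj = Conv2d(n_branches * out_channels, out_channels, 1, rng)
        self.proj_bn = BatchNorm2d(out_channels)

    def forward(self, x: Tensor) -> Tensor:
        x = as_tensor(x)
        h, w = x.data.shape[2], x.data.shape[3]
        branches = [relu(self.bn1(self.conv1(x)))]
        for conv, bn in self.dilated:
            branches.append(relu(bn(conv(x))))
        pooled = relu(self.pool_bn(self.pool_conv(F.global_avg_pool(x))))
        branches.append(F.broadcast_hw(pooled, h, w))
        return relu(self.proj_bn(self.proj(nn.concat(branches, axis=1))))


def receptive_field_3x3(dilation: int) -> int:
    """Receptive field (pixels) of a dilated 3x3 kernel: 2*rate + 1."""
    return 2 * dilation + 1
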