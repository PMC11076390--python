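"""Assembly of the dual-encoder/single-decoder segmentation network.

The network is a five-scale U-Net variant with:

* **Encoder 1** — plain U-Net feature extractor: per level, two 3x3
  conv + BN + ReLU, then 2x2 max pooling between levels.
* **Encoder 2** — the attention path: per level, an ASCO block, a DDEC
  block and an scSE gate.  At every level the same-scale encoder-1
  output is concatenated into the encoder-2 stage input, interconnecting
  the two paths layer by layer.
* **ASPP bridge** between the deepest encoder-2 feature and the decoder.
* **Decoder** — per level, 2x2 transposed-conv upsampling, concatenation
  with the same-level encoder-2 feature, and two 3x3 conv + BN + ReLU.
  The full-resolution (top) skip connection is removed by default: the
  last decoder stage consumes only upsampled features, so low-level
  noise is not passed straight to the output.
* **Head** — a 1x1 convolution emitting one logit channel (binary task;
  kidney and tumor are trained as separate models).

A plain single-encoder :class:`UNet` of matched width is provided as the
ablation baseline.
"""

from __future__ import annotations

import io
import warnings
from dataclasses import dataclass, field, asdict

import numpy as np

from . import nn
from .nn import functional as F
from .nn import BatchNorm2d, Conv2d, ConvTranspose2x2, Module, Tensor, as_tensor, relu
from .blocks import ASCOBlock, ASPPBridge, BlockConfig, DDECBlock, SCSEGate


@dataclass(frozen=True)
class NetworkConfig:
    """Architecture hyperparameters.

    Channel plan: ``base_channels * 2**(level-1)`` capped at
    ``max_channels`` (default 32 -> 64 -> 128 -> 256 -> 512).
    """

    depth: int = 5
    base_channels: int = 32
    max_channels: int = 512
    in_channels: int = 1
    out_classes: int = 1
    use_top_skip: bool = False
    block: BlockConfig = field(default_factory=BlockConfig)

    def __post_init__(self):
        if self.depth < 3:
            raise ValueError("depth must be >= 3")
        if self.base_channels < self.block.scse_reduction:
            raise ValueError("base_channels too small for the scSE reduction")

    def channels(self, level: int) -> int:
        return min(self.base_channels * 2 ** (level - 1), self.max_channels)

    @property
    def downsample_factor(self) -> int:
        return 2 ** (self.depth - 1)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["block"]["aspp_rates"] = list(d["block"]["aspp_rates"])
        return d

    @staticmethod
    def from_dict(d: dict) -> "NetworkConfig":
        d = dict(d)
        blk = d.pop("block", {})
        if "aspp_rates" in blk:
            blk["aspp_rates"] = tuple(blk["aspp_rates"])
        return NetworkConfig(block=BlockConfig(**blk), **d)


class _ConvBNReLU(Module):
    def __init__(self, cin: int, cout: int, rng: np.random.Generator):
        super().__init__()
        self.conv = Conv2d(cin, cout, 3, rng)
        self.bn = BatchNorm2d(cout)

    def forward(self, x):
        return relu(self.bn(self.conv(x)))


class _DoubleConv(Module):
    def __init__(self, cin: int, cout: int, rng: np.random.Generator):
        super().__init__()
        self.a = _ConvBNReLU(cin, cout, rng)
        self.b = _ConvBNReLU(cout, cout, rng)

    def forward(self, x):
        return self.b(self.a(x))


class _Encoder2Stage(Module):
    def __init__(self, cin: int, cout: int, rng, block: BlockConfig):
        super().__init__()
        self.asco = ASCOBlock(cin, cout, rng, block)
        self.ddec = DDECBlock(cout, cout, rng, block)
        self.scse = SCSEGate(cout, rng, block.scse_reduction)

    def forward(self, x):
        return self.scse(self.ddec(self.asco(x)))


class _DecoderStage(Module):
    def __init__(self, cin_up: int, cout: int, has_skip: bool, rng):
        super().__init__()
        self.has_skip = has_skip
        self.up = ConvTranspose2x2(cin_up, cout, rng)
        self.convs = _DoubleConv(cout * 2 if has_skip else cout, cout, rng)

    def forward(self, x, skip=None):
        x = self.up(x)
        if self.has_skip:
            if skip is None:
                raise ValueError("decoder stage expects a skip feature")
            x = nn.concat([x, skip], axis=1)
        return self.convs(x)


def _check_input(x: Tensor, config: NetworkConfig) -> Tensor:
    x = as_tensor(x)
    if x.data.ndim != 4:
        raise ValueError(f"expected (batch, channels, H, W), got shape {x.data.shape}")
    n, c, h, w = x.data.shape
    if c != config.in_channels:
        raise ValueError(f"expected {config.in_channels} input channels, got {c}")
    f = config.downsample_factor
    if h % f or w % f:
        raise ValueError(
            f"spatial dims {h}x{w} must be divisible by {f} (depth {config.depth})")
    return x


class ASDNet(Module):
    """The dual-encoder attention segmentation network."""

    def __init__(self, config: NetworkConfig = NetworkConfig(), seed: int = 0):
        super().__init__()
        self.config = config
        rng = np.random.default_rng(seed)
        d = config.depth
        ch = [config.channels(l) for l in range(1, d + 1)]

        for l in range(1, d + 1):
            cin = config.in_channels if l == 1 else ch[l - 2]
            setattr(self, f"enc1_{l}", _DoubleConv(cin, ch[l - 1], rng))
        for l in range(1, d + 1):
            cin = (config.in_channels if l == 1 else ch[l - 2]) + ch[l - 1]
            setattr(self, f"enc2_{l}", _Encoder2Stage(cin, ch[l - 1], rng, config.block))
        self.aspp = ASPPBridge(ch[d - 1], ch[d - 1], rng, config.block)
        for l in range(d - 1, 0, -1):
            has_skip = (l > 1) or config.use_top_skip
            setattr(self, f"dec_{l}", _DecoderStage(ch[l], ch[l - 1], has_skip, rng))
        self.head = Conv2d(ch[0], config.out_classes, 1, rng)
        # bias toward background at initialisation: segmentation foregrounds
        # are sparse, and starting near the class prior avoids spending the
        # first epochs unlearning a 50% foreground prediction
        self.head.bias.data[:] = -2.0

    def forward(self, x) -> Tensor:
        cfg = self.config
        x = _check_input(x, cfg)
        d = cfg.depth

        e1: list[Tensor] = []
        f = x
        for l in range(1, d + 1):
            if l > 1:
                f = F.max_pool2d(f)
            f = getattr(self, f"enc1_{l}")(f)
            e1.append(f)

        e2: list[Tensor] = []
        for l in range(1, d + 1):
            carry = x if l == 1 else F.max_pool2d(e2[-1])
            g = getattr(self, f"enc2_{l}")(nn.concat([carry, e1[l - 1]], axis=1))
            e2.append(g)

        h = self.aspp(e2[-1])
        for l in range(d - 1, 0, -1):
            stage: _DecoderStage = getattr(self, f"dec_{l}")
            h = stage(h, e2[l - 1] if stage.has_skip else None)
        return self.head(h)


class UNet(Module):
    """Plain single-encoder U-Net of matched width (ablation baseline).

    Same double-conv stages, max pooling, transposed-conv upsampling and
    1x1 head as the main network, with skip connections at every level
    (including the top one) and no attention blocks.
    """

    def __init__(self, config: NetworkConfig = NetworkConfig(), seed: int = 0):
        super().__init__()
        self.config = config
        rng = np.random.default_rng(seed)
        d = config.depth
        ch = [config.channels(l) for l in range(1, d + 1)]
        for l in range(1, d + 1):
            cin = config.in_channels if l == 1 else ch[l - 2]
            setattr(self, f"enc_{l}", _DoubleConv(cin, ch[l - 1], rng))
        for l in range(d - 1, 0, -1):
            setattr(self, f"dec_{l}", _DecoderStage(ch[l], ch[l - 1], True, rng))
        self.head = Conv2d(ch[0], config.out_classes, 1, rng)
        self.head.bias.data[:] = -2.0  # background prior, as in the main model

    def forward(self, x) -> Tensor:
        cfg = self.config
        x = _check_input(x, cfg)
        d = cfg.depth
        feats = []
        f = x
        for l in range(1, d + 1):
            if l > 1:
                f = F.max_pool2d(f)
            f = getattr(self, f"enc_{l}")(f)
            feats.append(f)
        h = feats[-1]
        for l in range(d - 1, 0, -1):
            h = getattr(self, f"dec_{l}")(h, feats[l - 1])
        return self.head(h)


def build_network(config: NetworkConfig = NetworkConfig(), seed: int = 0,
                  arch: str = "asdnet") -> Module:
    """Construct a segmentation model (``asdnet`` or the ``unet`` baseline)."""
    if arch == "asdnet":
        return ASDNet(config, seed)
    if arch == "unet":
        return UNet(config, seed)
    raise ValueError(f"unknown architecture {arch!r}")


def predict_mask(model: Module, image: np.ndarray, threshold: float = 0.5,
                 ) -> np.ndarray:
    """Binary prediction: sigmoid(logits) >= threshold (ties are foreground).

    ``image`` may be a single 2-D slice or a (batch, 1, H, W) array of
    normalised intensities in [0, 1].
    """
    if not 0.0 < threshold < 1.0:
        raise ValueError("threshold must lie in (0, 1)")
    arr = np.asarray(image, dtype=np.float32)
    squeeze = arr.ndim == 2
    if squeeze:
        arr = arr[None, None]
    if arr.min() < -1e-6 or arr.max() > 1.0 + 1e-6:
        warnings.warn("input intensities outside [0, 1]; was the image normalised?",
                      stacklevel=2)
    was_training = model.training
    model.eval()
    try:
        with nn.no_grad():
            logits = model(Tensor(arr)).data
    finally:
        model.train(was_training)
    probs = 1.0 / (1.0 + np.exp(-logits.astype(np.float64)))
    mask = (probs >= threshold).astype(np.uint8)
    return mask[0, 0] if squeeze else mask


def summary(model: Module) -> str:
    """Plain-text architecture summary (per-parameter-tensor shapes)."""
    buf = io.StringIO()
    total = 0
    for name, p in model.named_parameters():
        buf.write(f"{name:60s} {str(p.data.shape):20s} {p.data.size}\n")
        total += p.data.size
    buf.write(f"{'total parameters':60s} {'':20s} {total}\n")
    return buf.getvalue()


def save_checkpoint(model: Module, path) -> None:
    """Save weights (and running statistics) as a compressed npz."""
    np.savez_compressed(path, **model.state_dict())


def load_checkpoint(model: Module, path) -> Module:
    with np.load(path) as data:
        model.load_state_dict({k: data[k] for k in data.files})
    return model
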