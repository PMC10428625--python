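"""Multi-scale feature-fusion segmentation network (MSSNet).

The network is an encoder–decoder for per-pixel crop classification:

* a ResNet-style backbone tapped at two depths — a low-level feature map at
  1/4 resolution with 64 channels and a high-level map at 1/16 resolution
  with 256 channels;
* a receptive-field block (RFB): four branches mixing plain and dilated
  convolutions at distinct rates, fused by a 3×3 convolution and added to a
  1×1-projected identity shortcut;
* a decoder with two 4× bilinear upsamplings and one skip concatenation of
  the low-level tap, followed by small convolution stacks and a 1×1
  softmax classifier.

For the default 256×256×3 input the canonical checkpoint shapes are
64×64×64 (low tap), 16×16×256 (high tap), 16×16×768 (RFB out),
16×16×512, 64×64×512, 64×64×576 (post-skip), 64×64×256 and 256×256×K.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import nn


# ---------------------------------------------------------------------------
# convolution output-size arithmetic


@dataclass(frozen=True)
class ConvGeometry:
    """Geometry of a (possibly dilated) 2-D convolution, per axis."""

    h_in: int
    w_in: int
    kernel: tuple[int, int] = (3, 3)
    stride: tuple[int, int] = (1, 1)
    padding: tuple[int, int] = (0, 0)
    atrous: tuple[int, int] = (1, 1)

    def __post_init__(self):
        for name in ("h_in", "w_in"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        for name in ("kernel", "stride", "atrous"):
            if min(getattr(self, name)) < 1:
                raise ValueError(f"{name} entries must be >= 1")
        if min(self.padding) < 0:
            raise ValueError("padding must be >= 0")


def conv_output_size(g: ConvGeometry) -> tuple[int, int]:
    """Output height and width of a dilated convolution.

    out = floor((in + 2*padding - atrous*(kernel-1) - 1) / stride) + 1,
    applied independently to each axis.  Raises ``ValueError`` when the
    (dilated) kernel does not fit in the padded input.
    """
    out = []
    for size, k, s, p, a in zip(
        (g.h_in, g.w_in), g.kernel, g.stride, g.padding, g.atrous
    ):
        o = (size + 2 * p - a * (k - 1) - 1) // s + 1
        if o < 1:
            raise ValueError(
                f"non-positive output size {o} for input {size}, kernel {k}, "
                f"stride {s}, padding {p}, dilation {a}"
            )
        out.append(o)
    return out[0], out[1]


# ---------------------------------------------------------------------------
# configuration


@dataclass
class ModelConfig:
    """Hyperparameters of the segmentation network.

    Defaults reproduce the published architecture: 256×256×3 input, three
    crop classes, RFB dilation rates (1, 3, 5) for branches 2–4, RFB fusion
    width 768, decoder widths 512 then 256.  ``backbone="reduced"`` halves
    the residual-block counts (desk-scale training) while preserving both
    tap shapes.
    """

    input_size: int = 256
    in_channels: int = 3
    n_classes: int = 3
    backbone: str = "full"  # "full" | "reduced"
    rfb_dilations: tuple[int, int, int] = (1, 3, 5)
    rfb_out_channels: int = 768
    decoder_channels: tuple[int, int] = (512, 256)
    upsample_mode: str = "bilinear"  # "bilinear" | "transposed"
    seed: int = 0

    # tap widths fixed by the architecture contract
    low_channels: int = 64
    high_channels: int = 256

    def __post_init__(self):
        if self.input_size % 16 != 0:
            raise ValueError("input_size must be divisible by 16")
        if self.backbone not in ("full", "reduced"):
            raise ValueError(f"unknown backbone preset {self.backbone!r}")
        if self.upsample_mode not in ("bilinear", "transposed"):
            raise ValueError(f"unknown upsample_mode {self.upsample_mode!r}")
        if len(self.rfb_dilations) != 3:
            raise ValueError("rfb_dilations must list rates for branches 2-4")


CHECKPOINTS = (
    "backbone_low",
    "backbone_high",
    "rfb_out",
    "pre_upsample1",
    "post_upsample1",
    "post_skip_concat",
    "post_decoder2",
    "logits",
)


@dataclass
class ShapeTrace:
    """(H, W, C) recorded at the canonical checkpoints of a forward pass."""

    shapes: dict[str, tuple[int, int, int]] = field(default_factory=dict)

    def __getitem__(self, key: str) -> tuple[int, int, int]:
        return self.shapes[key]

    def as_table(self) -> str:
        width = max(len(k) for k in self.shapes)
        lines = [f"{k.ljust(width)}  {h} x {w} x {c}" for k, (h, w, c) in self.shapes.items()]
        return "\n".join(lines)

    def to_dict(self) -> dict[str, list[int]]:
        return {k: list(v) for k, v in self.shapes.items()}


def _upsample(mode: str, scale: int, channels: int, rng) -> nn.Layer:
    if mode == "bilinear":
        return nn.BilinearUpsample(scale)
    # transposed convolution alternative: kernel 2*scale, stride scale
    raise NotImplementedError("transposed upsampling is not implemented; use bilinear")


# ---------------------------------------------------------------------------
# backbone


class Backbone(nn.Layer):
    """ResNet-style trunk with two tap points.

    Stage 0 is a 7×7/2 convolution plus 3×3/2 max-pool giving the low-level
    tap at 1/4 resolution with 64 channels; three stages of basic residual
    blocks (64 → 128 → 256 channels, strides 1/2/2) give the high-level tap
    at 1/16 resolution with 256 channels.  The "full" preset uses (3, 4, 6)
    blocks per stage, the "reduced" preset (2, 2, 3).
    """

    def __init__(self, cfg: ModelConfig, rng: np.random.Generator):
        blocks = {"full": (3, 4, 6), "reduced": (2, 2, 3)}[cfg.backbone]
        c_low, c_high = cfg.low_channels, cfg.high_channels
        self.stage0 = nn.Sequential(
            nn.Conv2d(cfg.in_channels, c_low, 7, stride=2, padding=3, bias=False, rng=rng),
            nn.BatchNorm2d(c_low),
            nn.ReLU(),
            nn.MaxPool2d(3, 2, 1),
        )
        widths = (c_low, c_low * 2, c_high)
        strides = (1, 2, 2)
        stages = []
        in_ch = c_low
        for n_blocks, width, stride in zip(blocks, widths, strides):
            for b in range(n_blocks):
                stages.append(
                    nn.ResidualBlock(in_ch, width, stride=stride if b == 0 else 1, rng=rng)
                )
                in_ch = width
        self.stages = nn.Sequential(*stages)

    def params(self):
        return self.stage0.params() + self.stages.params()

    def forward(self, x, train: bool = False):
        """Return (low_tap, high_tap) feature maps."""
        low = self.stage0.forward(x, train=train)
        high = self.stages.forward(low, train=train)
        return low, high

    def backward_taps(self, d_low, d_high):
        d_mid = self.stages.backward(d_high)
        return self.stage0.backward(d_mid + d_low)


def build_backbone(cfg: ModelConfig | None = None) -> Backbone:
    cfg = cfg or ModelConfig()
    rng = np.random.default_rng(cfg.seed)
    return Backbone(cfg, rng)


# ---------------------------------------------------------------------------
# multi-scale fusion blocks


class RFB(nn.Layer):
    """Receptive-field block.

    Branch 1 is an identity shortcut projected to the fusion width by a 1×1
    convolution.  Branch 2 is a 3×3 convolution followed by a dilated 3×3
    at rate d2; branches 3 and 4 are two 3×3 convolutions followed by
    dilated 3×3 at rates d3 and d4.  Branches 2–4 (each keeping the input
    width) are concatenated, fused by a 3×3 convolution to ``out_channels``
    and added to the projected shortcut.  Spatial size is preserved
    throughout (dilated convolutions get padding = rate·(kernel−1)/2).
    """

    def __init__(
        self,
        in_channels: int,
        dilations: tuple[int, int, int] = (1, 3, 5),
        out_channels: int = 768,
        rng: np.random.Generator | None = None,
    ):
        rng = rng if rng is not None else np.random.default_rng()
        self.in_channels, self.out_channels = in_channels, out_channels
        self.dilations = tuple(dilations)
        b = in_channels
        d2, d3, d4 = self.dilations
        self.shortcut = nn.Sequential(
            nn.Conv2d(in_channels, out_channels, 1, bias=False, rng=rng),
            nn.BatchNorm2d(out_channels),
        )
        self.branch2 = nn.Sequential(
            nn.conv_bn_relu(in_channels, b, 3, rng=rng),
            nn.conv_bn_relu(b, b, 3, dilation=d2, rng=rng),
        )
        self.branch3 = nn.Sequential(
            nn.conv_bn_relu(in_channels, b, 3, rng=rng),
            nn.conv_bn_relu(b, b, 3, rng=rng),
            nn.conv_bn_relu(b, b, 3, dilation=d3, rng=rng),
        )
        self.branch4 = nn.Sequential(
            nn.conv_bn_relu(in_channels, b, 3, rng=rng),
            nn.conv_bn_relu(b, b, 3, rng=rng),
            nn.conv_bn_relu(b, b, 3, dilation=d4, rng=rng),
        )
        self.fuse = nn.Sequential(
            nn.Conv2d(3 * b, out_channels, 3, padding=1, bias=False, rng=rng),
            nn.BatchNorm2d(out_channels),
        )
        self._mask = None

    def params(self):
        return (
            self.shortcut.params()
            + self.branch2.params()
            + self.branch3.params()
            + self.branch4.params()
            + self.fuse.params()
        )

    def branch_outputs(self, x, train: bool = False):
        """Outputs of branches 2-4 (used for inspection and shape checks)."""
        return (
            self.branch2.forward(x, train=train),
            self.branch3.forward(x, train=train),
            self.branch4.forward(x, train=train),
        )

    def forward(self, x, train: bool = False):
        if x.shape[1] != self.in_channels:
            raise ValueError(
                f"RFB expects {self.in_channels} channels, got {x.shape[1]}"
            )
        b2, b3, b4 = self.branch_outputs(x, train=train)
        fused = self.fuse.forward(np.concatenate([b2, b3, b4], axis=1), train=train)
        out = fused + self.shortcut.forward(x, train=train)
        if train:
            self._mask = out > 0
        return np.maximum(out, 0.0)

    def backward(self, dy):
        d = dy * self._mask
        self._mask = None
        dcat = self.fuse.backward(d)
        b = self.in_channels
        dx = self.branch2.backward(dcat[:, :b])
        dx = dx + self.branch3.backward(dcat[:, b : 2 * b])
        dx = dx + self.branch4.backward(dcat[:, 2 * b :])
        return dx + self.shortcut.backward(d)


def build_rfb(
    in_channels: int = 256,
    dilations: tuple[int, int, int] = (1, 3, 5),
    out_channels: int = 768,
    seed: int = 0,
) -> RFB:
    return RFB(in_channels, dilations, out_channels, rng=np.random.default_rng(seed))


class ASPP(nn.Layer):
    """Atrous spatial pyramid pooling: parallel dilated 3×3 convolutions.

    Drop-in alternative to the RFB for ablation: four branches at the given
    dilation rates, concatenated and fused by a 1×1 convolution.
    """

    def __init__(
        self,
        in_channels: int,
        rates: tuple[int, int, int, int] = (1, 2, 4, 8),
        out_channels: int = 768,
        rng: np.random.Generator | None = None,
    ):
        rng = rng if rng is not None else np.random.default_rng()
        self.in_channels, self.out_channels = in_channels, out_channels
        self.rates = tuple(rates)
        self.branches = [
            nn.conv_bn_relu(in_channels, in_channels, 3, dilation=r, rng=rng)
            for r in self.rates
        ]
        self.fuse = nn.conv_bn_relu(len(self.rates) * in_channels, out_channels, 1, rng=rng)

    def params(self):
        return [p for br in self.branches for p in br.params()] + self.fuse.params()

    def forward(self, x, train: bool = False):
        outs = [br.forward(x, train=train) for br in self.branches]
        return self.fuse.forward(np.concatenate(outs, axis=1), train=train)

    def backward(self, dy):
        dcat = self.fuse.backward(dy)
        b = self.in_channels
        dx = None
        for i, br in enumerate(self.branches):
            d = br.backward(dcat[:, i * b : (i + 1) * b])
            dx = d if dx is None else dx + d
        return dx


def build_aspp(
    in_channels: int = 256,
    rates: tuple[int, ...] = (1, 2, 4, 8),
    out_channels: int = 768,
    seed: int = 0,
) -> ASPP:
    return ASPP(in_channels, tuple(rates), out_channels, rng=np.random.default_rng(seed))


# ---------------------------------------------------------------------------
# full network


class MSSNet(nn.Layer):
    """Encoder–decoder with RFB fusion and one low-level skip connection."""

    def __init__(self, cfg: ModelConfig):
        self.cfg = cfg
        rng = np.random.default_rng(cfg.seed)
        d1, d2 = cfg.decoder_channels
        self.backbone = Backbone(cfg, rng)
        self.rfb = RFB(cfg.high_channels, cfg.rfb_dilations, cfg.rfb_out_channels, rng=rng)
        self.reduce = nn.Sequential(
            nn.conv_bn_relu(cfg.rfb_out_channels, d1, 3, rng=rng),
            nn.conv_bn_relu(d1, d1, 3, rng=rng),
            nn.conv_bn_relu(d1, d1, 3, rng=rng),
        )
        self.up1 = _upsample(cfg.upsample_mode, 4, d1, rng)
        self.decode = nn.Sequential(
            nn.conv_bn_relu(d1 + cfg.low_channels, d2, 3, rng=rng),
            nn.conv_bn_relu(d2, d2, 3, rng=rng),
            nn.conv_bn_relu(d2, d2, 3, rng=rng),
        )
        self.up2 = _upsample(cfg.upsample_mode, 4, d2, rng)
        self.head = nn.Sequential(
            *[nn.conv_bn_relu(d2, d2, 3, rng=rng) for _ in range(4)]
        )
        self.classifier = nn.Conv2d(d2, cfg.n_classes, 1, bias=True, rng=rng)
        self.last_trace: ShapeTrace | None = None

    def params(self):
        return (
            self.backbone.params()
            + self.rfb.params()
            + self.reduce.params()
            + self.decode.params()
            + self.head.params()
            + self.classifier.params()
        )

    @staticmethod
    def _hwc(t: np.ndarray) -> tuple[int, int, int]:
        return (t.shape[2], t.shape[3], t.shape[1])

    def forward_logits(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        """NCHW logits; records a ShapeTrace on ``last_trace``."""
        tr = ShapeTrace()
        low, high = self.backbone.forward(x, train=train)
        tr.shapes["backbone_low"] = self._hwc(low)
        tr.shapes["backbone_high"] = self._hwc(high)
        y = self.rfb.forward(high, train=train)
        tr.shapes["rfb_out"] = self._hwc(y)
        y = self.reduce.forward(y, train=train)
        tr.shapes["pre_upsample1"] = self._hwc(y)
        y = self.up1.forward(y, train=train)
        tr.shapes["post_upsample1"] = self._hwc(y)
        y = np.concatenate([y, low], axis=1)
        tr.shapes["post_skip_concat"] = self._hwc(y)
        self._skip_channels = self.cfg.decoder_channels[0]
        y = self.decode.forward(y, train=train)
        tr.shapes["post_decoder2"] = self._hwc(y)
        y = self.up2.forward(y, train=train)
        y = self.head.forward(y, train=train)
        logits = self.classifier.forward(y, train=train)
        tr.shapes["logits"] = self._hwc(logits)
        self.last_trace = tr
        return logits

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        """Per-pixel class probabilities (softmax over channels)."""
        return nn.softmax_channels(self.forward_logits(x, train=train))

    def backward(self, dlogits: np.ndarray) -> np.ndarray:
        d = self.classifier.backward(dlogits)
        d = self.head.backward(d)
        d = self.up2.backward(d)
        d = self.decode.backward(d)
        d_up, d_low = d[:, : self._skip_channels], d[:, self._skip_channels :]
        d = self.up1.backward(d_up)
        d = self.reduce.backward(d)
        d = self.rfb.backward(d)
        return self.backbone.backward_taps(d_low, d)


def build_mssnet(cfg: ModelConfig | None = None) -> MSSNet:
    return MSSNet(cfg or ModelConfig())


def shape_trace(model: MSSNet, input_shape: tuple[int, int, int] | None = None) -> ShapeTrace:
    """Record (H, W, C) at the canonical checkpoints by one forward pass on zeros."""
    if input_shape is None:
        input_shape = (model.cfg.input_size, model.cfg.input_size, model.cfg.in_channels)
    h, w, c = input_shape
    x = np.zeros((1, c, h, w), dtype=np.float32)
    model.forward_logits(x, train=False)
    assert model.last_trace is not None
    missing = [k for k in CHECKPOINTS if k not in model.last_trace.shapes]
    if missing:
        raise RuntimeError(f"trace missing checkpoints: {missing}")
    return model.last_trace
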