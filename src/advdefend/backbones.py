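"""Feature-extractor backbones: a runnable tiny CNN and analytic catalogs.

The transfer-learning and stacked classifiers are defined over ImageNet
backbones (VGG16, VGG19, MobileNetV2, DenseNet169).  Their pretrained
weights are not shippable here, so those names resolve to *summary-only*
handles: the layer walk reproduces the published output shapes and
parameter counts exactly (e.g. MobileNetV2 at 224 emits a (7, 7, 1280)
feature map with 2,257,984 parameters), while forward/gradient calls raise
a :class:`~advdefend.errors.CapabilityError` directing the caller to the
always-available ``tinycnn`` backbone.  Every runnable code path in the
package (training, attacks, defense) uses ``tinycnn``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import nn
from .errors import CapabilityError, ShapeError

KNOWN_BACKBONES = ("tinycnn", "vgg16", "vgg19", "mobilenetv2_1.00_224",
                   "densenet169")


@dataclass
class BackboneSpec:
    """Which feature extractor to build and at what input size."""

    name: str = "tinycnn"
    input_size: int = 224
    frozen: bool = True
    width: int = 32  # final feature channels; tinycnn only

    def __post_init__(self) -> None:
        if self.name not in KNOWN_BACKBONES:
            raise CapabilityError(
                f"unknown backbone '{self.name}'; known: {KNOWN_BACKBONES}")


@dataclass
class BackboneHandle:
    """A feature extractor plus its summary metadata.

    ``network`` is None for summary-only pretrained catalogs; such handles
    support shape/parameter queries but not computation.
    """

    spec: BackboneSpec
    output_shape: tuple[int, int, int]  # (h, w, c)
    params_total: int
    params_trainable: int
    layer_summary: list = field(default_factory=list)
    network: "nn.Network | None" = None

    @property
    def name(self) -> str:
        return self.spec.name

    @property
    def feature_width(self) -> int:
        return int(self.output_shape[-1])

    @property
    def runnable(self) -> bool:
        return self.network is not None

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        if self.network is None:
            raise CapabilityError(
                f"backbone '{self.name}' has no weights available offline; "
                "build it with pretrained weights in a framework environment, "
                "or use the 'tinycnn' backbone which needs none")
        if x.shape[1] != self.spec.input_size:
            raise ShapeError(
                f"backbone '{self.name}' expects {self.spec.input_size}px "
                f"input, got {x.shape[1]}")
        return self.network.forward(x, training=training)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        if self.network is None:
            raise CapabilityError(
                f"backbone '{self.name}' is summary-only and cannot "
                "backpropagate; use 'tinycnn'")
        return self.network.backward(dy)


# ---------------------------------------------------------------------
# analytic layer walks (summary-only catalogs)
# ---------------------------------------------------------------------

def _bn(c: int) -> int:
    # gamma, beta, moving mean, moving variance
    return 4 * c


def _vgg_summary(cfg, size: int):
    """VGG conv stack: 3x3 convs (with bias) and 2x2 max pools."""
    rows, c_in, total = [], 3, 0
    for item in cfg:
        if item == "M":
            size //= 2
            rows.append(("MaxPool2D", (size, size, c_in), 0))
        else:
            p = 9 * c_in * item + item
            total += p
            rows.append((f"Conv2D({c_in}->{item})", (size, size, item), p))
            c_in = item
    return rows, (size, size, c_in), total


_VGG16 = [64, 64, "M", 128, 128, "M", 256, 256, 256, "M",
          512, 512, 512, "M", 512, 512, 512, "M"]
_VGG19 = [64, 64, "M", 128, 128, "M", 256, 256, 256, 256, "M",
          512, 512, 512, 512, "M", 512, 512, 512, 512, "M"]

# MobileNetV2 inverted-residual groups: (expansion, out channels, repeats, stride)
_MOBILENETV2_BLOCKS = [(1, 16, 1, 1), (6, 24, 2, 2), (6, 32, 3, 2),
                       (6, 64, 4, 2), (6, 96, 3, 1), (6, 160, 3, 2),
                       (6, 320, 1, 1)]


def _mobilenetv2_summary(size: int):
    rows, total = [], 0

    def add(name, shape, p):
        nonlocal total
        rows.append((name, shape, p))
        total += p

    size //= 2
    add("Conv2D(3->32, stride 2) + BN", (size, size, 32), 9 * 3 * 32 + _bn(32))
    c_in = 32
    for t, c_out, n, stride in _MOBILENETV2_BLOCKS:
        for i in range(n):
            s = stride if i == 0 else 1
            size //= s
            mid = t * c_in
            p = 0
            if t != 1:
                p += c_in * mid + _bn(mid)          # expand 1x1, no bias
            p += 9 * mid + _bn(mid)                 # depthwise 3x3
            p += mid * c_out + _bn(c_out)           # project 1x1
            add(f"InvertedResidual(t={t}, {c_in}->{c_out}, s={s})",
                (size, size, c_out), p)
            c_in = c_out
    add("Conv2D(320->1280, 1x1) + BN", (size, size, 1280),
        320 * 1280 + _bn(1280))
    return rows, (size, size, 1280), total


def _densenet169_summary(size: int):
    """DenseNet169 feature extractor: growth 32, blocks (6, 12, 32, 32)."""
    rows, total = [], 0
    growth, blocks = 32, (6, 12, 32, 32)

    def add(name, shape, p):
        nonlocal total
        rows.append((name, shape, p))
        total += p

    size //= 2
    add("Conv2D(3->64, 7x7, stride 2) + BN", (size, size, 64),
        49 * 3 * 64 + _bn(64))
    size //= 2
    add("MaxPool2D(3x3, stride 2)", (size, size, 64), 0)
    c = 64
    for bi, n_layers in enumerate(blocks):
        p = 0
        for _ in range(n_layers):
            mid = 4 * growth
            p += _bn(c) + c * mid          # BN + 1x1 bottleneck, no bias
            p += _bn(mid) + 9 * mid * growth  # BN + 3x3 conv, no bias
            c += growth
        add(f"DenseBlock{bi + 1}({n_layers} layers)", (size, size, c), p)
        if bi < len(blocks) - 1:
            p = _bn(c) + c * (c // 2)
            c //= 2
            size //= 2
            add(f"Transition{bi + 1}", (size, size, c), p)
    add("BatchNorm", (size, size, c), _bn(c))
    return rows, (size, size, c), total


# ---------------------------------------------------------------------
# the runnable tiny CNN
# ---------------------------------------------------------------------

def _tinycnn_network(width: int, seed: int, dtype=np.float32) -> nn.Network:
    """Two conv/pool stages ending at ``width`` feature channels.

    Operates on 3-channel input (grayscale is replicated upstream) so the
    channel-replication contract matches the pretrained backbones.
    """
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0xB0]))
    c1 = max(width // 2, 4)
    return nn.Network([
        nn.Conv2D(3, c1, rng=rng, dtype=dtype),
        nn.ReLU(),
        nn.MaxPool2D(2),
        nn.Conv2D(c1, width, rng=rng, dtype=dtype),
        nn.ReLU(),
        nn.MaxPool2D(2),
    ])


def build_backbone(spec: BackboneSpec, *, seed: int = 0,
                   dtype=np.float32) -> BackboneHandle:
    """Build (tinycnn) or catalog (pretrained names) a feature extractor."""
    size = spec.input_size
    if spec.name == "tinycnn":
        if size % 4:
            raise ShapeError("tinycnn needs input_size divisible by 4 "
                             "(two 2x2 poolings)")
        net = _tinycnn_network(spec.width, seed, dtype)
        rows = net.summary((1, size, size, 3))
        return BackboneHandle(
            spec=spec,
            output_shape=(size // 4, size // 4, spec.width),
            params_total=net.n_params(),
            params_trainable=0 if spec.frozen else net.n_trainable(),
            layer_summary=[(n, s[1:], p) for n, s, p in rows],
            network=net)
    if spec.name in ("vgg16", "vgg19"):
        cfg = _VGG16 if spec.name == "vgg16" else _VGG19
        rows, out, total = _vgg_summary(cfg, size)
    elif spec.name == "mobilenetv2_1.00_224":
        rows, out, total = _mobilenetv2_summary(size)
    else:  # densenet169
        rows, out, total = _densenet169_summary(size)
    return BackboneHandle(
        spec=spec, output_shape=out, params_total=total,
        params_trainable=0 if spec.frozen else total,
        layer_summary=rows, network=None)
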