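"""Target classifiers: transfer-style single-backbone models and the
stacked two-backbone feature-fusion model.

All classifiers consume grayscale batches; a channel-replication adapter
inside the model boundary maps (n, h, w, 1) to the 3-channel input the
backbones expect, so classifying a grayscale image is *identical* to
classifying its explicit 3-channel replication, and attack gradients are
well defined in the original [0, 1] grayscale pixel space.

The stacked model follows the published fusion head: each backbone ->
global average pool -> flatten, concatenate, then
BN -> dense(256)+ReLU -> dropout -> BN -> dense(128)+ReLU -> dropout ->
dense(3)+softmax.  With 1280- and 1664-wide backbones the head parameter
counts are 11,776 / 753,920 / 1,024 / 32,896 / 387.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from . import nn
from .backbones import BackboneHandle, BackboneSpec, build_backbone
from .data import ImageBatch
from .errors import CapabilityError, DataError, NumericError, ShapeError

N_CLASSES = 3


@dataclass
class StackHeadConfig:
    """Fusion head hyper-parameters (dense widths fixed by the design)."""

    dense1: int = 256
    dense2: int = 128
    n_classes: int = N_CLASSES
    dropout_rate: float = 0.3


@dataclass
class ClassifierTrainConfig:
    """Classifier training hyper-parameters.

    Defaults are the published stack-model settings: categorical
    cross-entropy (the coherent reading of the stated loss for a 3-way
    softmax), Adam at 1e-4, 30 epochs, batch size 21.
    """

    loss: str = "cross_entropy"
    optimizer: str = "adam"
    learning_rate: float = 1e-4
    epochs: int = 30
    batch_size: int = 21
    seed: int = 0


@dataclass
class TrainingHistory:
    """Per-epoch curves from a training run."""

    train_loss: list[float] = field(default_factory=list)
    val_loss: list[float] = field(default_factory=list)
    train_accuracy: list[float] = field(default_factory=list)
    val_accuracy: list[float] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.train_loss)


class ClassifierModel:
    """A differentiable 3-class classifier over [0, 1] grayscale images.

    Wraps an engine network emitting logits; exposes probabilities,
    predictions and the input gradient of the training loss (the handle
    the attack module requires).
    """

    def __init__(self, network, input_size: int, name: str,
                 frozen_prefixes: tuple = ()) -> None:
        self.network = network
        self.input_size = int(input_size)
        self.name = name
        # networks whose parameters the optimizer must not update
        self._frozen = frozen_prefixes

    # -- adapters ------------------------------------------------------
    def _to_input(self, pixels: np.ndarray) -> np.ndarray:
        pixels = np.asarray(pixels)
        if pixels.ndim != 4:
            raise ShapeError(f"expected (n, h, w, c) tensor, got {pixels.shape}")
        if pixels.shape[1] != self.input_size or pixels.shape[2] != self.input_size:
            raise ShapeError(
                f"model '{self.name}' expects {self.input_size}px input, "
                f"got {pixels.shape[1]}x{pixels.shape[2]}")
        if pixels.shape[-1] == 1:
            return np.repeat(pixels, 3, axis=-1)
        if pixels.shape[-1] == 3:
            return pixels
        raise ShapeError(f"expected 1 or 3 channels, got {pixels.shape[-1]}")

    # -- inference -----------------------------------------------------
    def logits(self, pixels: np.ndarray, training: bool = False) -> np.ndarray:
        return self.network.forward(self._to_input(pixels), training=training)

    def predict_proba(self, pixels: np.ndarray) -> np.ndarray:
        return nn.softmax(self.logits(pixels))

    def predict(self, batch: ImageBatch | np.ndarray):
        """Per-image probability vectors and argmax labels."""
        pixels = batch.pixels if isinstance(batch, ImageBatch) else batch
        probs = self.predict_proba(pixels)
        return probs, probs.argmax(axis=-1)

    def accuracy(self, batch: ImageBatch) -> float:
        """Percent correct on a batch."""
        _, pred = self.predict(batch)
        return float((pred == batch.labels).mean() * 100.0)

    # -- gradients -------------------------------------------------------
    def input_gradient(self, pixels: np.ndarray, labels: np.ndarray) -> np.ndarray:
        """d(mean cross-entropy)/d(pixels), in the caller's channel layout."""
        x3 = self._to_input(pixels)
        logits = self.network.forward(x3, training=False)
        _, dlogits = nn.softmax_cross_entropy(logits, np.asarray(labels))
        dx = self.network.backward(dlogits)
        if np.asarray(pixels).shape[-1] == 1:
            dx = dx.sum(axis=-1, keepdims=True)  # adjoint of replication
        return dx

    # -- persistence -----------------------------------------------------
    def get_weights(self):
        return self.network.get_weights()

    def set_weights(self, weights):
        self.network.set_weights(weights)

    def n_params(self) -> int:
        return self.network.n_params()


# ---------------------------------------------------------------------
# builders
# ---------------------------------------------------------------------

def _require_runnable(handle: BackboneHandle):
    if not handle.runnable:
        raise CapabilityError(
            f"backbone '{handle.name}' is summary-only (no offline weights); "
            "a runnable classifier needs the 'tinycnn' backbone")


def build_transfer_classifier(spec: BackboneSpec, n_classes: int = N_CLASSES,
                              *, seed: int = 0, dtype=np.float32) -> ClassifierModel:
    """Backbone + global-average-pooled dense head + softmax."""
    handle = build_backbone(spec, seed=seed, dtype=dtype)
    _require_runnable(handle)
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0xC1]))
    width = handle.feature_width
    head = [
        nn.GlobalAvgPool(),
        nn.Dense(width, 32, rng=rng, dtype=dtype),
        nn.ReLU(),
        nn.Dense(32, n_classes, rng=rng, dtype=dtype),
    ]
    net = nn.Network(handle.network.layers + head)
    model = ClassifierModel(net, spec.input_size, f"transfer-{spec.name}")
    if spec.frozen:
        model._frozen = tuple(handle.network.layers)
    return model


def head_parameter_counts(width1: int, width2: int,
                          head: StackHeadConfig | None = None) -> list[int]:
    """Fusion-head parameter counts for given backbone feature widths."""
    head = head or StackHeadConfig()
    concat = width1 + width2
    return [4 * concat,
            concat * head.dense1 + head.dense1,
            4 * head.dense1,
            head.dense1 * head.dense2 + head.dense2,
            head.dense2 * head.n_classes + head.n_classes]


def build_stack_model(b1: BackboneHandle, b2: BackboneHandle,
                      head: StackHeadConfig | None = None, *, seed: int = 0,
                      dtype=np.float32) -> ClassifierModel:
    """Two-backbone feature-fusion classifier.

    Summary-only backbones yield a summary-capable but non-runnable model;
    runnable (tinycnn) backbones yield a trainable one.
    """
    head = head or StackHeadConfig()
    if b1.spec.input_size != b2.spec.input_size:
        raise ShapeError("stacked backbones must share input size")
    w1, w2 = b1.feature_width, b2.feature_width
    concat = w1 + w2
    expected = head_parameter_counts(1280, 1664, head)
    actual = head_parameter_counts(w1, w2, head)
    if (w1, w2) != (1280, 1664) and actual != expected:
        warnings.warn(
            f"backbone widths ({w1}, {w2}) differ from the published "
            f"(1280, 1664); head counts recomputed as {actual}",
            stacklevel=2)
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0xC2]))
    head_net = nn.Network([
        nn.BatchNorm(concat, dtype=dtype),
        nn.Dense(concat, head.dense1, rng=rng, dtype=dtype),
        nn.ReLU(),
        nn.Dropout(head.dropout_rate),
        nn.BatchNorm(head.dense1, dtype=dtype),
        nn.Dense(head.dense1, head.dense2, rng=rng, dtype=dtype),
        nn.ReLU(),
        nn.Dropout(head.dropout_rate),
        nn.Dense(head.dense2, head.n_classes, rng=rng, dtype=dtype),
    ])
    model = StackModel(b1, b2, head_net)
    return model


class StackModel(ClassifierModel):
    """Feature-fusion classifier with a layer summary mirroring the design."""

    def __init__(self, b1: BackboneHandle, b2: BackboneHandle,
                 head_net) -> None:
        self.backbones = (b1, b2)
        branches = []
        for b in self.backbones:
            layers = (b.network.layers if b.runnable else [])
            branches.append(nn.Network(layers + [nn.GlobalAvgPool(),
                                                 nn.Flatten()]))
        network = nn.ConcatNetwork(branches, head_net)
        super().__init__(network, b1.spec.input_size,
                         f"stack-{b1.name}+{b2.name}")
        if b1.spec.frozen and b1.runnable:
            self._frozen = tuple(b1.network.layers) + (
                tuple(b2.network.layers) if b2.runnable else ())
        self._head_net = head_net

    @property
    def runnable(self) -> bool:
        return all(b.runnable for b in self.backbones)

    def logits(self, pixels, training: bool = False):
        for b in self.backbones:
            if not b.runnable:
                raise CapabilityError(
                    f"stack model uses summary-only backbone '{b.name}'; "
                    "use tinycnn backbones for a runnable stack")
        return super().logits(pixels, training=training)

    def layer_summary(self):
        """(name, output shape, param count) rows: backbones then head."""
        b1, b2 = self.backbones
        rows = [(f"{b.name} (features)", b.output_shape, b.params_total)
                for b in self.backbones]
        rows += [("GlobalAveragePooling2D", (b1.feature_width,), 0),
                 ("GlobalAveragePooling2D", (b2.feature_width,), 0)]
        concat = b1.feature_width + b2.feature_width
        rows.append(("Concatenate", (concat,), 0))
        rows += [(name, shape[1:], p)
                 for name, shape, p in self._head_net.summary((1, concat))]
        return rows


# ---------------------------------------------------------------------
# training
# ---------------------------------------------------------------------

def train_classifier(model: ClassifierModel, train: ImageBatch,
                     val: ImageBatch, config: ClassifierTrainConfig
                     ) -> tuple[ClassifierModel, TrainingHistory]:
    """Seeded minibatch training with Adam on cross-entropy.

    Frozen backbone layers are excluded from the update.  Aborts with a
    :class:`NumericError` on non-finite loss.
    """
    if len(np.unique(train.labels)) < 2:
        raise DataError("training data must contain at least 2 classes")
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 0x7]))
    model.network.set_seed(config.seed)
    frozen = set(id(l) for l in model._frozen)

    class _Trainable:
        def trainable(self):
            for layer, name in model.network.trainable():
                if id(layer) not in frozen:
                    yield layer, name

    opt = nn.Adam(_Trainable(), lr=config.learning_rate)
    history = TrainingHistory()
    n = len(train)
    for _ in range(config.epochs):
        order = rng.permutation(n)
        losses, correct = [], 0
        for start in range(0, n, config.batch_size):
            idx = order[start:start + config.batch_size]
            x = model._to_input(train.pixels[idx])
            y = train.labels[idx]
            logits = model.network.forward(x, training=True)
            loss, dlogits = nn.softmax_cross_entropy(logits, y)
            if not np.isfinite(loss):
                raise NumericError(
                    f"non-finite training loss in '{model.name}'")
            model.network.backward(dlogits)
            opt.step()
            losses.append(loss * len(idx))
            correct += int((logits.argmax(-1) == y).sum())
        history.train_loss.append(sum(losses) / n)
        history.train_accuracy.append(100.0 * correct / n)
        val_logits = model.logits(val.pixels)
        val_loss, _ = nn.softmax_cross_entropy(val_logits, val.labels)
        history.val_loss.append(val_loss)
        history.val_accuracy.append(
            float((val_logits.argmax(-1) == val.labels).mean() * 100.0))
    return model, history


def predict(model: ClassifierModel, batch: ImageBatch):
    """Module-level alias for :meth:`ClassifierModel.predict`."""
    return model.predict(batch)
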