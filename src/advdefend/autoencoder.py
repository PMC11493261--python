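"""The convolutional denoising autoencoder used as the defense.

Architecture (fixed, spatial-size agnostic for inputs divisible by 4):

    encoder: Conv(1->32, 3x3, same) + ReLU -> MaxPool(2x2)
             Conv(32->32, 3x3, same) + ReLU -> MaxPool(2x2)
    decoder: ConvTranspose(32->32, 3x3, stride 2, same) + ReLU
             ConvTranspose(32->32, 3x3, stride 2, same) + ReLU
             Conv(32->1, 3x3, same) + Sigmoid

At 224px input the bottleneck is (56, 56, 32) and the per-layer trainable
parameter counts are 320 / 9,248 / 9,248 / 9,248 / 289 (28,353 total);
the counts are independent of the spatial size.

Training reconstructs clean images (input == target) under MSE with Adam,
the published recipe: lr 0.001, 30 epochs, batch 128.  A noisy-input
variant (noisy in, clean target) is available behind a flag.  The defense
simply maps a (possibly attacked) batch through the trained network; the
sigmoid output keeps pixels in [0, 1] and the bottleneck discards the
high-frequency adversarial perturbation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import nn
from .data import ImageBatch
from .errors import DataError, NumericError, ShapeError


@dataclass
class DenoiserArchitecture:
    """Fixed encoder/decoder shape; only the input size varies."""

    input_size: int = 224
    channels: int = 32
    kernel: int = 3
    pool: int = 2

    def __post_init__(self) -> None:
        if self.input_size % (self.pool ** 2):
            raise ShapeError(
                f"input_size {self.input_size} must be divisible by "
                f"{self.pool ** 2}: the encoder applies two "
                f"{self.pool}x{self.pool} poolings")


@dataclass
class DenoiserTrainConfig:
    """Published autoencoder training recipe (MSE / Adam / 1e-3 / 30 / 128)."""

    loss: str = "mse"
    optimizer: str = "adam"
    learning_rate: float = 1e-3
    epochs: int = 30
    batch_size: int = 128
    seed: int = 0


@dataclass
class TrainingHistory:
    """Per-epoch reconstruction MSE on the train and validation sets."""

    train_loss: list[float] = field(default_factory=list)
    val_loss: list[float] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.train_loss)


class DenoiserModel:
    """The trained (or trainable) autoencoder with its layer summary."""

    def __init__(self, network: nn.Network, arch: DenoiserArchitecture) -> None:
        self.network = network
        self.arch = arch

    @property
    def input_size(self) -> int:
        return self.arch.input_size

    @property
    def bottleneck_shape(self) -> tuple[int, int, int]:
        s = self.arch.input_size // (self.arch.pool ** 2)
        return (s, s, self.arch.channels)

    def layer_summary(self):
        """(layer name, output shape, trainable params) per layer."""
        rows = self.network.summary((1, self.input_size, self.input_size, 1))
        return [(name, shape[1:], p) for name, shape, p in rows]

    def n_params(self) -> int:
        return self.network.n_params()

    def forward(self, pixels: np.ndarray, training: bool = False) -> np.ndarray:
        pixels = np.asarray(pixels)
        if pixels.ndim != 4 or pixels.shape[1] != self.input_size \
                or pixels.shape[2] != self.input_size or pixels.shape[3] != 1:
            raise ShapeError(
                f"denoiser expects (n, {self.input_size}, {self.input_size}, 1); "
                f"got {pixels.shape}")
        return self.network.forward(pixels, training=training)

    def get_weights(self):
        return self.network.get_weights()

    def set_weights(self, weights):
        self.network.set_weights(weights)


def build_denoiser(arch: DenoiserArchitecture | int = 224, *, seed: int = 0,
                   dtype=np.float32) -> DenoiserModel:
    """Build the fixed encoder/decoder at the requested input size."""
    if isinstance(arch, int):
        arch = DenoiserArchitecture(input_size=arch)
    c, k = arch.channels, arch.kernel
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0xAE]))
    net = nn.Network([
        nn.Conv2D(1, c, k, rng=rng, dtype=dtype),
        nn.ReLU(),
        nn.MaxPool2D(arch.pool),
        nn.Conv2D(c, c, k, rng=rng, dtype=dtype),
        nn.ReLU(),
        nn.MaxPool2D(arch.pool),
        nn.ConvTranspose2D(c, c, k, arch.pool, rng=rng, dtype=dtype),
        nn.ReLU(),
        nn.ConvTranspose2D(c, c, k, arch.pool, rng=rng, dtype=dtype),
        nn.ReLU(),
        nn.Conv2D(c, 1, k, rng=rng, dtype=dtype),
        nn.Sigmoid(),
    ])
    return DenoiserModel(net, arch)


def train_denoiser(model: DenoiserModel, train: ImageBatch, val: ImageBatch,
                   config: DenoiserTrainConfig, *, noisy_input: bool = False,
                   input_noise_sd: float = 0.1, early_stopping: bool = False,
                   patience: int = 5) -> tuple[DenoiserModel, TrainingHistory]:
    """Train clean-reconstruction (default) or noisy-in/clean-target.

    Early stopping on validation MSE is available but off by default, in
    keeping with the fixed 30-epoch recipe.
    """
    if len(train) == 0 or len(val) == 0:
        raise DataError("train and validation batches must be non-empty")
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 0xD0]))
    opt = nn.Adam(model.network, lr=config.learning_rate)
    history = TrainingHistory()
    n = len(train)
    best_val, since_best = np.inf, 0
    for _ in range(config.epochs):
        order = rng.permutation(n)
        losses = []
        for start in range(0, n, config.batch_size):
            idx = order[start:start + config.batch_size]
            target = train.pixels[idx]
            x = target
            if noisy_input:
                x = np.clip(target + rng.normal(
                    0.0, input_noise_sd, target.shape).astype(target.dtype),
                    0.0, 1.0)
            recon = model.forward(x, training=True)
            loss, dy = nn.mse_loss(recon, target)
            if not np.isfinite(loss):
                raise NumericError("non-finite reconstruction loss; try a "
                                   "smaller learning rate")
            model.network.backward(dy)
            opt.step()
            losses.append(loss * len(idx))
        history.train_loss.append(sum(losses) / n)
        val_recon = model.forward(val.pixels)
        val_loss, _ = nn.mse_loss(val_recon, val.pixels)
        history.val_loss.append(val_loss)
        if early_stopping:
            if val_loss < best_val - 1e-12:
                best_val, since_best = val_loss, 0
            else:
                since_best += 1
                if since_best >= patience:
                    break
    return model, history


def denoise(model: DenoiserModel, batch: ImageBatch) -> ImageBatch:
    """Reconstruct a batch; labels and ids pass through unchanged."""
    recon = model.forward(batch.pixels)
    return ImageBatch(np.clip(recon, 0.0, 1.0), batch.labels.copy(), batch.ids)


def reconstruction_mse(batch: ImageBatch, reference: ImageBatch, *,
                       model: DenoiserModel | None = None
                       ) -> tuple[np.ndarray, float]:
    """Per-image and mean MSE of ``batch`` (optionally denoised) vs reference.

    With ``model=None`` this is the plain pixelwise MSE between the two
    batches; with a model, the batch is reconstructed first.
    """
    pixels = denoise(model, batch).pixels if model is not None else batch.pixels
    if pixels.shape != reference.pixels.shape:
        raise ShapeError(
            f"shape mismatch: {pixels.shape} vs {reference.pixels.shape}")
    diff = pixels.astype(np.float64) - reference.pixels.astype(np.float64)
    per_image = (diff ** 2).mean(axis=(1, 2, 3))
    return per_image, float(per_image.mean())
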