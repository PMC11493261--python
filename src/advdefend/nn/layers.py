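"""Minimal NHWC neural-network layers with exact backpropagation.

Every layer implements ``forward(x, training)`` / ``backward(dy)`` and the
shape/parameter bookkeeping needed for model summaries.  Gradients flow all
the way to the *input* tensor — white-box gradient attacks depend on exact
input gradients, so each layer's backward pass is the true adjoint of its
forward pass (verified against finite differences in the test suite).

Conventions: tensors are ``(n, h, w, c)`` float arrays; convolutions are
3x3 "same" padding unless stated; transposed convolutions use stride 2 and
double the spatial size.  Parameter counts follow the usual deep-learning
summary convention (batch-norm counts its moving statistics).
"""

from __future__ import annotations

import numpy as np

from ..errors import ShapeError


class Layer:
    """Base layer: no parameters, identity shape."""

    def __init__(self) -> None:
        self.params: dict[str, np.ndarray] = {}
        self.grads: dict[str, np.ndarray] = {}
        # parameter names that the optimizer may update
        self.trainable_names: tuple[str, ...] = ()

    # -- bookkeeping -------------------------------------------------
    @property
    def name(self) -> str:
        return type(self).__name__

    def n_params(self) -> int:
        return int(sum(p.size for p in self.params.values()))

    def n_trainable(self) -> int:
        return int(sum(self.params[k].size for k in self.trainable_names))

    def output_shape(self, in_shape: tuple[int, ...]) -> tuple[int, ...]:
        return in_shape

    # -- compute -----------------------------------------------------
    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        raise NotImplementedError

    def backward(self, dy: np.ndarray) -> np.ndarray:
        raise NotImplementedError


def _he_init(rng: np.random.Generator, shape, fan_in: int, dtype) -> np.ndarray:
    return (rng.standard_normal(shape) * np.sqrt(2.0 / fan_in)).astype(dtype)


class Conv2D(Layer):
    """3x3 (configurable odd k) stride-1 'same' convolution with bias."""

    def __init__(self, c_in: int, c_out: int, k: int = 3, *, rng=None,
                 dtype=np.float32) -> None:
        super().__init__()
        if k % 2 != 1:
            raise ValueError("kernel size must be odd for 'same' padding")
        self.c_in, self.c_out, self.k = c_in, c_out, k
        rng = rng or np.random.default_rng(0)
        self.params = {
            "W": _he_init(rng, (k, k, c_in, c_out), k * k * c_in, dtype),
            "b": np.zeros(c_out, dtype=dtype),
        }
        self.trainable_names = ("W", "b")
        self._cache = None

    @property
    def name(self) -> str:
        return f"Conv2D({self.c_in}->{self.c_out}, {self.k}x{self.k})"

    def output_shape(self, in_shape):
        n, h, w, c = in_shape
        if c != self.c_in:
            raise ShapeError(f"{self.name}: expected {self.c_in} channels, got {c}")
        return (n, h, w, self.c_out)

    def forward(self, x, training=False):
        if x.shape[-1] != self.c_in:
            raise ShapeError(f"{self.name}: expected {self.c_in} channels, got {x.shape[-1]}")
        p = self.k // 2
        n, h, w, _ = x.shape
        xp = np.pad(x, ((0, 0), (p, p), (p, p), (0, 0)))
        W = self.params["W"]
        y = np.zeros((n, h, w, self.c_out), dtype=x.dtype)
        for a in range(self.k):
            for b in range(self.k):
                y += xp[:, a:a + h, b:b + w, :] @ W[a, b]
        y += self.params["b"]
        self._cache = (xp, x.shape)
        return y

    def backward(self, dy):
        xp, x_shape = self._cache
        n, h, w, _ = x_shape
        p = self.k // 2
        W = self.params["W"]
        dW = np.zeros_like(W)
        dxp = np.zeros_like(xp)
        for a in range(self.k):
            for b in range(self.k):
                xs = xp[:, a:a + h, b:b + w, :]
                dW[a, b] = np.tensordot(xs, dy, axes=([0, 1, 2], [0, 1, 2]))
                dxp[:, a:a + h, b:b + w, :] += dy @ W[a, b].T
        self.grads = {"W": dW, "b": dy.sum(axis=(0, 1, 2))}
        return dxp[:, p:p + h, p:p + w, :]


class ConvTranspose2D(Layer):
    """3x3 stride-2 transposed convolution; output spatial size = 2x input."""

    def __init__(self, c_in: int, c_out: int, k: int = 3, stride: int = 2,
                 *, rng=None, dtype=np.float32) -> None:
        super().__init__()
        self.c_in, self.c_out, self.k, self.s = c_in, c_out, k, stride
        rng = rng or np.random.default_rng(0)
        self.params = {
            "W": _he_init(rng, (k, k, c_in, c_out), k * k * c_in, dtype),
            "b": np.zeros(c_out, dtype=dtype),
        }
        self.trainable_names = ("W", "b")
        self._cache = None

    @property
    def name(self) -> str:
        return f"ConvTranspose2D({self.c_in}->{self.c_out}, stride {self.s})"

    def output_shape(self, in_shape):
        n, h, w, c = in_shape
        if c != self.c_in:
            raise ShapeError(f"{self.name}: expected {self.c_in} channels, got {c}")
        return (n, h * self.s, w * self.s, self.c_out)

    def forward(self, x, training=False):
        if x.shape[-1] != self.c_in:
            raise ShapeError(f"{self.name}: expected {self.c_in} channels, got {x.shape[-1]}")
        n, h, w, _ = x.shape
        k, s = self.k, self.s
        ho, wo = h * s, w * s
        W = self.params["W"]
        # scatter-add into an uncropped buffer, then crop to 'same' size
        yf = np.zeros((n, ho + k - s, wo + k - s, self.c_out), dtype=x.dtype)
        for a in range(k):
            for b in range(k):
                yf[:, a:a + s * h:s, b:b + s * w:s, :] += x @ W[a, b]
        y = yf[:, :ho, :wo, :] + self.params["b"]
        self._cache = (x, (n, ho, wo))
        return y

    def backward(self, dy):
        x, (n, ho, wo) = self._cache
        k, s = self.k, self.s
        h, w = x.shape[1], x.shape[2]
        W = self.params["W"]
        dyf = np.zeros((n, ho + k - s, wo + k - s, self.c_out), dtype=dy.dtype)
        dyf[:, :ho, :wo, :] = dy
        dW = np.zeros_like(W)
        dx = np.zeros_like(x)
        for a in range(k):
            for b in range(k):
                ds = dyf[:, a:a + s * h:s, b:b + s * w:s, :]
                dW[a, b] = np.tensordot(x, ds, axes=([0, 1, 2], [0, 1, 2]))
                dx += ds @ W[a, b].T
        self.grads = {"W": dW, "b": dy.sum(axis=(0, 1, 2))}
        return dx


class MaxPool2D(Layer):
    """Non-overlapping max pooling (default 2x2)."""

    def __init__(self, pool: int = 2) -> None:
        super().__init__()
        self.pool = pool
        self._cache = None

    @property
    def name(self) -> str:
        return f"MaxPool2D({self.pool}x{self.pool})"

    def output_shape(self, in_shape):
        n, h, w, c = in_shape
        if h % self.pool or w % self.pool:
            raise ShapeError(f"{self.name}: spatial size {h}x{w} not divisible by {self.pool}")
        return (n, h // self.pool, w // self.pool, c)

    def forward(self, x, training=False):
        p = self.pool
        n, h, w, c = x.shape
        if h % p or w % p:
            raise ShapeError(f"{self.name}: spatial size {h}x{w} not divisible by {p}")
        h2, w2 = h // p, w // p
        xt = (x.reshape(n, h2, p, w2, p, c)
                .transpose(0, 1, 3, 5, 2, 4)
                .reshape(n, h2, w2, c, p * p))
        idx = xt.argmax(axis=-1)
        y = np.take_along_axis(xt, idx[..., None], axis=-1)[..., 0]
        self._cache = (idx, x.shape)
        return y

    def backward(self, dy):
        idx, x_shape = self._cache
        p = self.pool
        n, h, w, c = x_shape
        h2, w2 = h // p, w // p
        dxt = np.zeros((n, h2, w2, c, p * p), dtype=dy.dtype)
        np.put_along_axis(dxt, idx[..., None], dy[..., None], axis=-1)
        return (dxt.reshape(n, h2, w2, c, p, p)
                   .transpose(0, 1, 4, 2, 5, 3)
                   .reshape(n, h, w, c))


class GlobalAvgPool(Layer):
    def output_shape(self, in_shape):
        n, h, w, c = in_shape
        return (n, c)

    def forward(self, x, training=False):
        self._hw = x.shape[1] * x.shape[2]
        self._shape = x.shape
        return x.mean(axis=(1, 2))

    def backward(self, dy):
        n, h, w, c = self._shape
        return np.broadcast_to(dy[:, None, None, :] / self._hw, self._shape).copy()


class Flatten(Layer):
    def output_shape(self, in_shape):
        n = in_shape[0]
        size = 1
        for d in in_shape[1:]:
            size *= d
        return (n, size)

    def forward(self, x, training=False):
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, dy):
        return dy.reshape(self._shape)


class Dense(Layer):
    def __init__(self, d_in: int, d_out: int, *, rng=None, dtype=np.float32) -> None:
        super().__init__()
        self.d_in, self.d_out = d_in, d_out
        rng = rng or np.random.default_rng(0)
        lim = np.sqrt(6.0 / (d_in + d_out))  # Glorot uniform
        self.params = {
            "W": rng.uniform(-lim, lim, (d_in, d_out)).astype(dtype),
            "b": np.zeros(d_out, dtype=dtype),
        }
        self.trainable_names = ("W", "b")

    @property
    def name(self) -> str:
        return f"Dense({self.d_in}->{self.d_out})"

    def output_shape(self, in_shape):
        if in_shape[-1] != self.d_in:
            raise ShapeError(f"{self.name}: expected width {self.d_in}, got {in_shape[-1]}")
        return (in_shape[0], self.d_out)

    def forward(self, x, training=False):
        if x.shape[-1] != self.d_in:
            raise ShapeError(f"{self.name}: expected width {self.d_in}, got {x.shape[-1]}")
        self._x = x
        return x @ self.params["W"] + self.params["b"]

    def backward(self, dy):
        self.grads = {"W": self._x.T @ dy, "b": dy.sum(axis=0)}
        return dy @ self.params["W"].T


class ReLU(Layer):
    def forward(self, x, training=False):
        self._mask = x > 0
        return np.where(self._mask, x, 0)

    def backward(self, dy):
        return np.where(self._mask, dy, 0)


class Sigmoid(Layer):
    def forward(self, x, training=False):
        self._y = 1.0 / (1.0 + np.exp(-x))
        return self._y

    def backward(self, dy):
        return dy * self._y * (1.0 - self._y)


class BatchNorm(Layer):
    """Batch normalization over axis 0 of a (n, d) tensor.

    Parameter count follows the framework summary convention: gamma, beta,
    moving mean and moving variance all count (4d total, 2d trainable).
    """

    def __init__(self, d: int, *, momentum: float = 0.99, eps: float = 1e-3,
                 dtype=np.float32) -> None:
        super().__init__()
        self.d, self.momentum, self.eps = d, momentum, eps
        self.params = {
            "gamma": np.ones(d, dtype=dtype),
            "beta": np.zeros(d, dtype=dtype),
            "moving_mean": np.zeros(d, dtype=dtype),
            "moving_var": np.ones(d, dtype=dtype),
        }
        self.trainable_names = ("gamma", "beta")

    @property
    def name(self) -> str:
        return f"BatchNorm({self.d})"

    def forward(self, x, training=False):
        if training and x.shape[0] > 1:
            mu = x.mean(axis=0)
            var = x.var(axis=0)
            m = self.momentum
            self.params["moving_mean"] = (m * self.params["moving_mean"]
                                          + (1 - m) * mu).astype(x.dtype)
            self.params["moving_var"] = (m * self.params["moving_var"]
                                         + (1 - m) * var).astype(x.dtype)
            self._train_mode = True
        else:
            mu = self.params["moving_mean"]
            var = self.params["moving_var"]
            self._train_mode = False
        std = np.sqrt(var + self.eps)
        xhat = (x - mu) / std
        self._cache = (x, mu, std, xhat)
        return self.params["gamma"] * xhat + self.params["beta"]

    def backward(self, dy):
        x, mu, std, xhat = self._cache
        g = self.params["gamma"]
        self.grads = {"gamma": (dy * xhat).sum(axis=0), "beta": dy.sum(axis=0),
                      "moving_mean": np.zeros(self.d, dtype=dy.dtype),
                      "moving_var": np.zeros(self.d, dtype=dy.dtype)}
        dxhat = dy * g
        if not self._train_mode:
            return dxhat / std
        n = x.shape[0]
        # full batch-statistics adjoint
        dvar = (dxhat * (x - mu)).sum(axis=0) * (-0.5) / std**3
        dmu = -(dxhat.sum(axis=0)) / std + dvar * (-2.0 / n) * (x - mu).sum(axis=0)
        return dxhat / std + dvar * 2.0 * (x - mu) / n + dmu / n


class Dropout(Layer):
    """Inverted dropout; identity at inference time."""

    def __init__(self, rate: float) -> None:
        super().__init__()
        if not 0.0 <= rate < 1.0:
            raise ValueError("dropout rate must be in [0, 1)")
        self.rate = rate
        self.rng = np.random.default_rng(0)
        self._mask = None

    @property
    def name(self) -> str:
        return f"Dropout({self.rate})"

    def forward(self, x, training=False):
        if not training or self.rate == 0.0:
            self._mask = None
            return x
        keep = 1.0 - self.rate
        self._mask = (self.rng.random(x.shape) < keep).astype(x.dtype) / keep
        return x * self._mask

    def backward(self, dy):
        if self._mask is None:
            return dy
        return dy * self._mask
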