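"""Network containers, losses and the Adam optimizer."""

from __future__ import annotations

import numpy as np

from .layers import Layer
from ..errors import NumericError


class Network:
    """A plain sequential stack of layers with end-to-end backprop."""

    def __init__(self, layers: list[Layer]) -> None:
        self.layers = list(layers)

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x, training=training)
        return x

    def backward(self, dy: np.ndarray) -> np.ndarray:
        for layer in reversed(self.layers):
            dy = layer.backward(dy)
        return dy

    # -- parameters ---------------------------------------------------
    def trainable(self):
        """Yield (param_array, grad_fetcher) pairs for the optimizer."""
        for layer in self.layers:
            for name in layer.trainable_names:
                yield layer, name

    def n_params(self) -> int:
        return sum(l.n_params() for l in self.layers)

    def n_trainable(self) -> int:
        return sum(l.n_trainable() for l in self.layers)

    def set_seed(self, seed: int) -> None:
        """Reseed stochastic layers (dropout) for reproducible training."""
        for i, layer in enumerate(self.layers):
            if hasattr(layer, "rng"):
                layer.rng = np.random.default_rng((seed, i))

    def summary(self, in_shape: tuple[int, ...]):
        """List of (layer name, output shape, total params) rows."""
        rows = []
        shape = in_shape
        for layer in self.layers:
            shape = layer.output_shape(shape)
            rows.append((layer.name, shape, layer.n_params()))
        return rows

    # -- persistence ---------------------------------------------------
    def get_weights(self) -> dict[str, np.ndarray]:
        out = {}
        for i, layer in enumerate(self.layers):
            for name, arr in layer.params.items():
                out[f"{i}:{name}"] = arr
        return out

    def set_weights(self, weights: dict[str, np.ndarray]) -> None:
        for i, layer in enumerate(self.layers):
            for name in layer.params:
                layer.params[name] = np.asarray(weights[f"{i}:{name}"])


class ConcatNetwork:
    """Two branch networks fed the same input, concatenated, then a head.

    Used for the stacked feature-fusion classifier: each branch is
    backbone -> global average pool -> flatten; the head is the shared
    batch-norm / dense block.
    """

    def __init__(self, branches: list[Network], head: Network) -> None:
        self.branches = branches
        self.head = head

    def forward(self, x, training: bool = False):
        feats = [b.forward(x, training=training) for b in self.branches]
        self._widths = [f.shape[-1] for f in feats]
        h = np.concatenate(feats, axis=-1)
        return self.head.forward(h, training=training)

    def backward(self, dy):
        dh = self.head.backward(dy)
        dx = None
        start = 0
        for b, w in zip(self.branches, self._widths):
            d = b.backward(dh[:, start:start + w])
            dx = d if dx is None else dx + d
            start += w
        return dx

    def trainable(self):
        for net in (*self.branches, self.head):
            yield from net.trainable()

    def n_params(self) -> int:
        return sum(n.n_params() for n in (*self.branches, self.head))

    def n_trainable(self) -> int:
        return sum(n.n_trainable() for n in (*self.branches, self.head))

    def set_seed(self, seed: int) -> None:
        for j, net in enumerate((*self.branches, self.head)):
            net.set_seed(seed + 1000 * j)

    def get_weights(self):
        out = {}
        for j, net in enumerate((*self.branches, self.head)):
            for key, arr in net.get_weights().items():
                out[f"{j}/{key}"] = arr
        return out

    def set_weights(self, weights):
        for j, net in enumerate((*self.branches, self.head)):
            net.set_weights({k.split("/", 1)[1]: v for k, v in weights.items()
                             if k.startswith(f"{j}/")})


# -- losses -----------------------------------------------------------


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def softmax_cross_entropy(logits: np.ndarray, labels: np.ndarray):
    """Mean categorical cross-entropy and its gradient w.r.t. logits."""
    n = logits.shape[0]
    p = softmax(logits)
    eps = np.finfo(p.dtype).tiny
    loss = float(-np.log(p[np.arange(n), labels] + eps).mean())
    dlogits = p.copy()
    dlogits[np.arange(n), labels] -= 1.0
    return loss, dlogits / n


def mse_loss(pred: np.ndarray, target: np.ndarray):
    """Mean squared error over all elements and its gradient w.r.t. pred."""
    diff = pred - target
    loss = float(np.mean(diff * diff))
    return loss, 2.0 * diff / diff.size


class Adam:
    """Adam optimizer over a network's trainable parameters."""

    def __init__(self, net, lr: float = 1e-3, beta1: float = 0.9,
                 beta2: float = 0.999, eps: float = 1e-7) -> None:
        self.net = net
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.t = 0
        self._m: dict[tuple[int, str], np.ndarray] = {}
        self._v: dict[tuple[int, str], np.ndarray] = {}

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.b1, self.b2
        bias1 = 1.0 - b1 ** self.t
        bias2 = 1.0 - b2 ** self.t
        for layer, name in self.net.trainable():
            g = layer.grads.get(name)
            if g is None:
                continue
            if not np.all(np.isfinite(g)):
                raise NumericError(f"non-finite gradient in {layer.name}:{name}")
            key = (id(layer), name)
            if key not in self._m:
                self._m[key] = np.zeros_like(layer.params[name])
                self._v[key] = np.zeros_like(layer.params[name])
            m = self._m[key]
            v = self._v[key]
            m *= b1
            m += (1 - b1) * g
            v *= b2
            v += (1 - b2) * g * g
            layer.params[name] -= (self.lr * (m / bias1)
                                   / (np.sqrt(v / bias2) + self.eps)).astype(
                layer.params[name].dtype)
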