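"""Minimal NumPy neural-network layers for the mask classifier.

Implements exactly what the shape classifier needs — valid convolution
(im2col), 3x3 max pooling, dense layers, relu/tanh activations, softmax
cross-entropy and Adam — with deterministic seeded initialization.  Forward
passes cache what backward needs; parameters live in ``params`` /``grads``
dicts per layer so the optimizer can treat them uniformly.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Conv2D",
    "MaxPool",
    "Flatten",
    "Dense",
    "Activation",
    "Sequential",
    "Adam",
    "softmax",
    "softmax_cross_entropy",
]


def _im2col(x: np.ndarray, kh: int, kw: int) -> np.ndarray:
    """(N, H, W, C) -> (N, H-kh+1, W-kw+1, kh*kw*C) patch matrix (valid)."""
    n, h, w, c = x.shape
    oh, ow = h - kh + 1, w - kw + 1
    s0, s1, s2, s3 = x.strides
    patches = np.lib.stride_tricks.as_strided(
        x, shape=(n, oh, ow, kh, kw, c), strides=(s0, s1, s2, s1, s2, s3)
    )
    return patches.reshape(n, oh, ow, kh * kw * c)


class Layer:
    params: dict
    grads: dict

    def __init__(self) -> None:
        self.params, self.grads = {}, {}

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def backward(self, grad: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError


class Conv2D(Layer):
    """Valid 2D convolution, NHWC layout, He-initialized."""

    def __init__(self, in_channels: int, out_channels: int, kernel: int, rng: np.random.Generator):
        super().__init__()
        fan_in = kernel * kernel * in_channels
        self.kernel = kernel
        self.params = {
            "W": rng.standard_normal((fan_in, out_channels)) * np.sqrt(2.0 / fan_in),
            "b": np.zeros(out_channels),
        }

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        self._cols = _im2col(x, self.kernel, self.kernel)
        self._in_shape = x.shape
        return self._cols @ self.params["W"] + self.params["b"]

    def backward(self, grad: np.ndarray) -> np.ndarray:
        n, oh, ow, _ = grad.shape
        cols = self._cols.reshape(-1, self._cols.shape[-1])
        g = grad.reshape(-1, grad.shape[-1])
        self.grads = {"W": cols.T @ g, "b": g.sum(axis=0)}
        dcols = (g @ self.params["W"].T).reshape(n, oh, ow, self.kernel, self.kernel, -1)
        dx = np.zeros(self._in_shape)
        for i in range(self.kernel):
            for j in range(self.kernel):
                dx[:, i : i + oh, j : j + ow, :] += dcols[:, :, :, i, j, :]
        return dx


class MaxPool(Layer):
    """Non-overlapping max pooling (kernel = stride); trailing rows/cols that
    do not fill a window are dropped, as in standard 'valid' pooling."""

    def __init__(self, kernel: int = 3):
        super().__init__()
        self.k = kernel

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        k = self.k
        n, h, w, c = x.shape
        oh, ow = h // k, w // k
        x = x[:, : oh * k, : ow * k, :]
        windows = x.reshape(n, oh, k, ow, k, c)
        out = windows.max(axis=(2, 4))
        self._mask = windows == out[:, :, None, :, None, :]
        self._in_shape = (n, h, w, c)
        return out

    def backward(self, grad: np.ndarray) -> np.ndarray:
        k = self.k
        n, oh, ow, c = grad.shape
        expanded = self._mask * grad[:, :, None, :, None, :]
        dx = np.zeros(self._in_shape)
        dx[:, : oh * k, : ow * k, :] = expanded.reshape(n, oh * k, ow * k, c)
        return dx


class Flatten(Layer):
    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        self._in_shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        return grad.reshape(self._in_shape)


class Dense(Layer):
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator):
        super().__init__()
        self.params = {
            "W": rng.standard_normal((n_in, n_out)) * np.sqrt(2.0 / n_in),
            "b": np.zeros(n_out),
        }

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        self._x = x
        return x @ self.params["W"] + self.params["b"]

    def backward(self, grad: np.ndarray) -> np.ndarray:
        self.grads = {"W": self._x.T @ grad, "b": grad.sum(axis=0)}
        return grad @ self.params["W"].T


class Activation(Layer):
    def __init__(self, kind: str):
        super().__init__()
        if kind not in ("relu", "tanh"):
            raise ValueError(f"unknown activation {kind!r}")
        self.kind = kind

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        self._y = np.maximum(x, 0.0) if self.kind == "relu" else np.tanh(x)
        return self._y

    def backward(self, grad: np.ndarray) -> np.ndarray:
        if self.kind == "relu":
            return grad * (self._y > 0)
        return grad * (1.0 - self._y * self._y)


class Sequential:
    def __init__(self, layers: list[Layer]):
        self.layers = layers

    def forward(self, x: np.ndarray, train: bool = False, upto: int | None = None) -> np.ndarray:
        for layer in self.layers[:upto]:
            x = layer.forward(x, train=train)
        return x

    def backward(self, grad: np.ndarray) -> None:
        for layer in reversed(self.layers):
            grad = layer.backward(grad)

    def parameters(self) -> list[tuple[Layer, str]]:
        return [(layer, name) for layer in self.layers for name in layer.params]

    def state_dict(self) -> dict[str, np.ndarray]:
        return {
            f"{i}.{name}": layer.params[name]
            for i, layer in enumerate(self.layers)
            for name in layer.params
        }

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        for key, value in state.items():
            idx, name = key.split(".")
            self.layers[int(idx)].params[name] = np.asarray(value)


class Adam:
    """Adaptive-moment optimizer (the configurable default for training)."""

    def __init__(self, model: Sequential, lr: float = 1e-4, beta1: float = 0.9,
                 beta2: float = 0.999, eps: float = 1e-8):
        self.model, self.lr, self.b1, self.b2, self.eps = model, lr, beta1, beta2, eps
        self.m = {id(l): {k: np.zeros_like(v) for k, v in l.params.items()} for l in model.layers if l.params}
        self.v = {id(l): {k: np.zeros_like(v) for k, v in l.params.items()} for l in model.layers if l.params}
        self.t = 0

    def step(self) -> None:
        self.t += 1
        for layer in self.model.layers:
            for name, grad in layer.grads.items():
                m = self.m[id(layer)][name]
                v = self.v[id(layer)][name]
                m[:] = self.b1 * m + (1 - self.b1) * grad
                v[:] = self.b2 * v + (1 - self.b2) * grad * grad
                mhat = m / (1 - self.b1**self.t)
                vhat = v / (1 - self.b2**self.t)
                layer.params[name] -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


def softmax(z: np.ndarray) -> np.ndarray:
    z = z - z.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def softmax_cross_entropy(logits: np.ndarray, onehot: np.ndarray) -> tuple[float, np.ndarray]:
    """Mean cross entropy and its gradient w.r.t. the logits."""
    p = softmax(logits)
    n = logits.shape[0]
    loss = float(-(onehot * np.log(p + 1e-12)).sum() / n)
    return loss, (p - onehot) / n
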