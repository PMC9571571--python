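"""Feed-forward layers with explicit forward/backward passes.

All layers operate on the trailing axis of the input (so a dense layer maps
``(batch, features)`` as well as ``(batch, timesteps, features)`` tensors,
matching the broadcasting convention of the mainstream deep-learning
frameworks). Parameters and gradients live in per-layer dicts so the
optimizer can treat every layer uniformly.
"""

from __future__ import annotations

import numpy as np

from ..errors import InputError

# scaled-exponential-linear-unit constants (Klambauer et al. self-normalizing nets)
_SELU_LAMBDA = 1.0507009873554805
_SELU_ALPHA = 1.6732632423543772


def _act_forward(name, x):
    if name == "linear":
        return x
    if name == "relu":
        return np.maximum(x, 0)
    if name == "sigmoid":
        return 1.0 / (1.0 + np.exp(-x))
    if name == "tanh":
        return np.tanh(x)
    if name == "selu":
        return _SELU_LAMBDA * np.where(x > 0, x, _SELU_ALPHA * (np.exp(np.minimum(x, 0)) - 1))
    if name == "softmax":
        z = x - x.max(axis=-1, keepdims=True)
        e = np.exp(z)
        return e / e.sum(axis=-1, keepdims=True)
    raise InputError(f"unknown activation {name!r}")


def _act_backward(name, dy, x, y):
    if name == "linear":
        return dy
    if name == "relu":
        return dy * (x > 0)
    if name == "sigmoid":
        return dy * y * (1.0 - y)
    if name == "tanh":
        return dy * (1.0 - y * y)
    if name == "selu":
        return dy * _SELU_LAMBDA * np.where(x > 0, 1.0, _SELU_ALPHA * np.exp(np.minimum(x, 0)))
    if name == "softmax":
        # full Jacobian contracted against dy: dx = y * (dy - <dy, y>)
        return y * (dy - (dy * y).sum(axis=-1, keepdims=True))
    raise InputError(f"unknown activation {name!r}")


class Layer:
    """Base class; subclasses fill ``params``/``grads`` during ``build``."""

    def __init__(self):
        self.params: dict[str, np.ndarray] = {}
        self.grads: dict[str, np.ndarray] = {}
        self.built = False

    def build(self, input_shape, rng, dtype):
        self.built = True
        return self.output_shape(input_shape)

    def output_shape(self, input_shape):
        return input_shape

    def forward(self, x):  # pragma: no cover - abstract
        raise NotImplementedError

    def backward(self, dy):  # pragma: no cover - abstract
        raise NotImplementedError

    def zero_grads(self):
        for k in self.grads:
            self.grads[k][...] = 0.0


def _glorot(rng, shape, dtype):
    fan_in, fan_out = shape[-2], shape[-1]
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape).astype(dtype)


def _orthogonal(rng, n, dtype):
    a = rng.standard_normal((n, n))
    q, r = np.linalg.qr(a)
    q = q * np.sign(np.diag(r))
    return q.astype(dtype)


class Dense(Layer):
    """Affine map on the trailing axis with an optional fused activation."""

    def __init__(self, units, activation="linear"):
        super().__init__()
        self.units = int(units)
        self.activation = activation
        _act_forward(activation, np.zeros(1))  # validate name eagerly

    def output_shape(self, input_shape):
        return input_shape[:-1] + (self.units,)

    def build(self, input_shape, rng, dtype):
        fan_in = input_shape[-1]
        self.params = {
            "W": _glorot(rng, (fan_in, self.units), dtype),
            "b": np.zeros(self.units, dtype=dtype),
        }
        self.grads = {k: np.zeros_like(v) for k, v in self.params.items()}
        return super().build(input_shape, rng, dtype)

    def forward(self, x):
        self._x = x
        self._z = x @ self.params["W"] + self.params["b"]
        self._y = _act_forward(self.activation, self._z)
        return self._y

    def backward(self, dy):
        dz = _act_backward(self.activation, dy, self._z, self._y)
        x2 = self._x.reshape(-1, self._x.shape[-1])
        dz2 = dz.reshape(-1, dz.shape[-1])
        self.grads["W"] += x2.T @ dz2
        self.grads["b"] += dz2.sum(axis=0)
        return dz @ self.params["W"].T


class Activation(Layer):
    """Bare element-wise activation layer."""

    def __init__(self, activation):
        super().__init__()
        self.activation = activation
        _act_forward(activation, np.zeros(1))

    def forward(self, x):
        self._x = x
        self._y = _act_forward(self.activation, x)
        return self._y

    def backward(self, dy):
        return _act_backward(self.activation, dy, self._x, self._y)


class LeakyReLU(Layer):
    """Leaky rectifier with fixed negative slope (0.3, the Keras default)."""

    def __init__(self, alpha=0.3):
        super().__init__()
        self.alpha = float(alpha)

    def forward(self, x):
        self._x = x
        return np.where(x > 0, x, self.alpha * x)

    def backward(self, dy):
        return dy * np.where(self._x > 0, 1.0, self.alpha)


class PReLU(Layer):
    """Rectifier with a learned per-feature negative slope (initialized to 0)."""

    def build(self, input_shape, rng, dtype):
        self.params = {"alpha": np.zeros(input_shape[-1], dtype=dtype)}
        self.grads = {"alpha": np.zeros_like(self.params["alpha"])}
        return super().build(input_shape, rng, dtype)

    def forward(self, x):
        self._x = x
        return np.where(x > 0, x, self.params["alpha"] * x)

    def backward(self, dy):
        neg = self._x <= 0
        contrib = dy * self._x * neg
        self.grads["alpha"] += contrib.reshape(-1, contrib.shape[-1]).sum(axis=0)
        return dy * np.where(neg, self.params["alpha"], 1.0)


class Reshape(Layer):
    """Reshape trailing axes, preserving the batch axis."""

    def __init__(self, target_shape):
        super().__init__()
        self.target_shape = tuple(int(t) for t in target_shape)

    def output_shape(self, input_shape):
        if int(np.prod(input_shape[1:])) != int(np.prod(self.target_shape)):
            raise InputError(
                f"cannot reshape trailing shape {input_shape[1:]} into {self.target_shape}"
            )
        return (input_shape[0],) + self.target_shape

    def forward(self, x):
        self._in_shape = x.shape
        return x.reshape((x.shape[0],) + self.target_shape)

    def backward(self, dy):
        return dy.reshape(self._in_shape)


class Flatten(Layer):
    def output_shape(self, input_shape):
        return (input_shape[0], int(np.prod(input_shape[1:])))

    def forward(self, x):
        self._in_shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, dy):
        return dy.reshape(self._in_shape)


class Conv1D(Layer):
    """1-D convolution (stride 1, 'same' zero padding) over ``(batch, length, ch)``."""

    def __init__(self, filters, kernel_size, activation="linear"):
        super().__init__()
        self.filters = int(filters)
        self.kernel_size = int(kernel_size)
        self.activation = activation
        _act_forward(activation, np.zeros(1))

    def output_shape(self, input_shape):
        return input_shape[:-1] + (self.filters,)

    def build(self, input_shape, rng, dtype):
        ch = input_shape[-1]
        fan_in = self.kernel_size * ch
        limit = np.sqrt(6.0 / (fan_in + self.filters))
        self.params = {
            "W": rng.uniform(-limit, limit, size=(self.kernel_size, ch, self.filters)).astype(dtype),
            "b": np.zeros(self.filters, dtype=dtype),
        }
        self.grads = {k: np.zeros_like(v) for k, v in self.params.items()}
        return super().build(input_shape, rng, dtype)

    def _pad(self, x):
        k = self.kernel_size
        left = (k - 1) // 2
        right = k - 1 - left
        return np.pad(x, ((0, 0), (left, right), (0, 0))), left

    def forward(self, x):
        self._x = x
        xp, _ = self._pad(x)
        self._xp = xp
        win = np.lib.stride_tricks.sliding_window_view(xp, self.kernel_size, axis=1)
        # win: (batch, length, ch, k) -> contract with W (k, ch, filters)
        self._z = np.einsum("blck,kcf->blf", win, self.params["W"]) + self.params["b"]
        self._y = _act_forward(self.activation, self._z)
        return self._y

    def backward(self, dy):
        dz = _act_backward(self.activation, dy, self._z, self._y)
        win = np.lib.stride_tricks.sliding_window_view(self._xp, self.kernel_size, axis=1)
        self.grads["W"] += np.einsum("blck,blf->kcf", win, dz)
        self.grads["b"] += dz.sum(axis=(0, 1))
        k = self.kernel_size
        length = self._x.shape[1]
        dxp = np.zeros_like(self._xp)
        for j in range(k):
            dxp[:, j : j + length, :] += dz @ self.params["W"][j].T
        left = (k - 1) // 2
        return dxp[:, left : left + length, :]
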