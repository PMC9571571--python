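"""Recurrent layers (simple tanh RNN and LSTM) with truncated-free BPTT.

Both layers consume ``(batch, timesteps, features)`` and return the final
hidden state ``(batch, units)``, mirroring the default (non-sequence-output)
behaviour of the mainstream framework layers they are named after.
"""

from __future__ import annotations

import numpy as np

from .layers import Layer, _glorot, _orthogonal


class SimpleRNN(Layer):
    """Fully-connected tanh recurrence; returns the last hidden state."""

    def __init__(self, units):
        super().__init__()
        self.units = int(units)

    def output_shape(self, input_shape):
        return (input_shape[0], self.units)

    def build(self, input_shape, rng, dtype):
        fan_in = input_shape[-1]
        self.params = {
            "Wx": _glorot(rng, (fan_in, self.units), dtype),
            "Wh": _orthogonal(rng, self.units, dtype),
            "b": np.zeros(self.units, dtype=dtype),
        }
        self.grads = {k: np.zeros_like(v) for k, v in self.params.items()}
        return super().build(input_shape, rng, dtype)

    def forward(self, x):
        self._x = x
        batch, steps, _ = x.shape
        hs = np.zeros((steps + 1, batch, self.units), dtype=x.dtype)
        for t in range(steps):
            hs[t + 1] = np.tanh(
                x[:, t] @ self.params["Wx"] + hs[t] @ self.params["Wh"] + self.params["b"]
            )
        self._hs = hs
        return hs[-1]

    def backward(self, dy):
        x, hs = self._x, self._hs
        batch, steps, _ = x.shape
        dx = np.empty_like(x)
        dh = dy
        for t in range(steps - 1, -1, -1):
            h = hs[t + 1]
            dz = dh * (1.0 - h * h)
            self.grads["Wx"] += x[:, t].T @ dz
            self.grads["Wh"] += hs[t].T @ dz
            self.grads["b"] += dz.sum(axis=0)
            dx[:, t] = dz @ self.params["Wx"].T
            dh = dz @ self.params["Wh"].T
        return dx


class LSTM(Layer):
    """Standard LSTM cell unrolled over time; returns the last hidden state.

    Gate order in the stacked weight matrices is (input, forget, cell, output);
    the forget-gate bias is initialized to one.
    """

    def __init__(self, units):
        super().__init__()
        self.units = int(units)

    def output_shape(self, input_shape):
        return (input_shape[0], self.units)

    def build(self, input_shape, rng, dtype):
        fan_in = input_shape[-1]
        u = self.units
        wh = np.concatenate([_orthogonal(rng, u, dtype) for _ in range(4)], axis=1)
        b = np.zeros(4 * u, dtype=dtype)
        b[u : 2 * u] = 1.0  # forget-gate bias
        self.params = {"Wx": _glorot(rng, (fan_in, 4 * u), dtype), "Wh": wh, "b": b}
        self.grads = {k: np.zeros_like(v) for k, v in self.params.items()}
        return super().build(input_shape, rng, dtype)

    @staticmethod
    def _sigmoid(x):
        return 1.0 / (1.0 + np.exp(-x))

    def forward(self, x):
        self._x = x
        batch, steps, _ = x.shape
        u = self.units
        h = np.zeros((batch, u), dtype=x.dtype)
        c = np.zeros((batch, u), dtype=x.dtype)
        cache = []
        for t in range(steps):
            z = x[:, t] @ self.params["Wx"] + h @ self.params["Wh"] + self.params["b"]
            i = self._sigmoid(z[:, :u])
            f = self._sigmoid(z[:, u : 2 * u])
            g = np.tanh(z[:, 2 * u : 3 * u])
            o = self._sigmoid(z[:, 3 * u :])
            c_new = f * c + i * g
            tc = np.tanh(c_new)
            h_new = o * tc
            cache.append((h, c, i, f, g, o, tc))
            h, c = h_new, c_new
        self._cache = cache
        return h

    def backward(self, dy):
        x = self._x
        batch, steps, _ = x.shape
        u = self.units
        dh = dy
        dc = np.zeros_like(dy)
        dx = np.empty_like(x)
        for t in range(steps - 1, -1, -1):
            h_prev, c_prev, i, f, g, o, tc = self._cache[t]
            do = dh * tc
            dc = dc + dh * o * (1.0 - tc * tc)
            di = dc * g
            df = dc * c_prev
            dg = dc * i
            dz = np.concatenate(
                [
                    di * i * (1.0 - i),
                    df * f * (1.0 - f),
                    dg * (1.0 - g * g),
                    do * o * (1.0 - o),
                ],
                axis=1,
            )
            self.grads["Wx"] += x[:, t].T @ dz
            self.grads["Wh"] += h_prev.T @ dz
            self.grads["b"] += dz.sum(axis=0)
            dx[:, t] = dz @ self.params["Wx"].T
            dh = dz @ self.params["Wh"].T
            dc = dc * f
        return dx
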