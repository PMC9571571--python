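"""Sequential model container with Adam/MSE training.

The training loop mirrors the conventions of the mainstream frameworks: mean
squared error over every output dimension, adaptive-moment (Adam)
optimization, mini-batch shuffling driven by a mandatory seed, and a
train/validation split recorded per epoch in a :class:`TrainingHistory`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ..errors import ContractError, DivergenceError, InputError


@dataclass
class TrainConfig:
    epochs: int = 100
    batch_size: int = 32
    learning_rate: float = 1e-3
    lr_decay: float = 1.0  # multiplicative per-epoch learning-rate decay
    validation_split: float = 0.39  # train:validation = 0.61:0.39
    seed: int | None = None
    shuffle: bool = True

    def __post_init__(self):
        if self.seed is None:
            raise InputError("TrainConfig.seed is mandatory for reproducibility")
        if not 0.0 <= self.validation_split < 1.0:
            raise InputError("validation_split must lie in [0, 1)")


@dataclass
class TrainingHistory:
    """Per-epoch loss (MSE) and MAE on the train and validation fractions."""

    loss: list[float] = field(default_factory=list)
    mae: list[float] = field(default_factory=list)
    val_loss: list[float] = field(default_factory=list)
    val_mae: list[float] = field(default_factory=list)


def mse(pred, target):
    d = pred - target
    return float(np.mean(d * d))


def mae(pred, target):
    return float(np.mean(np.abs(pred - target)))


class Adam:
    """Adaptive moment estimation over a flat list of parameter arrays."""

    def __init__(self, params, learning_rate=1e-3, beta1=0.9, beta2=0.999, eps=1e-7):
        self.params = params
        self.lr = learning_rate
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self, grads):
        self.t += 1
        b1t = 1.0 - self.beta1**self.t
        b2t = 1.0 - self.beta2**self.t
        for p, g, m, v in zip(self.params, grads, self.m, self.v):
            m *= self.beta1
            m += (1.0 - self.beta1) * g
            v *= self.beta2
            v += (1.0 - self.beta2) * (g * g)
            p -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)


class Sequential:
    """Ordered stack of layers trained end-to-end by backpropagation."""

    def __init__(self, layers, seed, dtype=np.float32):
        self.layers = list(layers)
        self.seed = int(seed)
        self.dtype = np.dtype(dtype)
        self.built = False
        self.input_shape = None

    def build(self, input_shape):
        rng = np.random.default_rng(self.seed)
        shape = (None,) + tuple(input_shape)
        for layer in self.layers:
            layer_rng = np.random.default_rng(rng.integers(2**31))
            if not layer.built:
                layer.build(shape, layer_rng, self.dtype)
            shape = layer.output_shape(shape)
        self.input_shape = tuple(input_shape)
        self.output_shape = shape[1:]
        self.built = True
        return self

    def _check_input(self, X):
        X = np.asarray(X, dtype=self.dtype)
        if self.built and X.shape[1:] != self.input_shape:
            raise ContractError(
                f"model expects input shape {self.input_shape}, got {X.shape[1:]}"
            )
        return X

    def forward(self, X):
        for layer in self.layers:
            X = layer.forward(X)
        return X

    def backward(self, dY):
        for layer in reversed(self.layers):
            dY = layer.backward(dY)
        return dY

    def predict(self, X, batch_size=512):
        X = np.atleast_2d(np.asarray(X, dtype=self.dtype))
        if not self.built:
            self.build(X.shape[1:])
        X = self._check_input(X)
        outs = [self.forward(X[i : i + batch_size]) for i in range(0, len(X), batch_size)]
        return np.concatenate(outs, axis=0)

    @property
    def param_list(self):
        return [p for layer in self.layers for p in layer.params.values()]

    @property
    def grad_list(self):
        return [g for layer in self.layers for g in layer.grads.values()]

    def fit(self, X, Y, config: TrainConfig):
        X = np.asarray(X, dtype=self.dtype)
        Y = np.asarray(Y, dtype=self.dtype)
        if len(X) == 0:
            raise InputError("training set is empty")
        if len(X) != len(Y):
            raise InputError("X and Y lengths differ")
        if not self.built:
            self.build(X.shape[1:])
        X = self._check_input(X)

        n_val = int(round(len(X) * config.validation_split))
        n_val = min(n_val, len(X) - 1)
        if n_val > 0:
            X_tr, Y_tr = X[:-n_val], Y[:-n_val]
            X_val, Y_val = X[-n_val:], Y[-n_val:]
        else:
            X_tr, Y_tr = X, Y
            X_val = Y_val = None

        rng = np.random.default_rng(config.seed)
        opt = Adam(self.param_list, learning_rate=config.learning_rate)
        history = TrainingHistory()
        n = len(X_tr)
        for epoch in range(config.epochs):
            opt.lr = config.learning_rate * config.lr_decay**epoch
            order = rng.permutation(n) if config.shuffle else np.arange(n)
            loss_sum = mae_sum = 0.0
            for start in range(0, n, config.batch_size):
                idx = order[start : start + config.batch_size]
                xb, yb = X_tr[idx], Y_tr[idx]
                pred = self.forward(xb)
                diff = pred - yb
                loss_sum += float(np.sum(diff * diff)) / diff[0].size
                mae_sum += float(np.sum(np.abs(diff))) / diff[0].size
                for layer in self.layers:
                    layer.zero_grads()
                self.backward(2.0 * diff / diff.size)
                opt.step(self.grad_list)
            epoch_loss = loss_sum / n
            history.loss.append(epoch_loss)
            history.mae.append(mae_sum / n)
            if X_val is not None:
                pred_val = self.predict(X_val)
                history.val_loss.append(mse(pred_val, Y_val))
                history.val_mae.append(mae(pred_val, Y_val))
            if not np.isfinite(epoch_loss):
                raise DivergenceError(
                    f"non-finite training loss at epoch {epoch}", config=config
                )
        return history
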