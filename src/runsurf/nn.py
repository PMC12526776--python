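"""A compact 1D convolutional network engine on numpy.

Implements exactly the pieces the classifier architectures need —
1D convolution, batch normalization, ReLU, max pooling, dropout, dense
layers, a softmax cross-entropy head, and SGD/RMSprop/Adam optimizers —
with explicit forward/backward passes in float32.  Everything is driven
by ``numpy.random.Generator`` streams, so fixed seeds give bit-identical
initialization, dropout masks and batch order on one device.

Array convention: activations are (batch, time, channels); dense layers
take (batch, features).
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

_F32 = np.float32


class Layer:
    """Base layer: optional parameters, cached forward state."""

    #: parameter name -> array; subclasses populate in __init__.
    def __init__(self) -> None:
        self.params: dict[str, np.ndarray] = {}
        self.grads: dict[str, np.ndarray] = {}
        #: names of parameters that count as weights for L1/L2 penalties
        self.weight_names: tuple[str, ...] = ()

    def forward(self, x: np.ndarray, training: bool, rng) -> np.ndarray:
        raise NotImplementedError

    def backward(self, grad: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def describe(self) -> str:
        return type(self).__name__


class Conv1D(Layer):
    """Valid-mode 1D convolution: (N, T, C) -> (N, T-k+1, F)."""

    def __init__(self, in_channels: int, filters: int, kernel_size: int, rng):
        super().__init__()
        self.k = int(kernel_size)
        self.cin = int(in_channels)
        self.f = int(filters)
        fan_in = self.k * self.cin
        scale = np.sqrt(2.0 / fan_in)  # He init for ReLU nets
        self.params = {
            "W": (rng.normal(0.0, scale, size=(fan_in, self.f))).astype(_F32),
            "b": np.zeros(self.f, dtype=_F32),
        }
        self.weight_names = ("W",)

    def forward(self, x, training, rng):
        n, t, c = x.shape
        if c != self.cin:
            raise ValueError(f"expected {self.cin} input channels, got {c}")
        if t < self.k:
            raise ValueError(f"input length {t} shorter than kernel {self.k}")
        # (N, T-k+1, C, k) -> (N, T-k+1, k, C) -> flat columns
        cols = sliding_window_view(x, self.k, axis=1).transpose(0, 1, 3, 2)
        self._cols = np.ascontiguousarray(cols).reshape(n, t - self.k + 1, -1)
        self._in_shape = x.shape
        return self._cols @ self.params["W"] + self.params["b"]

    def backward(self, grad):
        n, to, f = grad.shape
        cols2 = self._cols.reshape(-1, self.k * self.cin)
        g2 = grad.reshape(-1, f).astype(_F32)
        self.grads = {
            "W": cols2.T @ g2,
            "b": g2.sum(axis=0),
        }
        dcols = (g2 @ self.params["W"].T).reshape(n, to, self.k, self.cin)
        dx = np.zeros(self._in_shape, dtype=_F32)
        for i in range(self.k):
            dx[:, i : i + to, :] += dcols[:, :, i, :]
        return dx

    def describe(self):
        return f"Conv1D(filters={self.f}, kernel={self.k})"


class BatchNorm1D(Layer):
    """Per-channel batch normalization over (batch, time)."""

    def __init__(self, channels: int, momentum: float = 0.9, eps: float = 1e-5):
        super().__init__()
        self.momentum = momentum
        self.eps = eps
        self.params = {
            "gamma": np.ones(channels, dtype=_F32),
            "beta": np.zeros(channels, dtype=_F32),
        }
        self.running_mean = np.zeros(channels, dtype=_F32)
        self.running_var = np.ones(channels, dtype=_F32)

    def forward(self, x, training, rng):
        axes = tuple(range(x.ndim - 1))
        if training:
            mean = x.mean(axis=axes)
            var = x.var(axis=axes)
            self.running_mean = (
                self.momentum * self.running_mean + (1 - self.momentum) * mean
            ).astype(_F32)
            self.running_var = (
                self.momentum * self.running_var + (1 - self.momentum) * var
            ).astype(_F32)
        else:
            mean, var = self.running_mean, self.running_var
        self._std = np.sqrt(var + self.eps).astype(_F32)
        self._xhat = ((x - mean) / self._std).astype(_F32)
        self._training = training
        return self.params["gamma"] * self._xhat + self.params["beta"]

    def backward(self, grad):
        axes = tuple(range(grad.ndim - 1))
        self.grads = {
            "gamma": (grad * self._xhat).sum(axis=axes).astype(_F32),
            "beta": grad.sum(axis=axes).astype(_F32),
        }
        g = grad * self.params["gamma"]
        if not self._training:
            return (g / self._std).astype(_F32)
        m = np.prod([grad.shape[a] for a in axes])
        dx = (
            g - g.mean(axis=axes) - self._xhat * (g * self._xhat).mean(axis=axes)
        ) / self._std
        return dx.astype(_F32)

    def describe(self):
        return "BatchNorm"


class ReLU(Layer):
    def forward(self, x, training, rng):
        self._mask = x > 0
        return np.where(self._mask, x, 0).astype(_F32)

    def backward(self, grad):
        return np.where(self._mask, grad, 0).astype(_F32)


class MaxPool1D(Layer):
    """Non-overlapping temporal max pooling; trailing remainder dropped."""

    def __init__(self, pool: int = 2):
        super().__init__()
        self.pool = int(pool)

    def forward(self, x, training, rng):
        n, t, c = x.shape
        to = t // self.pool
        if to == 0:
            raise ValueError(f"input length {t} shorter than pool {self.pool}")
        self._in_shape = x.shape
        xr = x[:, : to * self.pool].reshape(n, to, self.pool, c)
        self._argmax = xr.argmax(axis=2)
        return xr.max(axis=2)

    def backward(self, grad):
        n, to, c = grad.shape
        dxr = np.zeros((n, to, self.pool, c), dtype=_F32)
        np.put_along_axis(dxr, self._argmax[:, :, None, :], grad[:, :, None, :], axis=2)
        dx = np.zeros(self._in_shape, dtype=_F32)
        dx[:, : to * self.pool] = dxr.reshape(n, to * self.pool, c)
        return dx

    def describe(self):
        return f"MaxPool(pool={self.pool})"


class Dropout(Layer):
    def __init__(self, rate: float):
        super().__init__()
        if not 0 <= rate < 1:
            raise ValueError("dropout rate must lie in [0, 1)")
        self.rate = float(rate)

    def forward(self, x, training, rng):
        if not training or self.rate == 0:
            self._mask = None
            return x
        keep = 1.0 - self.rate
        self._mask = (rng.random(x.shape) < keep).astype(_F32) / keep
        return x * self._mask

    def backward(self, grad):
        if self._mask is None:
            return grad
        return grad * self._mask

    def describe(self):
        return f"Dropout(rate={self.rate})"


class Flatten(Layer):
    def forward(self, x, training, rng):
        self._in_shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, grad):
        return grad.reshape(self._in_shape)


class Dense(Layer):
    def __init__(self, in_features: int, units: int, rng):
        super().__init__()
        scale = np.sqrt(2.0 / in_features)
        self.params = {
            "W": rng.normal(0.0, scale, size=(in_features, units)).astype(_F32),
            "b": np.zeros(units, dtype=_F32),
        }
        self.weight_names = ("W",)
        self.units = units

    def forward(self, x, training, rng):
        self._x = x
        return x @ self.params["W"] + self.params["b"]

    def backward(self, grad):
        g = grad.astype(_F32)
        self.grads = {"W": self._x.T @ g, "b": g.sum(axis=0)}
        return g @ self.params["W"].T

    def describe(self):
        return f"Dense(units={self.units})"


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


class Network:
    """A feed-forward stack with a 2-way softmax cross-entropy head."""

    def __init__(self, layers: Sequence[Layer], n_classes: int = 2):
        self.layers = list(layers)
        self.n_classes = n_classes

    # -- forward / backward ------------------------------------------------
    def forward(self, x: np.ndarray, training: bool = False, rng=None) -> np.ndarray:
        """Logits for a batch."""
        out = np.asarray(x, dtype=_F32)
        for layer in self.layers:
            out = layer.forward(out, training, rng)
        return out

    def predict_proba(self, x: np.ndarray, batch_size: int = 512) -> np.ndarray:
        x = np.asarray(x, dtype=_F32)
        chunks = [
            softmax(self.forward(x[i : i + batch_size], training=False))
            for i in range(0, len(x), batch_size)
        ]
        return np.concatenate(chunks, axis=0)

    def loss_and_grads(
        self,
        x: np.ndarray,
        y: np.ndarray,
        rng,
        l1: float = 0.0,
        l2: float = 0.0,
    ) -> tuple[float, float]:
        """One training forward/backward pass.

        Returns (cross-entropy loss incl. penalties, batch accuracy) and
        leaves gradients in each layer.
        """
        logits = self.forward(x, training=True, rng=rng)
        probs = softmax(logits)
        n = len(y)
        ce = float(-np.mean(np.log(probs[np.arange(n), y] + 1e-12)))
        acc = float(np.mean(probs.argmax(axis=1) == y))

        grad = probs.astype(_F32)
        grad[np.arange(n), y] -= 1.0
        grad /= n
        for layer in reversed(self.layers):
            grad = layer.backward(grad)

        penalty = 0.0
        if l1 or l2:
            for layer in self.layers:
                for name in layer.weight_names:
                    w = layer.params[name]
                    if l1:
                        penalty += l1 * float(np.abs(w).sum())
                        layer.grads[name] += (l1 * np.sign(w)).astype(_F32)
                    if l2:
                        penalty += l2 * float((w * w).sum())
                        layer.grads[name] += (2.0 * l2 * w).astype(_F32)
        return ce + penalty, acc

    def evaluate(self, x: np.ndarray, y: np.ndarray, batch_size: int = 512):
        """(mean cross-entropy, accuracy) in inference mode."""
        probs = self.predict_proba(x, batch_size)
        n = len(y)
        loss = float(-np.mean(np.log(probs[np.arange(n), y] + 1e-12)))
        acc = float(np.mean(probs.argmax(axis=1) == y))
        return loss, acc

    # -- parameter management ---------------------------------------------
    def parameters(self) -> list[tuple[Layer, str]]:
        return [(layer, name) for layer in self.layers for name in layer.params]

    def get_weights(self) -> list[np.ndarray]:
        return [layer.params[name].copy() for layer, name in self.parameters()]

    def set_weights(self, weights: Sequence[np.ndarray]) -> None:
        handles = self.parameters()
        if len(weights) != len(handles):
            raise ValueError("weight list does not match architecture")
        for (layer, name), w in zip(handles, weights):
            layer.params[name] = w.astype(_F32).copy()

    def get_state(self) -> list[np.ndarray]:
        """Weights plus batch-norm running statistics."""
        state = self.get_weights()
        for layer in self.layers:
            if isinstance(layer, BatchNorm1D):
                state.append(layer.running_mean.copy())
                state.append(layer.running_var.copy())
        return state

    def set_state(self, state: Sequence[np.ndarray]) -> None:
        n_params = len(self.parameters())
        self.set_weights(state[:n_params])
        rest = list(state[n_params:])
        for layer in self.layers:
            if isinstance(layer, BatchNorm1D):
                layer.running_mean = rest.pop(0).astype(_F32).copy()
                layer.running_var = rest.pop(0).astype(_F32).copy()
        if rest:
            raise ValueError("state does not match architecture")

    def describe(self) -> list[str]:
        return [layer.describe() for layer in self.layers]


# -- optimizers -----------------------------------------------------------


class Optimizer:
    def __init__(self, lr: float):
        self.lr = float(lr)
        self._state: dict[tuple[int, str], dict[str, np.ndarray]] = {}

    def step(self, network: Network) -> None:
        for layer, name in network.parameters():
            g = layer.grads.get(name)
            if g is None:
                continue
            key = (id(layer), name)
            slot = self._state.setdefault(key, {})
            layer.params[name] = self._update(layer.params[name], g, slot)

    def _update(self, w, g, slot):
        raise NotImplementedError


class SGD(Optimizer):
    def __init__(self, lr: float, momentum: float = 0.9):
        super().__init__(lr)
        self.momentum = momentum

    def _update(self, w, g, slot):
        v = slot.get("v")
        if v is None:
            v = np.zeros_like(w)
        v = self.momentum * v - self.lr * g
        slot["v"] = v
        return w + v


class RMSprop(Optimizer):
    def __init__(self, lr: float, rho: float = 0.9, eps: float = 1e-7):
        super().__init__(lr)
        self.rho = rho
        self.eps = eps

    def _update(self, w, g, slot):
        s = slot.get("s")
        if s is None:
            s = np.zeros_like(w)
        s = self.rho * s + (1 - self.rho) * g * g
        slot["s"] = s
        return w - self.lr * g / (np.sqrt(s) + self.eps)


class Adam(Optimizer):
    def __init__(
        self, lr: float, beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-7
    ):
        super().__init__(lr)
        self.beta1, self.beta2, self.eps = beta1, beta2, eps

    def _update(self, w, g, slot):
        m = slot.get("m")
        if m is None:
            m = np.zeros_like(w)
            slot["t"] = 0
            slot["v"] = np.zeros_like(w)
        v = slot["v"]
        slot["t"] += 1
        t = slot["t"]
        m = self.beta1 * m + (1 - self.beta1) * g
        v = self.beta2 * v + (1 - self.beta2) * g * g
        slot["m"], slot["v"] = m, v
        mhat = m / (1 - self.beta1**t)
        vhat = v / (1 - self.beta2**t)
        return w - self.lr * mhat / (np.sqrt(vhat) + self.eps)


OPTIMIZERS = {"sgd": SGD, "rmsprop": RMSprop, "adam": Adam}


def make_optimizer(name: str, lr: float) -> Optimizer:
    if name not in OPTIMIZERS:
        raise ValueError(f"unknown optimizer {name!r}; expected {tuple(OPTIMIZERS)}")
    return OPTIMIZERS[name](lr)
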