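"""Minimal feed-forward/recurrent network engine in numpy.

Implements exactly the layer types the off-target classifier needs —
length-preserving 1-D convolution, bidirectional GRU with stacked layers,
dense layers, ReLU/sigmoid activations, inverted dropout — together with
reverse-mode gradients (including gradients with respect to the input,
needed for attribution) and an Adam optimizer.

Conventions
-----------
* Batches are ``(n, T, channels)`` for sequence layers and ``(n, features)``
  after :class:`Flatten`.
* ``forward(x, train=...)`` caches whatever ``backward(dy)`` needs;
  ``backward`` accumulates parameter gradients in ``layer.grads`` and
  returns the gradient with respect to the layer input.
* The GRU follows the common "reset-after" formulation with separate input
  and recurrent biases, so a bidirectional layer with ``u`` units over
  ``i`` input channels has ``2 * 3 * (u*(u+i) + 2u)`` parameters.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Conv1DSame",
    "Inception",
    "BiGRU",
    "Flatten",
    "Dense",
    "Dropout",
    "Network",
    "Adam",
    "sigmoid",
]


def sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


def _glorot(rng: np.random.Generator, shape: tuple[int, ...]) -> np.ndarray:
    fan_in, fan_out = shape[-2], shape[-1]
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape).astype(np.float64)


def _orthogonal(rng: np.random.Generator, rows: int, cols: int) -> np.ndarray:
    a = rng.standard_normal((max(rows, cols), min(rows, cols)))
    q, r = np.linalg.qr(a)
    q *= np.sign(np.diag(r))
    return (q if rows >= cols else q.T)[:rows, :cols]


class Layer:
    params: list[np.ndarray]
    grads: list[np.ndarray]

    def __init__(self):
        self.params = []
        self.grads = []

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        raise NotImplementedError

    def backward(self, dy: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def zero_grad(self) -> None:
        for g in self.grads:
            g[...] = 0.0


class Conv1DSame(Layer):
    """1-D convolution over the position axis with 'same' zero padding.

    Keeps the 24-position axis intact so downstream position indexing (and
    per-position attribution) stays meaningful.
    """

    def __init__(self, width: int, in_channels: int, filters: int,
                 rng: np.random.Generator, relu: bool = True):
        super().__init__()
        self.width = width
        self.relu = relu
        self.W = _glorot(rng, (width, in_channels, filters))
        self.b = np.zeros(filters)
        self.params = [self.W, self.b]
        self.grads = [np.zeros_like(self.W), np.zeros_like(self.b)]
        self.left = (width - 1) // 2

    def forward(self, x, train=False):
        n, T, c = x.shape
        xp = np.zeros((n, T + self.width - 1, c))
        xp[:, self.left:self.left + T] = x
        self._xp = xp
        y = np.tensordot(xp[:, 0:T], self.W[0], axes=([2], [0])) + self.b
        for k in range(1, self.width):
            y += np.tensordot(xp[:, k:k + T], self.W[k], axes=([2], [0]))
        if self.relu:
            self._mask = y > 0
            y = y * self._mask
        return y

    def backward(self, dy):
        if self.relu:
            dy = dy * self._mask
        n, T, _ = dy.shape
        dW, db = self.grads
        db += dy.sum(axis=(0, 1))
        dxp = np.zeros_like(self._xp)
        for k in range(self.width):
            dW[k] += np.tensordot(self._xp[:, k:k + T], dy, axes=([0, 1], [0, 1]))
            dxp[:, k:k + T] += np.tensordot(dy, self.W[k], axes=([2], [1]))
        return dxp[:, self.left:self.left + T]


class Inception(Layer):
    """Parallel convolution branches concatenated along the channel axis."""

    def __init__(self, widths: list[int], in_channels: int, filters: int,
                 rng: np.random.Generator):
        super().__init__()
        self.branches = [Conv1DSame(w, in_channels, filters, rng) for w in widths]
        self.filters = filters
        for br in self.branches:
            self.params += br.params
            self.grads += br.grads

    @property
    def out_channels(self) -> int:
        return self.filters * len(self.branches)

    def forward(self, x, train=False):
        return np.concatenate([br.forward(x, train) for br in self.branches], axis=2)

    def backward(self, dy):
        dx = None
        for i, br in enumerate(self.branches):
            chunk = dy[:, :, i * self.filters:(i + 1) * self.filters]
            g = br.backward(chunk)
            dx = g if dx is None else dx + g
        return dx


class _GRUDirection:
    """One direction of a GRU layer (gate order: update z, reset r, candidate h)."""

    def __init__(self, units: int, in_channels: int, rng: np.random.Generator,
                 reverse: bool):
        u, i = units, in_channels
        self.units, self.reverse = u, reverse
        self.W = _glorot(rng, (i, 3 * u))
        self.U = np.concatenate(
            [_orthogonal(rng, u, u) for _ in range(3)], axis=1)
        self.b_in = np.zeros(3 * u)
        self.b_rec = np.zeros(3 * u)
        self.params = [self.W, self.U, self.b_in, self.b_rec]
        self.grads = [np.zeros_like(p) for p in self.params]

    def forward(self, x):
        n, T, _ = x.shape
        u = self.units
        order = range(T - 1, -1, -1) if self.reverse else range(T)
        h = np.zeros((n, u))
        self._cache = []
        out = np.zeros((n, T, u))
        xW = x @ self.W + self.b_in  # all timesteps at once
        for t in order:
            hU = h @ self.U + self.b_rec
            z = sigmoid(xW[:, t, :u] + hU[:, :u])
            r = sigmoid(xW[:, t, u:2 * u] + hU[:, u:2 * u])
            hh = np.tanh(xW[:, t, 2 * u:] + r * hU[:, 2 * u:])
            h_new = z * h + (1.0 - z) * hh
            self._cache.append((t, x[:, t], h, z, r, hh, hU[:, 2 * u:]))
            h = h_new
            out[:, t] = h
        return out

    def backward(self, dy):
        u = self.units
        n, T, _ = dy.shape
        dW, dU, db_in, db_rec = self.grads
        dx = np.zeros((n, T, self.W.shape[0]))
        dh_next = np.zeros((n, u))
        for t, x_t, h_prev, z, r, hh, hU_h in reversed(self._cache):
            dh = dy[:, t] + dh_next
            dz = dh * (h_prev - hh)
            dhh = dh * (1.0 - z)
            dh_prev = dh * z
            da_h = dhh * (1.0 - hh * hh)
            dr = da_h * hU_h
            da_z = dz * z * (1.0 - z)
            da_r = dr * r * (1.0 - r)
            dxW = np.concatenate([da_z, da_r, da_h], axis=1)
            dhU = np.concatenate([da_z, da_r, da_h * r], axis=1)
            dW += x_t.T @ dxW
            dU += h_prev.T @ dhU
            db_in += dxW.sum(axis=0)
            db_rec += dhU.sum(axis=0)
            dx[:, t] = dxW @ self.W.T
            dh_next = dh_prev + dhU @ self.U.T
        return dx


class BiGRU(Layer):
    """Bidirectional GRU returning the full per-position output sequence."""

    def __init__(self, units: int, in_channels: int, rng: np.random.Generator):
        super().__init__()
        self.fwd = _GRUDirection(units, in_channels, rng, reverse=False)
        self.bwd = _GRUDirection(units, in_channels, rng, reverse=True)
        self.units = units
        self.params = self.fwd.params + self.bwd.params
        self.grads = self.fwd.grads + self.bwd.grads

    @property
    def out_channels(self) -> int:
        return 2 * self.units

    def forward(self, x, train=False):
        return np.concatenate([self.fwd.forward(x), self.bwd.forward(x)], axis=2)

    def backward(self, dy):
        u = self.units
        return self.fwd.backward(dy[:, :, :u]) + self.bwd.backward(dy[:, :, u:])


class Flatten(Layer):
    def forward(self, x, train=False):
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, dy):
        return dy.reshape(self._shape)


class Dense(Layer):
    def __init__(self, in_features: int, units: int, rng: np.random.Generator,
                 activation: str = "relu"):
        super().__init__()
        if activation not in ("relu", "sigmoid", "linear"):
            raise ValueError(f"unknown activation {activation!r}")
        self.activation = activation
        self.W = _glorot(rng, (in_features, units))
        self.b = np.zeros(units)
        self.params = [self.W, self.b]
        self.grads = [np.zeros_like(self.W), np.zeros_like(self.b)]

    def forward(self, x, train=False):
        self._x = x
        y = x @ self.W + self.b
        if self.activation == "relu":
            self._mask = y > 0
            return y * self._mask
        if self.activation == "sigmoid":
            self._out = sigmoid(y)
            return self._out
        return y

    def backward(self, dy):
        if self.activation == "relu":
            dy = dy * self._mask
        elif self.activation == "sigmoid":
            dy = dy * self._out * (1.0 - self._out)
        dW, db = self.grads
        dW += self._x.T @ dy
        db += dy.sum(axis=0)
        return dy @ self.W.T


class Dropout(Layer):
    """Inverted dropout; identity outside training mode."""

    def __init__(self, rate: float, rng: np.random.Generator):
        super().__init__()
        if not 0.0 <= rate < 1.0:
            raise ValueError("dropout rate must be in [0, 1)")
        self.rate = rate
        self.rng = rng

    def forward(self, x, train=False):
        if train and self.rate > 0.0:
            self._mask = (self.rng.random(x.shape) >= self.rate) / (1.0 - self.rate)
            return x * self._mask
        self._mask = None
        return x

    def backward(self, dy):
        return dy if self._mask is None else dy * self._mask


class Network:
    """A plain layer stack with shared forward/backward plumbing."""

    def __init__(self, layers: list[Layer]):
        self.layers = layers

    # -- core passes ----------------------------------------------------
    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x, train=train)
        return x

    def backward(self, dy: np.ndarray) -> np.ndarray:
        for layer in reversed(self.layers):
            dy = layer.backward(dy)
        return dy

    def zero_grad(self) -> None:
        for layer in self.layers:
            layer.zero_grad()

    # -- inference helpers ----------------------------------------------
    def predict(self, x: np.ndarray, batch_size: int = 2048) -> np.ndarray:
        if x.shape[0] == 0:
            probe = self.forward(np.zeros((1,) + x.shape[1:]))
            return np.zeros((0, probe.shape[1]))
        chunks = [self.forward(x[i:i + batch_size])
                  for i in range(0, x.shape[0], batch_size)]
        return np.concatenate(chunks, axis=0)

    def input_gradient(self, x: np.ndarray, output_index: int) -> np.ndarray:
        """d(sum of output[:, output_index]) / dx, one row per sample.

        Samples do not interact in any layer, so the batched gradient of
        the summed output equals the per-sample gradients.
        """
        out = self.forward(x, train=False)
        self.zero_grad()
        dy = np.zeros_like(out)
        dy[:, output_index] = 1.0
        return self.backward(dy)

    # -- parameters ------------------------------------------------------
    def parameters(self) -> list[np.ndarray]:
        return [p for layer in self.layers for p in layer.params]

    def gradients(self) -> list[np.ndarray]:
        return [g for layer in self.layers for g in layer.grads]

    @property
    def parameter_count(self) -> int:
        return int(sum(p.size for p in self.parameters()))

    def get_weights(self) -> list[np.ndarray]:
        return [p.copy() for p in self.parameters()]

    def set_weights(self, weights: list[np.ndarray]) -> None:
        params = self.parameters()
        if len(weights) != len(params):
            raise ValueError("weight list does not match network structure")
        for p, w in zip(params, weights):
            if p.shape != w.shape:
                raise ValueError(f"shape mismatch: {p.shape} vs {w.shape}")
            p[...] = w


class Adam:
    """Adam optimizer with the standard bias-corrected moment estimates."""

    def __init__(self, params: list[np.ndarray], lr: float = 1e-4,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.params = params
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self, grads: list[np.ndarray]) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        lr_t = self.lr * np.sqrt(1.0 - b2 ** self.t) / (1.0 - b1 ** self.t)
        for p, g, m, v in zip(self.params, grads, self.m, self.v):
            m *= b1
            m += (1.0 - b1) * g
            v *= b2
            v += (1.0 - b2) * g * g
            p -= lr_t * m / (np.sqrt(v) + self.eps)
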