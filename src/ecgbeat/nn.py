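"""A small, exact numpy backend for the package's three classifiers.

Implements forward and backward passes for the layers the architectures
need — LSTM (and its bidirectional wrapper), Dense, Conv1D with 'same'
padding, BatchNormalization, Dropout, Permute, GlobalAveragePooling1D —
plus the Adam optimizer and softmax cross-entropy.  Parameter layout and
counting follow the Keras conventions the architecture tables assume:

* LSTM: kernel ``(D, 4U)``, recurrent kernel ``(U, 4U)``, single bias
  ``(4U,)`` with gate order i, f, g, o → ``4·(U·(U+D) + U)`` parameters;
* Conv1D: ``C·k·F + F``;
* BatchNorm: gamma, beta plus the two running statistics → ``4·C``
  (the running statistics are counted but not trained).

Sequences are batch-major ``(N, T, D)``.  All randomness (initialization,
shuffling, dropout) flows from explicit generators, so identical seeds
give bit-identical training runs.
"""

from __future__ import annotations

import numpy as np


def _sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


def _glorot(rng: np.random.Generator, shape: tuple[int, ...]) -> np.ndarray:
    fan_in, fan_out = shape[0], shape[-1]
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape)


def _he_uniform(rng: np.random.Generator, shape: tuple[int, ...], fan_in: int) -> np.ndarray:
    limit = np.sqrt(6.0 / fan_in)
    return rng.uniform(-limit, limit, size=shape)


def _orthogonal(rng: np.random.Generator, shape: tuple[int, int]) -> np.ndarray:
    a = rng.standard_normal(shape)
    q, r = np.linalg.qr(a)
    return q * np.sign(np.diag(r))


class Layer:
    """Base layer: trainable ``params``/``grads`` are parallel lists."""

    def __init__(self) -> None:
        self.params: list[np.ndarray] = []
        self.grads: list[np.ndarray] = []

    @property
    def param_count(self) -> int:
        return int(sum(p.size for p in self.params))

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        raise NotImplementedError

    def backward(self, dy: np.ndarray) -> np.ndarray | None:
        raise NotImplementedError


class Dense(Layer):
    def __init__(self, in_dim: int, units: int, activation: str,
                 rng: np.random.Generator) -> None:
        super().__init__()
        self.activation = activation
        self.W = _glorot(rng, (in_dim, units))
        self.b = np.zeros(units)
        self.params = [self.W, self.b]
        self.grads = [np.zeros_like(self.W), np.zeros_like(self.b)]

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        self._x = x
        z = x @ self.W + self.b
        if self.activation == "tanh":
            self._a = np.tanh(z)
        elif self.activation == "relu":
            self._a = np.maximum(z, 0.0)
        elif self.activation in ("linear", "softmax"):
            # softmax is folded into the loss; forward emits logits here
            self._a = z
        else:
            raise ValueError(f"unknown activation {self.activation!r}")
        return self._a

    def backward(self, dy: np.ndarray) -> np.ndarray:
        if self.activation == "tanh":
            dz = dy * (1.0 - self._a ** 2)
        elif self.activation == "relu":
            dz = dy * (self._a > 0)
        else:
            dz = dy
        self.grads[0][...] = self._x.T @ dz
        self.grads[1][...] = dz.sum(axis=0)
        return dz @ self.W.T


class LSTM(Layer):
    """Unidirectional LSTM returning the final hidden state ``(N, U)``."""

    def __init__(self, in_dim: int, units: int, rng: np.random.Generator) -> None:
        super().__init__()
        self.units = units
        self.W = _glorot(rng, (in_dim, 4 * units))
        self.U = np.hstack([_orthogonal(rng, (units, units)) for _ in range(4)])
        self.b = np.zeros(4 * units)
        self.b[units:2 * units] = 1.0   # forget-gate bias
        self.params = [self.W, self.U, self.b]
        self.grads = [np.zeros_like(p) for p in self.params]

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        n, t_len, _ = x.shape
        u = self.units
        h = np.zeros((n, u))
        c = np.zeros((n, u))
        self._x = x
        self._cache = []
        xw = x.reshape(n * t_len, -1) @ self.W
        xw = xw.reshape(n, t_len, 4 * u)
        for t in range(t_len):
            z = xw[:, t, :] + h @ self.U + self.b
            i = _sigmoid(z[:, :u])
            f = _sigmoid(z[:, u:2 * u])
            g = np.tanh(z[:, 2 * u:3 * u])
            o = _sigmoid(z[:, 3 * u:])
            c_new = f * c + i * g
            tanh_c = np.tanh(c_new)
            h_new = o * tanh_c
            self._cache.append((h, c, i, f, g, o, tanh_c))
            h, c = h_new, c_new
        self._h_last = h
        return h

    def backward(self, dy: np.ndarray) -> None:
        n, t_len, d = self._x.shape
        u = self.units
        dW = self.grads[0]
        dU = self.grads[1]
        db = self.grads[2]
        dW[...] = 0.0
        dU[...] = 0.0
        db[...] = 0.0
        dh = dy.copy()
        dc = np.zeros((n, u))
        for t in range(t_len - 1, -1, -1):
            h_prev, c_prev, i, f, g, o, tanh_c = self._cache[t]
            do = dh * tanh_c
            dc = dc + dh * o * (1.0 - tanh_c ** 2)
            di = dc * g
            df = dc * c_prev
            dg = dc * i
            dz = np.concatenate([
                di * i * (1.0 - i),
                df * f * (1.0 - f),
                dg * (1.0 - g ** 2),
                do * o * (1.0 - o),
            ], axis=1)
            dW += self._x[:, t, :].T @ dz
            dU += h_prev.T @ dz
            db += dz.sum(axis=0)
            dh = dz @ self.U.T
            dc = dc * f
        return None


class Bidirectional(Layer):
    """Concatenate final states of a forward and a backward LSTM."""

    def __init__(self, in_dim: int, units: int, rng: np.random.Generator) -> None:
        super().__init__()
        self.fwd = LSTM(in_dim, units, rng)
        self.bwd = LSTM(in_dim, units, rng)
        self.params = self.fwd.params + self.bwd.params
        self.grads = self.fwd.grads + self.bwd.grads

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        hf = self.fwd.forward(x, training)
        hb = self.bwd.forward(x[:, ::-1, :], training)
        return np.concatenate([hf, hb], axis=1)

    def backward(self, dy: np.ndarray) -> None:
        u = self.fwd.units
        self.fwd.backward(dy[:, :u])
        self.bwd.backward(dy[:, u:])
        return None


class Conv1D(Layer):
    """1-D convolution over the time axis with Keras 'same' padding."""

    def __init__(self, in_channels: int, filters: int, kernel: int,
                 rng: np.random.Generator) -> None:
        super().__init__()
        self.kernel = kernel
        self.W = _he_uniform(rng, (kernel, in_channels, filters),
                             fan_in=kernel * in_channels)
        self.b = np.zeros(filters)
        self.params = [self.W, self.b]
        self.grads = [np.zeros_like(self.W), np.zeros_like(self.b)]
        self.pad_left = (kernel - 1) // 2
        self.pad_right = kernel - 1 - self.pad_left

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        n, t_len, _ = x.shape
        xp = np.pad(x, ((0, 0), (self.pad_left, self.pad_right), (0, 0)))
        self._xp = xp
        y = np.broadcast_to(self.b, (n, t_len, self.b.size)).copy()
        for k in range(self.kernel):
            y += xp[:, k:k + t_len, :] @ self.W[k]
        return y

    def backward(self, dy: np.ndarray) -> np.ndarray:
        n, t_len, _ = dy.shape
        dW, db = self.grads
        dW[...] = 0.0
        db[...] = dy.sum(axis=(0, 1))
        dxp = np.zeros_like(self._xp)
        for k in range(self.kernel):
            xk = self._xp[:, k:k + t_len, :]
            dW[k] = np.einsum("ntc,ntf->cf", xk, dy)
            dxp[:, k:k + t_len, :] += dy @ self.W[k].T
        return dxp[:, self.pad_left:self.pad_left + t_len, :]


class BatchNorm(Layer):
    """Channel-wise batch normalization over the batch and time axes.

    Running statistics are held as parameters so they are counted (the
    printed BN parameter totals include them) but flagged non-trainable.
    """

    def __init__(self, channels: int, momentum: float = 0.99,
                 eps: float = 1e-3) -> None:
        super().__init__()
        self.eps = eps
        self.momentum = momentum
        self.gamma = np.ones(channels)
        self.beta = np.zeros(channels)
        self.running_mean = np.zeros(channels)
        self.running_var = np.ones(channels)
        self.params = [self.gamma, self.beta, self.running_mean, self.running_var]
        self.grads = [np.zeros_like(self.gamma), np.zeros_like(self.beta)]
        self.trainable_params = self.params[:2]

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        axes = tuple(range(x.ndim - 1))
        if training:
            mean = x.mean(axis=axes)
            var = x.var(axis=axes)
            self.running_mean[...] = self.momentum * self.running_mean + (1 - self.momentum) * mean
            self.running_var[...] = self.momentum * self.running_var + (1 - self.momentum) * var
        else:
            mean, var = self.running_mean, self.running_var
        self._std = np.sqrt(var + self.eps)
        self._xhat = (x - mean) / self._std
        self._m = int(np.prod([x.shape[a] for a in axes]))
        self._training = training
        return self.gamma * self._xhat + self.beta

    def backward(self, dy: np.ndarray) -> np.ndarray:
        axes = tuple(range(dy.ndim - 1))
        self.grads[0][...] = (dy * self._xhat).sum(axis=axes)
        self.grads[1][...] = dy.sum(axis=axes)
        if not self._training:
            return dy * self.gamma / self._std
        m = self._m
        dxhat = dy * self.gamma
        return (dxhat - dxhat.mean(axis=axes)
                - self._xhat * (dxhat * self._xhat).mean(axis=axes)) / self._std


class Dropout(Layer):
    def __init__(self, rate: float, rng: np.random.Generator) -> None:
        super().__init__()
        self.rate = rate
        self.rng = rng

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        if not training or self.rate == 0.0:
            self._mask = None
            return x
        self._mask = (self.rng.random(x.shape) >= self.rate) / (1.0 - self.rate)
        return x * self._mask

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return dy if self._mask is None else dy * self._mask


class Permute(Layer):
    """Swap the time and channel axes: ``(N, T, C) -> (N, C, T)``."""

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        return np.transpose(x, (0, 2, 1))

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return np.transpose(dy, (0, 2, 1))


class GlobalAvgPool(Layer):
    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        self._t = x.shape[1]
        return x.mean(axis=1)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return np.repeat(dy[:, None, :], self._t, axis=1) / self._t


# ---------------------------------------------------------------------------
# Networks
# ---------------------------------------------------------------------------

class Network:
    """Base: a classifier mapping ``(N, T, 1)`` sequences to logits."""

    layers: list[Layer]

    def count_params(self) -> int:
        return int(sum(layer.param_count for layer in self.layers))

    def trainable(self) -> list[tuple[np.ndarray, np.ndarray]]:
        pairs = []
        for layer in self.layers:
            params = getattr(layer, "trainable_params", layer.params)
            for p, g in zip(params, layer.grads):
                pairs.append((p, g))
        return pairs

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        raise NotImplementedError

    def backward(self, dlogits: np.ndarray) -> None:
        raise NotImplementedError

    def predict_proba(self, x: np.ndarray, batch_size: int = 1024) -> np.ndarray:
        outs = []
        for i in range(0, len(x), batch_size):
            logits = self.forward(x[i:i + batch_size], training=False)
            outs.append(softmax(logits))
        return np.vstack(outs)


class Chain(Network):
    """A linear stack (LSTM-Sequential and Bi-LSTM)."""

    def __init__(self, layers: list[Layer]) -> None:
        self.layers = layers

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x, training)
        return x

    def backward(self, dlogits: np.ndarray) -> None:
        dy = dlogits
        for layer in reversed(self.layers):
            dy = layer.backward(dy)
            if dy is None:
                break


class TwoBranch(Network):
    """The LSTM-FCN graph: an LSTM branch and a convolutional branch on the
    same input, concatenated before the softmax classifier."""

    def __init__(self, lstm_branch: list[Layer], conv_branch: list[Layer],
                 head: Dense) -> None:
        self.lstm_branch = lstm_branch
        self.conv_branch = conv_branch
        self.head = head
        self.layers = lstm_branch + conv_branch + [head]

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        a = x
        for layer in self.lstm_branch:
            a = layer.forward(a, training)
        b = x
        for layer in self.conv_branch:
            b = layer.forward(b, training)
        self._split = a.shape[1]
        return self.head.forward(np.concatenate([a, b], axis=1), training)

    def backward(self, dlogits: np.ndarray) -> None:
        dcat = self.head.backward(dlogits)
        da, db = dcat[:, :self._split], dcat[:, self._split:]
        for layer in reversed(self.lstm_branch):
            da = layer.backward(da)
            if da is None:
                break
        for layer in reversed(self.conv_branch):
            db = layer.backward(db)
            if db is None:
                break


# ---------------------------------------------------------------------------
# Loss and optimizer
# ---------------------------------------------------------------------------

def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def softmax_cross_entropy(logits: np.ndarray, onehot: np.ndarray) -> tuple[float, np.ndarray]:
    """Mean categorical cross-entropy and its gradient w.r.t. the logits."""
    probs = softmax(logits)
    n = len(logits)
    loss = -np.sum(onehot * np.log(np.clip(probs, 1e-12, None))) / n
    return float(loss), (probs - onehot) / n


class Adam:
    def __init__(self, pairs: list[tuple[np.ndarray, np.ndarray]],
                 lr: float = 0.001, beta1: float = 0.9, beta2: float = 0.999,
                 eps: float = 1e-7) -> None:
        self.pairs = pairs
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p) for p, _ in pairs]
        self.v = [np.zeros_like(p) for p, _ in pairs]
        self.t = 0

    def step(self) -> None:
        self.t += 1
        b1t = 1.0 - self.beta1 ** self.t
        b2t = 1.0 - self.beta2 ** self.t
        for (p, g), m, v in zip(self.pairs, self.m, self.v):
            m *= self.beta1
            m += (1 - self.beta1) * g
            v *= self.beta2
            v += (1 - self.beta2) * g * g
            p -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)
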