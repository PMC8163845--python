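"""Neural-network layers used by the Siamese retention-time model.

All layers hold their parameters as :class:`~xlrt._nn.autograd.Tensor`
objects with ``requires_grad=True`` and expose them through
:meth:`Layer.parameters` for the optimizer.  Stochastic layers (dropout)
draw from the ``numpy.random.Generator`` passed at call time so that a
single master seed makes training fully reproducible.
"""

from __future__ import annotations

import numpy as np

from .autograd import Tensor, concatenate, gather_rows


class Layer:
    def parameters(self):
        return [v for v in vars(self).values() if isinstance(v, Tensor) and v.requires_grad]

    def state_arrays(self):
        """Name -> ndarray map of everything needed to restore the layer."""
        out = {}
        for name, v in vars(self).items():
            if isinstance(v, Tensor) and v.requires_grad:
                out[name] = v.data
            elif isinstance(v, np.ndarray):
                out[name] = v
        return out

    def load_state_arrays(self, state):
        for name, arr in state.items():
            cur = getattr(self, name)
            if isinstance(cur, Tensor):
                cur.data = np.array(arr, dtype=np.float64)
            else:
                setattr(self, name, np.array(arr))


def _glorot(rng: np.random.Generator, fan_in: int, fan_out: int, shape) -> np.ndarray:
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape)


class Embedding(Layer):
    """Integer token ids -> dense vectors; id 0 is the padding token."""

    def __init__(self, vocab_size: int, dim: int, rng: np.random.Generator):
        self.weight = Tensor(_glorot(rng, vocab_size, dim, (vocab_size, dim)), requires_grad=True)

    def __call__(self, idx: np.ndarray) -> Tensor:
        return gather_rows(self.weight, idx)


class Dense(Layer):
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator):
        self.weight = Tensor(_glorot(rng, n_in, n_out, (n_in, n_out)), requires_grad=True)
        self.bias = Tensor(np.zeros(n_out), requires_grad=True)

    def __call__(self, x: Tensor) -> Tensor:
        return x @ self.weight + self.bias


class Dropout(Layer):
    def __init__(self, rate: float):
        self.rate = float(rate)

    def __call__(self, x: Tensor, training: bool, rng: np.random.Generator) -> Tensor:
        if not training or self.rate <= 0.0:
            return x
        keep = 1.0 - self.rate
        mask = (rng.random(x.shape) < keep) / keep
        return x * mask


class BatchNorm(Layer):
    """Batch normalization over axis 0 with running statistics for inference."""

    def __init__(self, dim: int, momentum: float = 0.9, eps: float = 1e-3):
        self.gamma = Tensor(np.ones(dim), requires_grad=True)
        self.beta = Tensor(np.zeros(dim), requires_grad=True)
        self.running_mean = np.zeros(dim)
        self.running_var = np.ones(dim)
        self.momentum = momentum
        self.eps = eps

    def __call__(self, x: Tensor, training: bool) -> Tensor:
        if training and x.shape[0] > 1:
            mu = x.mean(axis=0, keepdims=True)
            centred = x - mu
            var = (centred * centred).mean(axis=0, keepdims=True)
            self.running_mean = (
                self.momentum * self.running_mean + (1 - self.momentum) * mu.data.ravel()
            )
            self.running_var = (
                self.momentum * self.running_var + (1 - self.momentum) * var.data.ravel()
            )
            xhat = centred * ((var + self.eps) ** -0.5)
        else:
            xhat = (x - self.running_mean) * ((self.running_var + self.eps) ** -0.5)
        return xhat * self.gamma + self.beta


class GRU(Layer):
    """Gated recurrent unit returning the hidden state at the last real token.

    Padded positions (mask 0) carry the previous hidden state through, so
    trailing zero-padding never influences the output.
    """

    def __init__(self, n_in: int, units: int, rng: np.random.Generator):
        h = units
        self.w = Tensor(_glorot(rng, n_in, 3 * h, (n_in, 3 * h)), requires_grad=True)
        self.u = Tensor(_glorot(rng, h, 3 * h, (h, 3 * h)), requires_grad=True)
        self.bias = Tensor(np.zeros(3 * h), requires_grad=True)
        self.units = h

    def __call__(self, x: Tensor, mask: np.ndarray) -> Tensor:
        batch, steps = mask.shape
        h = self.units
        state = Tensor(np.zeros((batch, h)))
        for t in range(steps):
            if not mask[:, t].any():
                break
            xt = x[:, t, :]
            px = xt @ self.w + self.bias
            ph = state @ self.u
            z = (px[:, :h] + ph[:, :h]).sigmoid()
            r = (px[:, h : 2 * h] + ph[:, h : 2 * h]).sigmoid()
            n = (px[:, 2 * h :] + r * ph[:, 2 * h :]).tanh()
            new = (1.0 - z) * n + z * state
            m = mask[:, t : t + 1]
            state = m * new + (1.0 - m) * state
        return state


class LSTM(Layer):
    def __init__(self, n_in: int, units: int, rng: np.random.Generator):
        h = units
        self.w = Tensor(_glorot(rng, n_in, 4 * h, (n_in, 4 * h)), requires_grad=True)
        self.u = Tensor(_glorot(rng, h, 4 * h, (h, 4 * h)), requires_grad=True)
        self.bias = Tensor(np.zeros(4 * h), requires_grad=True)
        self.units = h

    def __call__(self, x: Tensor, mask: np.ndarray) -> Tensor:
        batch, steps = mask.shape
        h = self.units
        state = Tensor(np.zeros((batch, h)))
        cell = Tensor(np.zeros((batch, h)))
        for t in range(steps):
            if not mask[:, t].any():
                break
            p = x[:, t, :] @ self.w + state @ self.u + self.bias
            i = p[:, :h].sigmoid()
            f = p[:, h : 2 * h].sigmoid()
            g = p[:, 2 * h : 3 * h].tanh()
            o = p[:, 3 * h :].sigmoid()
            new_cell = f * cell + i * g
            new_state = o * new_cell.tanh()
            m = mask[:, t : t + 1]
            state = m * new_state + (1.0 - m) * state
            cell = m * new_cell + (1.0 - m) * cell
        return state


def combine(a: Tensor, b: Tensor, how: str) -> Tensor:
    """Merge the two Siamese branch outputs."""
    if how == "add":
        return a + b
    if how == "multiply":
        return a * b
    if how == "concatenate":
        return concatenate([a, b], axis=-1)
    raise ValueError(f"unknown combination '{how}'")


class Adam:
    def __init__(self, params, lr: float = 1e-3, beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-7):
        self.params = list(params)
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]
        self.t = 0

    def zero_grad(self):
        for p in self.params:
            p.grad = None

    def step(self):
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for p, m, v in zip(self.params, self.m, self.v):
            if p.grad is None:
                continue
            g = p.grad
            m *= b1
            m += (1 - b1) * g
            v *= b2
            v += (1 - b2) * g * g
            mhat = m / (1 - b1 ** self.t)
            vhat = v / (1 - b2 ** self.t)
            p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


def mse_loss(pred: Tensor, target: np.ndarray) -> Tensor:
    d = pred - np.asarray(target, dtype=np.float64)
    return (d * d).mean()


def bce_with_logits(logits: Tensor, target: np.ndarray) -> Tensor:
    """Mean binary cross-entropy computed stably from logits."""
    z = np.asarray(target, dtype=np.float64)
    return (logits.relu() - logits * z + (-logits.abs()).softplus()).mean()
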