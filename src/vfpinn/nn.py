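"""Neural-network building blocks on the package's autodiff tensors.

Implements exactly the components the inverse model needs: dense layers,
layer normalization, a single-layer LSTM usable as encoder or (teacher-forced)
decoder, a residual MLP head, the Adam optimizer and a reduce-on-plateau
learning-rate schedule.  Initialization is fully seeded; two modules built
from the same seed produce identical parameters and outputs.
"""

from __future__ import annotations

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor

__all__ = ["Module", "Linear", "LayerNorm", "LSTM", "ResidualMLP",
           "Adam", "ReduceLROnPlateau"]


class Module:
    """Parameter container with torch-like ergonomics (no buffers, no modes)."""

    def parameters(self):
        out = []
        for v in self.__dict__.values():
            if isinstance(v, Tensor) and v.requires_grad:
                out.append(v)
            elif isinstance(v, Module):
                out.extend(v.parameters())
            elif isinstance(v, (list, tuple)):
                for item in v:
                    if isinstance(item, Module):
                        out.extend(item.parameters())
                    elif isinstance(item, Tensor) and item.requires_grad:
                        out.append(item)
        return out

    def zero_grad(self):
        for p in self.parameters():
            p.grad = None

    def n_parameters(self):
        return int(sum(p.size for p in self.parameters()))

    def state_dict(self):
        return {i: p.value.copy() for i, p in enumerate(self.parameters())}

    def load_state_dict(self, state):
        for i, p in enumerate(self.parameters()):
            p.value[...] = state[i]


def _glorot(rng, fan_in, fan_out, shape):
    lim = np.sqrt(6.0 / (fan_in + fan_out))
    return Tensor(rng.uniform(-lim, lim, size=shape), requires_grad=True)


class Linear(Module):
    def __init__(self, in_features: int, out_features: int, rng: np.random.Generator):
        self.W = _glorot(rng, in_features, out_features, (in_features, out_features))
        self.b = Tensor(np.zeros(out_features), requires_grad=True)

    def __call__(self, x):
        return x @ self.W + self.b


class LayerNorm(Module):
    def __init__(self, n_features: int, eps: float = 1e-5):
        self.gamma = Tensor(np.ones(n_features), requires_grad=True)
        self.beta = Tensor(np.zeros(n_features), requires_grad=True)
        self.eps = eps

    def __call__(self, x):
        mu = x.mean(axis=-1, keepdims=True)
        xc = x - mu
        var = (xc * xc).mean(axis=-1, keepdims=True)
        return xc / ad.sqrt(var + self.eps) * self.gamma + self.beta


class LSTM(Module):
    """Single-layer LSTM; processes a (T, F) sequence, returns (T, H) hiddens.

    Gate ordering i, f, g, o. Forget-gate bias initialized to 1 (standard
    remedy for vanishing memory early in training).
    """

    def __init__(self, input_size: int, hidden_size: int, rng: np.random.Generator):
        H, F = hidden_size, input_size
        self.W_ih = _glorot(rng, F, 4 * H, (F, 4 * H))
        self.W_hh = _glorot(rng, H, 4 * H, (H, 4 * H))
        b = np.zeros(4 * H)
        b[H:2 * H] = 1.0
        self.b = Tensor(b, requires_grad=True)
        self.hidden_size = H

    def step(self, x_t, h, c):
        H = self.hidden_size
        gates = x_t @ self.W_ih + h @ self.W_hh + self.b
        i = ad.sigmoid(gates[..., 0:H])
        f = ad.sigmoid(gates[..., H:2 * H])
        g = ad.tanh(gates[..., 2 * H:3 * H])
        o = ad.sigmoid(gates[..., 3 * H:4 * H])
        c_new = f * c + i * g
        h_new = o * ad.tanh(c_new)
        return h_new, c_new

    def __call__(self, seq, h0=None, c0=None):
        H = self.hidden_size
        h = Tensor(np.zeros(H)) if h0 is None else h0
        c = Tensor(np.zeros(H)) if c0 is None else c0
        outs = []
        T = ad.asarray(seq).shape[0]
        for t in range(T):
            h, c = self.step(seq[t], h, c)
            outs.append(h)
        return ad.stack(outs, axis=0), (h, c)


class ResidualMLP(Module):
    """Four-layer (by default) ReLU MLP with residual connections and layer
    norms on the hidden width, plus a linear output head."""

    def __init__(self, width: int, depth: int, out_features: int,
                 rng: np.random.Generator, in_features: int | None = None):
        in_features = width if in_features is None else in_features
        self.inp = Linear(in_features, width, rng) if in_features != width else None
        self.layers = [Linear(width, width, rng) for _ in range(depth)]
        self.norms = [LayerNorm(width) for _ in range(depth)]
        self.head = Linear(width, out_features, rng)

    def __call__(self, x):
        if self.inp is not None:
            x = self.inp(x)
        for lin, norm in zip(self.layers, self.norms):
            x = x + ad.relu(lin(norm(x)))
        return self.head(x)


class Adam:
    """Adam with the standard bias correction (β1=0.9, β2=0.999)."""

    def __init__(self, params, lr: float = 1e-2, betas=(0.9, 0.999), eps: float = 1e-8):
        self.params = list(params)
        self.lr = float(lr)
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.value) for p in self.params]
        self.v = [np.zeros_like(p.value) for p in self.params]

    def step(self):
        self.t += 1
        b1t = 1.0 - self.b1 ** self.t
        b2t = 1.0 - self.b2 ** self.t
        for p, m, v in zip(self.params, self.m, self.v):
            if p.grad is None:
                continue
            g = p.grad
            m *= self.b1
            m += (1 - self.b1) * g
            v *= self.b2
            v += (1 - self.b2) * g * g
            p.value -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)

    def zero_grad(self):
        for p in self.params:
            p.grad = None


class ReduceLROnPlateau:
    """Multiply lr by `factor` when the monitored loss stalls for `patience`
    evaluations; never below `min_lr`."""

    def __init__(self, optimizer: Adam, factor: float = 0.5, patience: int = 500,
                 min_lr: float = 5e-5, threshold: float = 1e-4):
        self.opt = optimizer
        self.factor = factor
        self.patience = patience
        self.min_lr = min_lr
        self.threshold = threshold
        self.best = np.inf
        self.bad = 0

    def step(self, loss: float):
        if loss < self.best * (1.0 - self.threshold):
            self.best = loss
            self.bad = 0
        else:
            self.bad += 1
            if self.bad > self.patience:
                self.opt.lr = max(self.opt.lr * self.factor, self.min_lr)
                self.bad = 0
        return self.opt.lr
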