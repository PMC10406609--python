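"""Feed-forward building blocks and the AdamW optimizer on top of `_autograd`.

Layers hold their parameters as `Tensor`s with `requires_grad=True`;
initialization is driven by an explicit `numpy.random.Generator` so every
model build is reproducible from a seed.
"""

from __future__ import annotations

import numpy as np

from ._autograd import Tensor

__all__ = ["Linear", "LayerNorm", "Dropout", "MLP", "Module", "AdamW"]


class Module:
    """Parameter-container base; children are discovered by attribute walk."""

    def parameters(self) -> list[Tensor]:
        params: list[Tensor] = []
        seen: set[int] = set()
        stack = [self]
        while stack:
            obj = stack.pop()
            for v in vars(obj).values():
                if isinstance(v, Tensor) and v.requires_grad and id(v) not in seen:
                    seen.add(id(v))
                    params.append(v)
                elif isinstance(v, Module):
                    stack.append(v)
                elif isinstance(v, (list, tuple)):
                    stack.extend(x for x in v if isinstance(x, Module))
        return params

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.grad = None

    def state_arrays(self) -> list[np.ndarray]:
        return [p.data for p in self.parameters()]


class Linear(Module):
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator,
                 zero_init: bool = False):
        scale = 0.0 if zero_init else np.sqrt(2.0 / (n_in + n_out))
        self.weight = Tensor(rng.normal(0.0, scale or 1e-12, size=(n_in, n_out)),
                             requires_grad=True)
        self.bias = Tensor(np.zeros(n_out), requires_grad=True)

    def __call__(self, x: Tensor) -> Tensor:
        return x @ self.weight + self.bias


class LayerNorm(Module):
    def __init__(self, n: int, eps: float = 1e-5):
        self.gain = Tensor(np.ones(n), requires_grad=True)
        self.bias = Tensor(np.zeros(n), requires_grad=True)
        self.eps = eps

    def __call__(self, x: Tensor) -> Tensor:
        mu = x.mean(axis=-1, keepdims=True)
        centered = x - mu
        var = (centered * centered).mean(axis=-1, keepdims=True)
        return centered * ((var + self.eps) ** -0.5) * self.gain + self.bias


class Dropout(Module):
    """Inverted dropout; identity when `training` is False or rate is 0."""

    def __init__(self, rate: float):
        self.rate = float(rate)

    def __call__(self, x: Tensor, rng: np.random.Generator | None,
                 training: bool) -> Tensor:
        if not training or self.rate <= 0.0 or rng is None:
            return x
        keep = 1.0 - self.rate
        mask = (rng.random(x.shape) < keep) / keep
        return x * Tensor(mask)


class MLP(Module):
    """`n_layers` hidden blocks of Linear → LayerNorm → ReLU → Dropout."""

    def __init__(self, n_in: int, n_hidden: int, n_layers: int,
                 rng: np.random.Generator, dropout: float = 0.1,
                 use_layernorm: bool = True):
        self.linears: list[Linear] = []
        self.norms: list[LayerNorm | None] = []
        d = n_in
        for _ in range(n_layers):
            self.linears.append(Linear(d, n_hidden, rng))
            self.norms.append(LayerNorm(n_hidden) if use_layernorm else None)
            d = n_hidden
        self.dropout = Dropout(dropout)
        self.n_out = d

    def parameters(self) -> list[Tensor]:
        params: list[Tensor] = []
        for lin, norm in zip(self.linears, self.norms):
            params.extend(lin.parameters())
            if norm is not None:
                params.extend(norm.parameters())
        return params

    def __call__(self, x: Tensor, rng: np.random.Generator | None = None,
                 training: bool = False) -> Tensor:
        h = x
        for lin, norm in zip(self.linears, self.norms):
            h = lin(h)
            if norm is not None:
                h = norm(h)
            h = h.relu()
            h = self.dropout(h, rng, training)
        return h


class AdamW:
    """Decoupled weight decay Adam (betas 0.9/0.999, eps 1e-8 by default)."""

    def __init__(self, params: list[Tensor], lr: float = 1e-4,
                 weight_decay: float = 1e-3, betas: tuple[float, float] = (0.9, 0.999),
                 eps: float = 1e-8):
        self.params = params
        self.lr = lr
        self.weight_decay = weight_decay
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in params]
        self.v = [np.zeros_like(p.data) for p in params]

    def step(self) -> None:
        self.t += 1
        b1t = 1.0 - self.b1**self.t
        b2t = 1.0 - self.b2**self.t
        for i, p in enumerate(self.params):
            g = p.grad
            if g is None:
                continue
            self.m[i] = self.b1 * self.m[i] + (1.0 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1.0 - self.b2) * g * g
            mhat = self.m[i] / b1t
            vhat = self.v[i] / b2t
            p.data -= self.lr * (mhat / (np.sqrt(vhat) + self.eps)
                                 + self.weight_decay * p.data)

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None
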