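"""Small neural-network layer on top of the autodiff engine: modules,
linear layers, MLPs and an Adam optimizer. Initialization is fully
deterministic given a numpy Generator."""

from __future__ import annotations

import numpy as np

from ._autodiff import Tensor, concat

__all__ = ["Parameter", "Module", "Linear", "MLP", "Adam", "concat"]


class Parameter(Tensor):
    def __init__(self, data):
        super().__init__(data, requires_grad=True)


class Module:
    """Container with recursive parameter discovery (torch-like, minimal)."""

    def parameters(self):
        out = []
        for value in vars(self).values():
            out.extend(_collect(value))
        return out

    def zero_grad(self):
        for p in self.parameters():
            p.grad = None

    def state_dict(self):
        return {name: p.data.copy() for name, p in self.named_parameters()}

    def load_state_dict(self, state):
        for name, p in self.named_parameters():
            p.data[...] = state[name]

    def named_parameters(self, prefix=""):
        out = []
        for key, value in vars(self).items():
            out.extend(_collect_named(value, f"{prefix}{key}"))
        return out


def _collect(value):
    if isinstance(value, Parameter):
        return [value]
    if isinstance(value, Module):
        return value.parameters()
    if isinstance(value, (list, tuple)):
        out = []
        for v in value:
            out.extend(_collect(v))
        return out
    return []


def _collect_named(value, name):
    if isinstance(value, Parameter):
        return [(name, value)]
    if isinstance(value, Module):
        return value.named_parameters(prefix=name + ".")
    if isinstance(value, (list, tuple)):
        out = []
        for i, v in enumerate(value):
            out.extend(_collect_named(v, f"{name}.{i}"))
        return out
    return []


class Linear(Module):
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator):
        scale = np.sqrt(2.0 / (n_in + n_out))
        self.W = Parameter(rng.normal(0.0, scale, size=(n_in, n_out)))
        self.b = Parameter(np.zeros(n_out))

    def __call__(self, x: Tensor) -> Tensor:
        return x @ self.W + self.b


class MLP(Module):
    """Fully connected stack; tanh between layers, linear output."""

    def __init__(self, dims, rng: np.random.Generator, activation="tanh"):
        self.layers = [Linear(a, b, rng) for a, b in zip(dims[:-1], dims[1:])]
        self.activation = activation

    def __call__(self, x: Tensor) -> Tensor:
        for i, layer in enumerate(self.layers):
            x = layer(x)
            if i < len(self.layers) - 1:
                x = x.tanh() if self.activation == "tanh" else x.relu()
        return x


class Adam:
    def __init__(self, params, lr=1e-3, betas=(0.9, 0.999), eps=1e-8):
        self.params = list(params)
        self.lr, self.betas, self.eps = lr, betas, eps
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]
        self.t = 0

    def zero_grad(self):
        for p in self.params:
            p.grad = None

    def step(self):
        b1, b2 = self.betas
        self.t += 1
        for p, m, v in zip(self.params, self.m, self.v):
            if p.grad is None:
                continue
            g = p.grad
            m[...] = b1 * m + (1 - b1) * g
            v[...] = b2 * v + (1 - b2) * g * g
            mh = m / (1 - b1 ** self.t)
            vh = v / (1 - b2 ** self.t)
            p.data -= self.lr * mh / (np.sqrt(vh) + self.eps)
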