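"""Small neural-network toolkit built on :mod:`gyrosde.autodiff`.

Provides exactly the layers the model needs: linear maps, MLPs with tanh
or GELU activations, layer normalization, and an AdamW optimizer with
decoupled weight decay. Initialization is always driven by an explicit
:class:`numpy.random.Generator` so that every construction is reproducible
from a seed.
"""

from __future__ import annotations

import numpy as np

from .autodiff import Tensor


class Module:
    """Base class: tracks parameters for optimization/serialization."""

    def parameters(self) -> list[Tensor]:
        params: list[Tensor] = []
        for v in self.__dict__.values():
            if isinstance(v, Tensor) and v.requires_grad:
                params.append(v)
            elif isinstance(v, Module):
                params.extend(v.parameters())
            elif isinstance(v, (list, tuple)):
                for item in v:
                    if isinstance(item, Module):
                        params.extend(item.parameters())
                    elif isinstance(item, Tensor) and item.requires_grad:
                        params.append(item)
        return params

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.grad = None

    # -- flat serialization (state as a list of arrays, fixed order) ---
    def state_arrays(self) -> list[np.ndarray]:
        return [p.data.copy() for p in self.parameters()]

    def load_state_arrays(self, arrays: list[np.ndarray]) -> None:
        params = self.parameters()
        if len(arrays) != len(params):
            raise ValueError(
                f"state mismatch: {len(arrays)} arrays for {len(params)} parameters"
            )
        for p, a in zip(params, arrays):
            a = np.asarray(a, dtype=np.float64)
            if a.shape != p.data.shape:
                raise ValueError(f"shape mismatch {a.shape} vs {p.data.shape}")
            p.data = a.copy()


class Linear(Module):
    """Affine map with Glorot-uniform weights."""

    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator,
                 zero_init: bool = False):
        if zero_init:
            w = np.zeros((n_in, n_out))
        else:
            limit = np.sqrt(6.0 / (n_in + n_out))
            w = rng.uniform(-limit, limit, size=(n_in, n_out))
        self.w = Tensor(w, requires_grad=True)
        self.b = Tensor(np.zeros(n_out), requires_grad=True)

    def __call__(self, x: Tensor) -> Tensor:
        return x @ self.w + self.b


def gelu(x: Tensor) -> Tensor:
    """GELU via the tanh approximation (GPT2 convention)."""
    c = np.sqrt(2.0 / np.pi)
    return 0.5 * x * (1.0 + (c * (x + 0.044715 * x ** 3.0)).tanh())


class MLP(Module):
    """Feed-forward network with a configurable hidden stack.

    ``activation`` applies after every hidden layer; the output layer is
    linear. ``zero_last`` zero-initializes the output layer, which makes
    the network the zero map at construction (useful for drift fields and
    for the analytic zero-network checks).
    """

    def __init__(self, n_in: int, hidden: tuple, n_out: int,
                 rng: np.random.Generator, activation: str = "tanh",
                 zero_last: bool = False):
        dims = [n_in, *hidden, n_out]
        self.layers = [
            Linear(dims[i], dims[i + 1], rng,
                   zero_init=(zero_last and i == len(dims) - 2))
            for i in range(len(dims) - 1)
        ]
        if activation not in ("tanh", "gelu"):
            raise ValueError(f"unknown activation {activation!r}")
        self.activation = activation

    def __call__(self, x: Tensor) -> Tensor:
        for i, layer in enumerate(self.layers):
            x = layer(x)
            if i < len(self.layers) - 1:
                x = x.tanh() if self.activation == "tanh" else gelu(x)
        return x


class LayerNorm(Module):
    def __init__(self, dim: int, eps: float = 1e-5):
        self.gamma = Tensor(np.ones(dim), requires_grad=True)
        self.beta = Tensor(np.zeros(dim), requires_grad=True)
        self.eps = eps

    def __call__(self, x: Tensor) -> Tensor:
        mu = x.mean(axis=-1, keepdims=True)
        xc = x - mu
        var = (xc * xc).mean(axis=-1, keepdims=True)
        return xc * ((var + self.eps) ** -0.5) * self.gamma + self.beta


class AdamW:
    """Adam with decoupled weight decay.

    Weight decay is applied directly to the parameters (not through the
    gradient), which is the property that distinguishes AdamW from Adam
    with L2 regularization.
    """

    def __init__(self, params: list[Tensor], lr: float = 1e-3,
                 betas: tuple = (0.9, 0.999), eps: float = 1e-8,
                 weight_decay: float = 1e-2):
        self.params = list(params)
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.weight_decay = weight_decay
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.b1, self.b2
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            self.m[i] = b1 * self.m[i] + (1 - b1) * g
            self.v[i] = b2 * self.v[i] + (1 - b2) * g * g
            mhat = self.m[i] / (1 - b1 ** self.t)
            vhat = self.v[i] / (1 - b2 ** self.t)
            p.data = p.data - self.lr * (
                mhat / (np.sqrt(vhat) + self.eps) + self.weight_decay * p.data
            )

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None
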