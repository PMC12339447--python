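"""Neural-network building blocks on top of the autodiff core.

Modules follow the familiar container pattern: parameters are discovered by
attribute walking, ``state_dict`` exports named float64 arrays, and the
optimizer owns per-parameter moment buffers keyed by parameter name so that
checkpoints are stable across runs.
"""

from __future__ import annotations

from typing import Iterator

import numpy as np

from .autograd import Tensor

__all__ = ["Parameter", "Module", "ModuleList", "Linear", "LayerNorm",
           "Mlp", "AdamW", "trunc_normal"]


class Parameter(Tensor):
    """A trainable leaf tensor."""

    def __init__(self, data):
        super().__init__(data, requires_grad=True)


def trunc_normal(rng: np.random.Generator, shape, std: float = 0.02) -> np.ndarray:
    """Truncated normal init at ±2 std, the transformer default."""
    x = rng.normal(0.0, std, size=shape)
    return np.clip(x, -2.0 * std, 2.0 * std)


class Module:
    """Minimal module container with recursive parameter discovery."""

    training: bool = True

    def named_parameters(self, prefix: str = "") -> Iterator[tuple[str, Parameter]]:
        for name, value in vars(self).items():
            full = f"{prefix}{name}"
            if isinstance(value, Parameter):
                yield full, value
            elif isinstance(value, Module):
                yield from value.named_parameters(f"{full}.")

    def parameters(self) -> list[Parameter]:
        return [p for _, p in self.named_parameters()]

    def n_parameters(self) -> int:
        return int(sum(p.size for p in self.parameters()))

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.grad = None

    def train(self) -> "Module":
        self.training = True
        for value in vars(self).values():
            if isinstance(value, Module):
                value.train()
        return self

    def eval(self) -> "Module":
        self.training = False
        for value in vars(self).values():
            if isinstance(value, Module):
                value.eval()
        return self

    def state_dict(self) -> dict[str, np.ndarray]:
        return {name: p.data.copy() for name, p in self.named_parameters()}

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        own = dict(self.named_parameters())
        missing = set(own) - set(state)
        extra = set(state) - set(own)
        if missing or extra:
            raise KeyError(
                f"state mismatch: missing={sorted(missing)[:5]} extra={sorted(extra)[:5]}")
        for name, p in own.items():
            if p.data.shape != state[name].shape:
                raise ValueError(f"shape mismatch for {name}")
            p.data = np.asarray(state[name], dtype=np.float64).copy()

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)


class ModuleList(Module):
    def __init__(self, modules=()):
        modules = list(modules)
        self._n = len(modules)
        for i, m in enumerate(modules):
            setattr(self, str(i), m)

    def __len__(self) -> int:
        return self._n

    def __iter__(self):
        return (getattr(self, str(i)) for i in range(self._n))

    def __getitem__(self, i: int) -> Module:
        return getattr(self, str(i))


class Linear(Module):
    def __init__(self, rng: np.random.Generator, d_in: int, d_out: int,
                 bias: bool = True):
        self.weight = Parameter(trunc_normal(rng, (d_in, d_out)))
        self.bias = Parameter(np.zeros(d_out)) if bias else None

    def forward(self, x: Tensor) -> Tensor:
        y = x @ self.weight
        if self.bias is not None:
            y = y + self.bias
        return y


class LayerNorm(Module):
    def __init__(self, dim: int, eps: float = 1e-6):
        self.gamma = Parameter(np.ones(dim))
        self.beta = Parameter(np.zeros(dim))
        self.eps = eps

    def forward(self, x: Tensor) -> Tensor:
        mu = x.mean(axis=-1, keepdims=True)
        centered = x - mu
        var = (centered * centered).mean(axis=-1, keepdims=True)
        inv = (var + self.eps) ** -0.5
        return centered * inv * self.gamma + self.beta


class Mlp(Module):
    """Two-layer feed-forward block with GELU, the transformer default."""

    def __init__(self, rng: np.random.Generator, dim: int, hidden: int):
        self.fc1 = Linear(rng, dim, hidden)
        self.fc2 = Linear(rng, hidden, dim)

    def forward(self, x: Tensor) -> Tensor:
        return self.fc2(self.fc1(x).gelu())


class AdamW:
    """Adam with decoupled weight decay.

    Update for parameter θ with gradient g at step t:

        m ← β1 m + (1-β1) g
        v ← β2 v + (1-β2) g²
        θ ← θ − lr · ( m̂ / (√v̂ + ε) + wd · θ )

    with bias-corrected m̂ = m/(1-β1^t), v̂ = v/(1-β2^t).  The decay term
    multiplies the *parameter*, not the gradient (decoupled form).
    """

    def __init__(self, module: Module, lr: float = 1.5e-4,
                 betas: tuple[float, float] = (0.9, 0.95),
                 weight_decay: float = 0.05, eps: float = 1e-8):
        self.params = dict(module.named_parameters())
        self.lr = float(lr)
        self.beta1, self.beta2 = betas
        self.weight_decay = float(weight_decay)
        self.eps = eps
        self.t = 0
        self.m = {k: np.zeros_like(p.data) for k, p in self.params.items()}
        self.v = {k: np.zeros_like(p.data) for k, p in self.params.items()}

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        bc1 = 1.0 - b1 ** self.t
        bc2 = 1.0 - b2 ** self.t
        for name, p in self.params.items():
            if p.grad is None:
                continue
            g = p.grad
            self.m[name] = b1 * self.m[name] + (1 - b1) * g
            self.v[name] = b2 * self.v[name] + (1 - b2) * g * g
            m_hat = self.m[name] / bc1
            v_hat = self.v[name] / bc2
            p.data = p.data - self.lr * (
                m_hat / (np.sqrt(v_hat) + self.eps) + self.weight_decay * p.data)

    def zero_grad(self) -> None:
        for p in self.params.values():
            p.grad = None
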