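"""Neural-network building blocks over the :mod:`proteobridge.autodiff` engine.

Layers follow the usual conventions: ``Linear`` stores ``weight`` with shape
(in_features, out_features) and is initialised with Xavier/Glorot uniform
draws and zero biases; ``BatchNorm1d`` keeps running statistics so eval-mode
inference is well defined on single samples; ``Dropout`` uses inverted
scaling. ``AdamW`` implements decoupled weight decay (applied to weight
matrices only, not biases or normalisation parameters).
"""

from __future__ import annotations

from typing import Iterator, Optional

import numpy as np

from .autodiff import Tensor, as_tensor, parameter


def xavier_uniform(shape: tuple[int, int], rng: np.random.Generator) -> np.ndarray:
    """Glorot uniform draw: U(-a, a) with a = sqrt(6 / (fan_in + fan_out)).

    Variance of each entry is a^2/3 = 2 / (fan_in + fan_out).
    """
    fan_in, fan_out = shape
    a = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-a, a, size=shape)


class Module:
    """Base class: tracks sub-modules and parameters, toggles train/eval."""

    def __init__(self) -> None:
        self.training = True

    def parameters(self) -> Iterator[Tensor]:
        for v in self.__dict__.values():
            if isinstance(v, Tensor) and v.requires_grad:
                yield v
            elif isinstance(v, Module):
                yield from v.parameters()
            elif isinstance(v, (list, tuple)):
                for item in v:
                    if isinstance(item, Module):
                        yield from item.parameters()

    def named_modules(self, prefix: str = "") -> Iterator[tuple[str, "Module"]]:
        yield prefix, self
        for name, v in self.__dict__.items():
            sub = prefix + "." + name if prefix else name
            if isinstance(v, Module):
                yield from v.named_modules(sub)
            elif isinstance(v, (list, tuple)):
                for i, item in enumerate(v):
                    if isinstance(item, Module):
                        yield from item.named_modules(f"{sub}.{i}")

    def train(self) -> "Module":
        for _, m in self.named_modules():
            m.training = True
        return self

    def eval(self) -> "Module":
        for _, m in self.named_modules():
            m.training = False
        return self

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.zero_grad()

    # state (de)serialisation -- numpy arrays keyed by module path
    def state_dict(self) -> dict[str, np.ndarray]:
        out: dict[str, np.ndarray] = {}
        for path, m in self.named_modules():
            for name, v in m.__dict__.items():
                if isinstance(v, Tensor) and v.requires_grad:
                    out[f"{path}.{name}" if path else name] = v.data.copy()
                elif isinstance(v, np.ndarray):  # buffers (running stats)
                    out[f"{path}.{name}" if path else name] = v.copy()
        return out

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        index: dict[str, tuple[Module, str, bool]] = {}
        for path, m in self.named_modules():
            for name, v in m.__dict__.items():
                key = f"{path}.{name}" if path else name
                if isinstance(v, Tensor) and v.requires_grad:
                    index[key] = (m, name, True)
                elif isinstance(v, np.ndarray):
                    index[key] = (m, name, False)
        missing = set(index) - set(state)
        unexpected = set(state) - set(index)
        if missing or unexpected:
            raise ValueError(f"state mismatch: missing={sorted(missing)}, unexpected={sorted(unexpected)}")
        for key, arr in state.items():
            mod, name, is_param = index[key]
            if is_param:
                getattr(mod, name).data = np.asarray(arr, dtype=np.float64).copy()
            else:
                setattr(mod, name, np.asarray(arr, dtype=np.float64).copy())

    def __call__(self, x: Tensor) -> Tensor:
        return self.forward(x)

    def forward(self, x: Tensor) -> Tensor:  # pragma: no cover - abstract
        raise NotImplementedError


class Linear(Module):
    def __init__(self, in_features: int, out_features: int, rng: np.random.Generator):
        super().__init__()
        self.weight = parameter(xavier_uniform((in_features, out_features), rng))
        self.bias = parameter(np.zeros(out_features))

    def forward(self, x: Tensor) -> Tensor:
        return x @ self.weight + self.bias


class Identity(Module):
    def forward(self, x: Tensor) -> Tensor:
        return x


class ReLU(Module):
    def forward(self, x: Tensor) -> Tensor:
        return x.relu()


class Tanh(Module):
    def forward(self, x: Tensor) -> Tensor:
        return x.tanh()


def make_activation(name: str) -> Module:
    table = {"relu": ReLU, "tanh": Tanh, "identity": Identity}
    if name not in table:
        raise ValueError(f"unknown activation {name!r}; choose from {sorted(table)}")
    return table[name]()


class BatchNorm1d(Module):
    """Batch normalisation over axis 0 with running statistics.

    Train mode normalises by batch mean/variance (biased, as is standard) and
    updates exponential running statistics; eval mode uses the running
    statistics only, so single-sample inference is deterministic and
    batch-independent.
    """

    def __init__(self, num_features: int, momentum: float = 0.1, eps: float = 1e-5):
        super().__init__()
        self.gamma = parameter(np.ones(num_features))
        self.beta = parameter(np.zeros(num_features))
        self.running_mean = np.zeros(num_features)
        self.running_var = np.ones(num_features)
        self.momentum = momentum
        self.eps = eps

    def forward(self, x: Tensor) -> Tensor:
        if self.training:
            mu = x.mean(axis=0, keepdims=True)
            centered = x - mu
            var = (centered**2).mean(axis=0, keepdims=True)
            xhat = centered / (var + self.eps) ** 0.5
            self.running_mean = (1 - self.momentum) * self.running_mean + self.momentum * mu.data.ravel()
            self.running_var = (1 - self.momentum) * self.running_var + self.momentum * var.data.ravel()
        else:
            xhat = (x - self.running_mean) / np.sqrt(self.running_var + self.eps)
        return xhat * self.gamma + self.beta


class Dropout(Module):
    """Inverted dropout; a fresh mask is drawn from ``rng`` per forward call."""

    def __init__(self, p: float, rng: np.random.Generator):
        super().__init__()
        if not 0 <= p < 1:
            raise ValueError("dropout rate must be in [0, 1)")
        self.p = p
        self.rng = rng

    def forward(self, x: Tensor) -> Tensor:
        if not self.training or self.p == 0:
            return x
        mask = (self.rng.random(x.shape) >= self.p) / (1 - self.p)
        return x * mask


class DualHeadResBlock(Module):
    """Residual block with two parallel heads summed into the skip path.

    y = x + h1(x) + h2(x), each head being Linear -> [BN] -> act -> [Dropout].
    """

    def __init__(
        self,
        width: int,
        rng: np.random.Generator,
        activation: str = "relu",
        dropout: float = 0.1,
        use_batchnorm: bool = True,
    ):
        super().__init__()
        self.heads = [
            _HeadBranch(width, rng, activation, dropout, use_batchnorm) for _ in range(2)
        ]

    def forward(self, x: Tensor) -> Tensor:
        return x + self.heads[0](x) + self.heads[1](x)


class _HeadBranch(Module):
    def __init__(self, width, rng, activation, dropout, use_batchnorm):
        super().__init__()
        self.linear = Linear(width, width, rng)
        self.norm: Module = BatchNorm1d(width) if use_batchnorm else Identity()
        self.act = make_activation(activation)
        self.drop = Dropout(dropout, rng)

    def forward(self, x: Tensor) -> Tensor:
        return self.drop(self.act(self.norm(self.linear(x))))


class Sequential(Module):
    def __init__(self, *layers: Module):
        super().__init__()
        self.layers = list(layers)

    def forward(self, x: Tensor) -> Tensor:
        for layer in self.layers:
            x = layer(x)
        return x


class AdamW:
    """Adam with decoupled weight decay.

    Weight decay multiplies 2-D parameters (weight matrices) by
    ``1 - lr * weight_decay`` before the Adam update; vectors (biases,
    normalisation scales) are not decayed.
    """

    def __init__(
        self,
        params: list[Tensor],
        lr: float = 4e-4,
        betas: tuple[float, float] = (0.9, 0.999),
        eps: float = 1e-8,
        weight_decay: float = 1e-4,
    ):
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
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            if p.data.ndim >= 2 and self.weight_decay:
                p.data *= 1 - self.lr * self.weight_decay
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g**2
            mhat = self.m[i] / (1 - self.b1**self.t)
            vhat = self.v[i] / (1 - self.b2**self.t)
            p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)

    def zero_grad(self) -> None:
        for p in self.params:
            p.zero_grad()
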