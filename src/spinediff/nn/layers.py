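"""Layer/module abstractions and the Adam optimizer on top of the tape engine."""

from __future__ import annotations

import math

import numpy as np

from .tensor import Tensor, avg_pool2d, concat, conv2d, upsample_nearest2x

__all__ = [
    "Module", "Conv2d", "Linear", "GroupNorm", "RunningNorm", "Adam",
    "sinusoidal_embedding", "avg_pool2d", "concat", "upsample_nearest2x",
]


class Module:
    """Tracks parameters and sub-modules through attribute assignment."""

    def __init__(self):
        object.__setattr__(self, "_params", {})
        object.__setattr__(self, "_modules", {})

    def __setattr__(self, name, value):
        if isinstance(value, Tensor) and value.requires_grad:
            self._params[name] = value
        elif isinstance(value, Module):
            self._modules[name] = value
        elif isinstance(value, (list, tuple)) and value and all(
                isinstance(v, Module) for v in value):
            for i, v in enumerate(value):
                self._modules[f"{name}.{i}"] = v
        object.__setattr__(self, name, value)

    def parameters(self) -> list[Tensor]:
        out = list(self._params.values())
        for m in self._modules.values():
            out.extend(m.parameters())
        return out

    def named_parameters(self, prefix: str = "") -> dict[str, Tensor]:
        out = {prefix + k: v for k, v in self._params.items()}
        for name, m in self._modules.items():
            out.update(m.named_parameters(prefix + name + "."))
        return out

    def state_dict(self) -> dict[str, np.ndarray]:
        return {k: v.data.copy() for k, v in self.named_parameters().items()}

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        params = self.named_parameters()
        missing = set(params) ^ set(state)
        if missing:
            raise KeyError(f"state dict mismatch: {sorted(missing)}")
        for k, p in params.items():
            arr = np.asarray(state[k], dtype=np.float32)
            if arr.shape != p.data.shape:
                raise ValueError(f"shape mismatch for {k}: {arr.shape} vs {p.data.shape}")
            p.data[...] = arr

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.grad = None

    def n_parameters(self) -> int:
        return sum(p.data.size for p in self.parameters())

    def train(self, mode: bool = True) -> "Module":
        if hasattr(self, "training"):
            object.__setattr__(self, "training", mode)
        for m in self._modules.values():
            m.train(mode)
        return self

    def eval(self) -> "Module":
        return self.train(False)

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)


def _param(rng: np.random.Generator, shape, fan_in: int) -> Tensor:
    """Kaiming-uniform initialisation."""
    bound = 1.0 / math.sqrt(fan_in)
    return Tensor(rng.uniform(-bound, bound, size=shape).astype(np.float32),
                  requires_grad=True)


class Conv2d(Module):
    def __init__(self, cin: int, cout: int, k: int, rng: np.random.Generator,
                 padding: int | None = None, dilation: int = 1, groups: int = 1,
                 bias: bool = True):
        super().__init__()
        self.padding = ((k - 1) * dilation) // 2 if padding is None else padding
        self.dilation = dilation
        self.groups = groups
        fan_in = (cin // groups) * k * k
        self.weight = _param(rng, (cout, cin // groups, k, k), fan_in)
        self.bias = _param(rng, (cout,), fan_in) if bias else None

    def forward(self, x: Tensor) -> Tensor:
        return conv2d(x, self.weight, self.bias, padding=self.padding,
                      dilation=self.dilation, groups=self.groups)


class Linear(Module):
    def __init__(self, cin: int, cout: int, rng: np.random.Generator, bias: bool = True):
        super().__init__()
        self.weight = _param(rng, (cin, cout), cin)
        self.bias = _param(rng, (cout,), cin) if bias else None

    def forward(self, x: Tensor) -> Tensor:
        y = x @ self.weight
        if self.bias is not None:
            y = y + self.bias
        return y


class GroupNorm(Module):
    """Group normalisation over (channel-group, H, W); batch-size independent."""

    def __init__(self, channels: int, groups: int = 4, eps: float = 1e-5):
        super().__init__()
        self.groups = min(groups, channels)
        while channels % self.groups:
            self.groups -= 1
        self.eps = eps
        self.gamma = Tensor(np.ones(channels, dtype=np.float32), requires_grad=True)
        self.beta = Tensor(np.zeros(channels, dtype=np.float32), requires_grad=True)

    def forward(self, x: Tensor) -> Tensor:
        n, c, h, w = x.shape
        g = self.groups
        xg = x.reshape(n, g, (c // g) * h * w)
        mu = xg.mean(axis=2, keepdims=True)
        var = ((xg - mu) ** 2).mean(axis=2, keepdims=True)
        y = (xg - mu) / ((var + self.eps) ** 0.5)
        y = y.reshape(n, c, h, w)
        return y * self.gamma.reshape(1, c, 1, 1) + self.beta.reshape(1, c, 1, 1)


class RunningNorm(Module):
    """Per-feature normalisation by running statistics.

    Used where batch statistics are degenerate (batch size 1): each call in
    training mode folds the current sample into exponential running estimates
    of the per-feature mean and second moment, then normalises by them.  The
    running statistics are treated as constants by the tape (no gradient flows
    through them).  ``test_mode=True`` skips normalisation entirely so that
    unit tests have closed-form expectations.
    """

    def __init__(self, dim: int, momentum: float = 0.1, eps: float = 1e-5):
        super().__init__()
        self.momentum = momentum
        self.eps = eps
        self.run_mean = np.zeros(dim, dtype=np.float32)
        self.run_sq = np.ones(dim, dtype=np.float32)
        self.initialized = False
        self.training = True
        self.test_mode = False
        self.gamma = Tensor(np.ones(dim, dtype=np.float32), requires_grad=True)
        self.beta = Tensor(np.zeros(dim, dtype=np.float32), requires_grad=True)

    def forward(self, x: Tensor) -> Tensor:
        if self.test_mode:
            return x
        if self.training:
            m = x.data.reshape(-1, x.shape[-1]).mean(axis=0)
            sq = (x.data.reshape(-1, x.shape[-1]) ** 2).mean(axis=0)
            if not self.initialized:
                self.run_mean[...] = m
                self.run_sq[...] = sq
                self.initialized = True
            else:
                self.run_mean += self.momentum * (m - self.run_mean)
                self.run_sq += self.momentum * (sq - self.run_sq)
        var = np.maximum(self.run_sq - self.run_mean ** 2, 0.0)
        scale = 1.0 / np.sqrt(var + self.eps)
        return (x - self.run_mean) * scale * self.gamma + self.beta


class Adam:
    def __init__(self, params: list[Tensor], lr: float = 1e-4,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8):
        self.params = params
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in params]
        self.v = [np.zeros_like(p.data) for p in params]

    def step(self) -> None:
        self.t += 1
        b1t = 1.0 - self.b1 ** self.t
        b2t = 1.0 - self.b2 ** self.t
        for p, m, v in zip(self.params, self.m, self.v):
            if p.grad is None:
                continue
            g = p.grad
            m += (1.0 - self.b1) * (g - m)
            v += (1.0 - self.b2) * (g * g - v)
            p.data -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None


def sinusoidal_embedding(t: int, dim: int, max_period: float = 10000.0) -> np.ndarray:
    """Standard transformer/diffusion timestep embedding (length ``dim``)."""
    half = dim // 2
    freqs = np.exp(-math.log(max_period) * np.arange(half) / half)
    ang = t * freqs
    emb = np.concatenate([np.cos(ang), np.sin(ang)])
    if dim % 2:
        emb = np.concatenate([emb, [0.0]])
    return emb.astype(np.float32)
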