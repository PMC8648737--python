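"""Layer modules with Xavier-uniform initialized parameters."""

from __future__ import annotations

import numpy as np

from . import functional as F
from .tensor import Tensor

__all__ = [
    "Module",
    "Conv2d",
    "Conv1d",
    "ConvTranspose1d",
    "Linear",
    "BatchNorm2d",
    "Dropout",
    "Sequential",
    "LeakyReLU",
    "xavier_uniform",
]


def xavier_uniform(shape, fan_in: int, fan_out: int, rng: np.random.Generator) -> Tensor:
    bound = np.sqrt(6.0 / (fan_in + fan_out))
    return Tensor(rng.uniform(-bound, bound, size=shape), requires_grad=True)


class Module:
    """Base class: parameter discovery via attribute traversal."""

    training: bool = True

    def parameters(self) -> list[Tensor]:
        params: list[Tensor] = []
        seen: set[int] = set()
        self._collect(params, seen)
        return params

    def _collect(self, params: list[Tensor], seen: set[int]):
        for value in vars(self).values():
            if isinstance(value, Tensor) and value.requires_grad and id(value) not in seen:
                seen.add(id(value))
                params.append(value)
            elif isinstance(value, Module):
                value._collect(params, seen)
            elif isinstance(value, (list, tuple)):
                for item in value:
                    if isinstance(item, Module):
                        item._collect(params, seen)
                    elif isinstance(item, Tensor) and item.requires_grad and id(item) not in seen:
                        seen.add(id(item))
                        params.append(item)

    def named_state(self) -> dict[str, np.ndarray]:
        """Flat name -> array mapping of parameters and buffers (for checkpoints)."""
        state: dict[str, np.ndarray] = {}
        self._collect_state(state, prefix="")
        return state

    def _collect_state(self, state: dict[str, np.ndarray], prefix: str):
        for name, value in vars(self).items():
            key = f"{prefix}{name}"
            if isinstance(value, Tensor):
                state[key] = value.data
            elif isinstance(value, np.ndarray):
                state[key] = value
            elif isinstance(value, Module):
                value._collect_state(state, prefix=f"{key}.")
            elif isinstance(value, (list, tuple)):
                for i, item in enumerate(value):
                    if isinstance(item, Module):
                        item._collect_state(state, prefix=f"{key}.{i}.")
                    elif isinstance(item, Tensor):
                        state[f"{key}.{i}"] = item.data

    def load_state(self, state: dict[str, np.ndarray]):
        own = self.named_state()
        missing = set(own) - set(state)
        if missing:
            raise KeyError(f"checkpoint missing parameters: {sorted(missing)[:5]} ...")
        self._load_state(state, prefix="")

    def _load_state(self, state: dict[str, np.ndarray], prefix: str):
        for name, value in vars(self).items():
            key = f"{prefix}{name}"
            if isinstance(value, Tensor):
                value.data = np.array(state[key], dtype=value.data.dtype)
            elif isinstance(value, np.ndarray):
                setattr(self, name, np.array(state[key], dtype=value.dtype))
            elif isinstance(value, Module):
                value._load_state(state, prefix=f"{key}.")
            elif isinstance(value, (list, tuple)):
                for i, item in enumerate(value):
                    if isinstance(item, Module):
                        item._load_state(state, prefix=f"{key}.{i}.")
                    elif isinstance(item, Tensor):
                        item.data = np.array(state[f"{key}.{i}"], dtype=np.float64)

    def train(self, mode: bool = True):
        self.training = mode
        for value in vars(self).values():
            if isinstance(value, Module):
                value.train(mode)
            elif isinstance(value, (list, tuple)):
                for item in value:
                    if isinstance(item, Module):
                        item.train(mode)
        return self

    def eval(self):
        return self.train(False)

    def count_parameters(self) -> int:
        return int(sum(p.size for p in self.parameters()))

    def astype(self, dtype):
        """Cast all parameters in place (e.g. float32 for training speed)."""
        for p in self.parameters():
            p.data = p.data.astype(dtype)
        return self

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)


class Conv2d(Module):
    def __init__(self, cin: int, cout: int, kernel: int, rng: np.random.Generator):
        fan_in = cin * kernel * kernel
        fan_out = cout * kernel * kernel
        self.weight = xavier_uniform((cout, cin, kernel, kernel), fan_in, fan_out, rng)
        self.bias = Tensor(np.zeros(cout), requires_grad=True)

    def forward(self, x):
        return F.conv2d(x, self.weight, self.bias)


class Conv1d(Module):
    def __init__(self, cin: int, cout: int, kernel: int, rng: np.random.Generator,
                 stride: int = 1, padding: int = 0):
        self.stride, self.padding = stride, padding
        self.weight = xavier_uniform((cout, cin, kernel), cin * kernel, cout * kernel, rng)
        self.bias = Tensor(np.zeros(cout), requires_grad=True)

    def forward(self, x):
        return F.conv1d(x, self.weight, self.bias, stride=self.stride, padding=self.padding)


class ConvTranspose1d(Module):
    def __init__(self, cin: int, cout: int, kernel: int, rng: np.random.Generator,
                 stride: int = 1, padding: int = 0):
        self.stride, self.padding = stride, padding
        self.weight = xavier_uniform((cin, cout, kernel), cin * kernel, cout * kernel, rng)
        self.bias = Tensor(np.zeros(cout), requires_grad=True)

    def forward(self, x):
        return F.conv_transpose1d(x, self.weight, self.bias, stride=self.stride,
                                  padding=self.padding)


class Linear(Module):
    def __init__(self, fin: int, fout: int, rng: np.random.Generator):
        self.weight = xavier_uniform((fin, fout), fin, fout, rng)
        self.bias = Tensor(np.zeros(fout), requires_grad=True)

    def forward(self, x):
        return x @ self.weight + self.bias


class BatchNorm2d(Module):
    """Per-channel batch normalization with running statistics for inference."""

    def __init__(self, channels: int, momentum: float = 0.1, eps: float = 1e-5):
        self.gamma = Tensor(np.ones(channels), requires_grad=True)
        self.beta = Tensor(np.zeros(channels), requires_grad=True)
        self.running_mean = np.zeros(channels)
        self.running_var = np.ones(channels)
        self.momentum = momentum
        self.eps = eps

    def forward(self, x):
        if self.training:
            mu = x.mean(axis=(0, 2, 3), keepdims=True)
            var = ((x - mu) ** 2).mean(axis=(0, 2, 3), keepdims=True)
            self.running_mean = (
                (1 - self.momentum) * self.running_mean + self.momentum * mu.data.ravel()
            )
            self.running_var = (
                (1 - self.momentum) * self.running_var + self.momentum * var.data.ravel()
            )
        else:
            mu = Tensor(self.running_mean.reshape(1, -1, 1, 1))
            var = Tensor(self.running_var.reshape(1, -1, 1, 1))
        xn = (x - mu) / ((var + self.eps) ** 0.5)
        return xn * self.gamma.reshape(1, -1, 1, 1) + self.beta.reshape(1, -1, 1, 1)


class Dropout(Module):
    def __init__(self, p: float, rng: np.random.Generator):
        self.p = p
        self.rng = rng

    def forward(self, x):
        return F.dropout(x, self.p, self.rng, self.training)


class LeakyReLU(Module):
    def __init__(self, negative_slope: float = 0.01):
        self.negative_slope = negative_slope

    def forward(self, x):
        return x.leaky_relu(self.negative_slope)


class Sequential(Module):
    def __init__(self, *modules: Module):
        self.modules = list(modules)

    def forward(self, x):
        for m in self.modules:
            x = m(x)
        return x
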