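"""Layer/module system over the autograd core: parameter registration,
train/eval mode, convolution-normalisation-activation blocks."""

from __future__ import annotations

import math

import numpy as np

from .autograd import Tensor, batchnorm2d, conv2d, maxpool2d

_rng = np.random.default_rng(0)


def seed_all(seed: int) -> None:
    """Seed the parameter-initialisation stream (call before building models)."""
    global _rng
    _rng = np.random.default_rng(seed)


def init_rng() -> np.random.Generator:
    return _rng


class Module:
    """Base class; children registered as attributes are discovered recursively."""

    def __init__(self):
        self._training = True

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)

    def modules(self):
        def walk(v):
            if isinstance(v, Module):
                yield from v.modules()
            elif isinstance(v, (list, tuple)):
                for item in v:
                    yield from walk(item)
            elif isinstance(v, dict):
                for item in v.values():
                    yield from walk(item)

        yield self
        for v in self.__dict__.values():
            yield from walk(v)

    def parameters(self) -> list[Tensor]:
        params: list[Tensor] = []
        for m in self.modules():
            for v in m.__dict__.values():
                if isinstance(v, Tensor) and v.requires_grad:
                    params.append(v)
        return params

    def num_parameters(self) -> int:
        return int(sum(p.data.size for p in self.parameters()))

    def train(self, mode: bool = True):
        for m in self.modules():
            m._training = mode
        return self

    def eval(self):
        return self.train(False)

    @property
    def training(self) -> bool:
        return self._training

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.zero_grad()

    def state_arrays(self) -> dict[str, np.ndarray]:
        """Flat name → array mapping of parameters and buffers, for checkpoints."""
        out: dict[str, np.ndarray] = {}

        def walk(obj: Module, prefix: str):
            for name, v in obj.__dict__.items():
                key = f"{prefix}{name}"
                if isinstance(v, Tensor) and v.requires_grad:
                    out[key] = v.data
                elif isinstance(v, np.ndarray):
                    out[key] = v
                elif isinstance(v, Module):
                    walk(v, key + ".")
                elif isinstance(v, (list, tuple)):
                    for i, item in enumerate(v):
                        if isinstance(item, Module):
                            walk(item, f"{key}.{i}.")
                        elif isinstance(item, (list, tuple)):
                            for j, sub in enumerate(item):
                                if isinstance(sub, Module):
                                    walk(sub, f"{key}.{i}.{j}.")
                elif isinstance(v, dict):
                    for dk, item in v.items():
                        if isinstance(item, Module):
                            walk(item, f"{key}.{dk}.")

        walk(self, "")
        return out

    def load_state_arrays(self, state: dict[str, np.ndarray]) -> None:
        own = self.state_arrays()
        missing = set(own) ^ set(state)
        if missing:
            raise ValueError(f"checkpoint key mismatch: {sorted(missing)[:5]} ...")
        for k, dst in own.items():
            src = state[k]
            if dst.shape != src.shape:
                raise ValueError(f"shape mismatch for {k}: {dst.shape} vs {src.shape}")
            dst[...] = src


class Conv2d(Module):
    def __init__(self, c_in: int, c_out: int, k: int = 1, stride: int = 1,
                 padding: int | None = None, bias: bool = False):
        super().__init__()
        self.stride = stride
        self.padding = k // 2 if padding is None else padding
        fan_in = c_in * k * k
        bound = math.sqrt(2.0 / fan_in)
        self.weight = Tensor(_rng.normal(0.0, bound, (c_out, c_in, k, k)),
                             requires_grad=True)
        self.bias = Tensor(np.zeros(c_out), requires_grad=True) if bias else None

    def forward(self, x: Tensor) -> Tensor:
        return conv2d(x, self.weight, self.bias, self.stride, self.padding)


class BatchNorm2d(Module):
    def __init__(self, c: int, eps: float = 1e-3, momentum: float = 0.03):
        super().__init__()
        self.eps = eps
        self.momentum = momentum
        self.gamma = Tensor(np.ones(c), requires_grad=True)
        self.beta = Tensor(np.zeros(c), requires_grad=True)
        self.running_mean = np.zeros(c, dtype=np.float32)
        self.running_var = np.ones(c, dtype=np.float32)

    def forward(self, x: Tensor) -> Tensor:
        return batchnorm2d(x, self.gamma, self.beta, self.running_mean,
                           self.running_var, self._training, self.momentum, self.eps)


class ConvBlock(Module):
    """Conv → BatchNorm → SiLU, the standard detector building block."""

    def __init__(self, c_in: int, c_out: int, k: int = 1, stride: int = 1,
                 act: bool = True):
        super().__init__()
        self.conv = Conv2d(c_in, c_out, k, stride)
        self.bn = BatchNorm2d(c_out)
        self.act = act

    def forward(self, x: Tensor) -> Tensor:
        y = self.bn(self.conv(x))
        return y.silu() if self.act else y


class MaxPool2d(Module):
    def __init__(self, k: int, stride: int = 1, padding: int | None = None):
        super().__init__()
        self.k = k
        self.stride = stride
        self.padding = k // 2 if padding is None else padding

    def forward(self, x: Tensor) -> Tensor:
        return maxpool2d(x, self.k, self.stride, self.padding)
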