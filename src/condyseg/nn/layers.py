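"""Parameterized layers (modules) built on the autograd engine."""

from __future__ import annotations

import numpy as np

from . import autograd as ag
from .autograd import Tensor


class Module:
    """Base class: parameter discovery, train/eval mode, state (de)serialization."""

    def __init__(self):
        self.training = True

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
        return params

    def modules(self) -> list["Module"]:
        mods: list[Module] = [self]
        for v in self.__dict__.values():
            if isinstance(v, Module):
                mods.extend(v.modules())
            elif isinstance(v, (list, tuple)):
                for item in v:
                    if isinstance(item, Module):
                        mods.extend(item.modules())
        return mods

    def train(self) -> "Module":
        for m in self.modules():
            m.training = True
        return self

    def eval(self) -> "Module":
        for m in self.modules():
            m.training = False
        return self

    def count_parameters(self) -> int:
        return int(sum(p.data.size for p in self.parameters()))

    # -- flat state dict (arrays only), for .npz checkpoints ----------------

    def state_arrays(self) -> dict[str, np.ndarray]:
        state: dict[str, np.ndarray] = {}

        def walk(mod: Module, prefix: str) -> None:
            for k, v in mod.__dict__.items():
                if isinstance(v, Tensor):
                    state[f"{prefix}{k}"] = v.data.copy()
                elif isinstance(v, np.ndarray):
                    state[f"{prefix}{k}"] = v.copy()
                elif isinstance(v, Module):
                    walk(v, f"{prefix}{k}.")
                elif isinstance(v, (list, tuple)):
                    for i, item in enumerate(v):
                        if isinstance(item, Module):
                            walk(item, f"{prefix}{k}.{i}.")

        walk(self, "")
        return state

    def load_state_arrays(self, state: dict[str, np.ndarray]) -> None:
        def walk(mod: Module, prefix: str) -> None:
            for k, v in mod.__dict__.items():
                key = f"{prefix}{k}"
                if isinstance(v, Tensor):
                    v.data = np.asarray(state[key], dtype=np.float64).reshape(v.data.shape)
                elif isinstance(v, np.ndarray):
                    v[...] = np.asarray(state[key]).reshape(v.shape)
                elif isinstance(v, Module):
                    walk(v, f"{key}.")
                elif isinstance(v, (list, tuple)):
                    for i, item in enumerate(v):
                        if isinstance(item, Module):
                            walk(item, f"{key}.{i}.")

        walk(self, "")


def _he_init(rng: np.random.Generator, shape: tuple[int, ...], fan_in: int) -> np.ndarray:
    return rng.normal(0.0, np.sqrt(2.0 / fan_in), size=shape)


class Conv2d(Module):
    """Same-padding stride-1 convolution with odd kernel."""

    def __init__(self, c_in: int, c_out: int, kernel: int, rng: np.random.Generator):
        super().__init__()
        if kernel % 2 == 0:
            raise ValueError("Conv2d: kernel must be odd for same padding")
        self.kernel = kernel
        self.weight = Tensor(
            _he_init(rng, (c_out, c_in, kernel, kernel), c_in * kernel * kernel),
            requires_grad=True,
        )
        self.bias = Tensor(np.zeros(c_out), requires_grad=True)

    def __call__(self, x):
        return ag.conv2d(x, self.weight, self.bias)


class ConvTranspose2d(Module):
    """Kernel-2 stride-2 transposed convolution (doubles spatial dims)."""

    def __init__(self, c_in: int, c_out: int, rng: np.random.Generator):
        super().__init__()
        self.weight = Tensor(_he_init(rng, (c_in, c_out, 2, 2), c_in * 4), requires_grad=True)
        self.bias = Tensor(np.zeros(c_out), requires_grad=True)

    def __call__(self, x):
        return ag.conv_transpose2d(x, self.weight, self.bias)


class Linear(Module):
    def __init__(self, f_in: int, f_out: int, rng: np.random.Generator):
        super().__init__()
        self.weight = Tensor(_he_init(rng, (f_in, f_out), f_in), requires_grad=True)
        self.bias = Tensor(np.zeros(f_out), requires_grad=True)

    def __call__(self, x):
        return ag.add(ag.matmul(x, self.weight), self.bias)


class BatchNorm2d(Module):
    def __init__(self, channels: int, momentum: float = 0.1, eps: float = 1e-5):
        super().__init__()
        self.gamma = Tensor(np.ones(channels), requires_grad=True)
        self.beta = Tensor(np.zeros(channels), requires_grad=True)
        self.running_mean = np.zeros(channels)
        self.running_var = np.ones(channels)
        self.momentum = momentum
        self.eps = eps

    def __call__(self, x):
        return ag.batch_norm2d(
            x, self.gamma, self.beta, self.running_mean, self.running_var,
            training=self.training, momentum=self.momentum, eps=self.eps,
        )


class ReLU(Module):
    def __call__(self, x):
        return ag.relu(x)


class MaxPool2d(Module):
    def __init__(self, kernel: int, stride: int | None = None, padding: int = 0):
        super().__init__()
        self.kernel = kernel
        self.stride = stride if stride is not None else kernel
        self.padding = padding

    def __call__(self, x):
        return ag.maxpool2d(x, self.kernel, self.stride, self.padding)
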