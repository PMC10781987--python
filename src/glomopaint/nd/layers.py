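"""Layer/module abstraction over the autodiff engine.

Modules hold named parameters (Tensors with ``requires_grad=True``) and
buffers (plain arrays, e.g. batch-norm running statistics).  ``state_dict`` /
``load_state_dict`` use dotted names so checkpoints survive refactors of the
containing objects.
"""

from __future__ import annotations

import numpy as np

from . import functional as F
from .tensor import Tensor

__all__ = [
    "Module",
    "Sequential",
    "Conv2d",
    "ConvTranspose2d",
    "BatchNorm2d",
    "Linear",
    "LeakyReLU",
    "ReLU",
    "Tanh",
    "Sigmoid",
]


class Module:
    def __init__(self):
        self._params: dict[str, Tensor] = {}
        self._buffers: dict[str, np.ndarray] = {}
        self._modules: dict[str, Module] = {}
        self.training = True

    def __setattr__(self, name, value):
        if isinstance(value, Module):
            self.__dict__.setdefault("_modules", {})[name] = value
        object.__setattr__(self, name, value)

    def register_parameter(self, name: str, value: Tensor) -> Tensor:
        value.requires_grad = True
        self._params[name] = value
        object.__setattr__(self, name, value)
        return value

    def register_buffer(self, name: str, value: np.ndarray) -> np.ndarray:
        self._buffers[name] = value
        object.__setattr__(self, name, value)
        return value

    def add_module(self, name: str, module: "Module") -> "Module":
        self._modules[name] = module
        object.__setattr__(self, name, module)
        return module

    def parameters(self) -> list[Tensor]:
        out = list(self._params.values())
        for m in self._modules.values():
            out.extend(m.parameters())
        return out

    def named_state(self, prefix: str = "") -> dict[str, np.ndarray]:
        out = {prefix + k: v.data for k, v in self._params.items()}
        out.update({prefix + k: v for k, v in self._buffers.items()})
        for name, m in self._modules.items():
            out.update(m.named_state(prefix + name + "."))
        return out

    def state_dict(self) -> dict[str, np.ndarray]:
        return {k: v.copy() for k, v in self.named_state().items()}

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        own = self.named_state()
        missing = set(own) - set(state)
        if missing:
            raise KeyError(f"state dict missing keys: {sorted(missing)[:5]} ...")
        for k, arr in state.items():
            if k not in own:
                continue
            if own[k].shape != np.asarray(arr).shape:
                raise ValueError(f"shape mismatch for {k}")
            own[k][...] = arr

    def train(self, mode: bool = True) -> "Module":
        self.training = mode
        for m in self._modules.values():
            m.train(mode)
        return self

    def eval(self) -> "Module":
        return self.train(False)

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.grad = None

    def n_parameters(self) -> int:
        return sum(p.size for p in self.parameters())

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)

    def forward(self, *args, **kwargs):  # pragma: no cover
        raise NotImplementedError


class Sequential(Module):
    def __init__(self, *modules: Module):
        super().__init__()
        self.mods = list(modules)
        for i, m in enumerate(modules):
            self.add_module(str(i), m)

    def forward(self, x):
        for m in self.mods:
            x = m(x)
        return x


def _init_conv(rng: np.random.Generator, shape, gain: float = 0.02) -> np.ndarray:
    """DCGAN-style N(0, 0.02) initialisation."""
    return rng.normal(0.0, gain, size=shape).astype(np.float32)


class Conv2d(Module):
    def __init__(
        self,
        in_ch: int,
        out_ch: int,
        kernel: int,
        stride: int = 1,
        padding: int = 0,
        dilation: int = 1,
        bias: bool = True,
        rng: np.random.Generator | None = None,
    ):
        super().__init__()
        rng = rng or np.random.default_rng(0)
        self.stride, self.padding, self.dilation = stride, padding, dilation
        self.register_parameter(
            "weight", Tensor(_init_conv(rng, (out_ch, in_ch, kernel, kernel)))
        )
        self.bias = None
        if bias:
            self.register_parameter("bias", Tensor(np.zeros(out_ch, dtype=np.float32)))

    def forward(self, x):
        return F.conv2d(
            x, self.weight, self.bias,
            stride=self.stride, padding=self.padding, dilation=self.dilation,
        )


class ConvTranspose2d(Module):
    def __init__(
        self,
        in_ch: int,
        out_ch: int,
        kernel: int,
        stride: int = 2,
        padding: int = 1,
        bias: bool = True,
        rng: np.random.Generator | None = None,
    ):
        super().__init__()
        rng = rng or np.random.default_rng(0)
        self.stride, self.padding = stride, padding
        self.register_parameter(
            "weight", Tensor(_init_conv(rng, (in_ch, out_ch, kernel, kernel)))
        )
        self.bias = None
        if bias:
            self.register_parameter("bias", Tensor(np.zeros(out_ch, dtype=np.float32)))

    def forward(self, x):
        return F.conv_transpose2d(
            x, self.weight, self.bias, stride=self.stride, padding=self.padding
        )


class BatchNorm2d(Module):
    def __init__(self, n_ch: int, momentum: float = 0.1, eps: float = 1e-5):
        super().__init__()
        self.momentum, self.eps = momentum, eps
        self.register_parameter("gamma", Tensor(np.ones(n_ch, dtype=np.float32)))
        self.register_parameter("beta", Tensor(np.zeros(n_ch, dtype=np.float32)))
        self.register_buffer("running_mean", np.zeros(n_ch, dtype=np.float32))
        self.register_buffer("running_var", np.ones(n_ch, dtype=np.float32))

    def forward(self, x):
        return F.batch_norm2d(
            x, self.gamma, self.beta,
            self.running_mean, self.running_var,
            training=self.training, momentum=self.momentum, eps=self.eps,
        )


class Linear(Module):
    def __init__(self, in_f: int, out_f: int, rng: np.random.Generator | None = None):
        super().__init__()
        rng = rng or np.random.default_rng(0)
        self.register_parameter("weight", Tensor(_init_conv(rng, (in_f, out_f))))
        self.register_parameter("bias", Tensor(np.zeros(out_f, dtype=np.float32)))

    def forward(self, x):
        return x @ self.weight + self.bias


class LeakyReLU(Module):
    def __init__(self, slope: float = 0.2):
        super().__init__()
        self.slope = slope

    def forward(self, x):
        return x.leaky_relu(self.slope)


class ReLU(Module):
    def forward(self, x):
        return x.relu()


class Tanh(Module):
    def forward(self, x):
        return x.tanh()


class Sigmoid(Module):
    def forward(self, x):
        return x.sigmoid()
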