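"""Layer/module abstractions over the functional ops.

Follows the familiar ``Module`` pattern: submodules and parameters are
discovered by attribute traversal in definition order, which also fixes the
weight-initialisation order and therefore makes seeded builds reproducible.
"""

from __future__ import annotations

from typing import Iterator

import numpy as np

from . import functional as F
from .tensor import Tensor


class Parameter(Tensor):
    """A trainable tensor."""

    def __init__(self, data):
        super().__init__(data, requires_grad=True)


class Module:
    def __init__(self):
        object.__setattr__(self, "_params", {})
        object.__setattr__(self, "_modules", {})
        object.__setattr__(self, "_buffers", {})
        object.__setattr__(self, "training", True)

    def __setattr__(self, name, value):
        if isinstance(value, Parameter):
            self._params[name] = value
        elif isinstance(value, Module):
            self._modules[name] = value
        elif isinstance(value, ModuleList):
            self._modules[name] = value
        object.__setattr__(self, name, value)

    def named_parameters(self, prefix: str = "") -> Iterator[tuple[str, Parameter]]:
        for name, p in self._params.items():
            yield prefix + name, p
        for name, m in self._modules.items():
            yield from m.named_parameters(prefix + name + ".")

    def parameters(self) -> Iterator[Parameter]:
        for _, p in self.named_parameters():
            yield p

    def named_buffers(self, prefix: str = "") -> Iterator[tuple[str, np.ndarray]]:
        for name, b in self._buffers.items():
            yield prefix + name, b
        for name, m in self._modules.items():
            yield from m.named_buffers(prefix + name + ".")

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.zero_grad()

    def train(self, mode: bool = True) -> "Module":
        object.__setattr__(self, "training", mode)
        for m in self._modules.values():
            m.train(mode)
        return self

    def eval(self) -> "Module":
        return self.train(False)

    def num_parameters(self) -> int:
        return sum(p.size for p in self.parameters())

    def state_dict(self) -> dict[str, np.ndarray]:
        state = {name: p.data.copy() for name, p in self.named_parameters()}
        state.update({name: b.copy() for name, b in self.named_buffers()})
        return state

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        own = dict(self.named_parameters())
        bufs = dict(self.named_buffers())
        missing = (set(own) | set(bufs)) - set(state)
        if missing:
            raise KeyError(f"state dict missing entries: {sorted(missing)[:5]}")
        for name, p in own.items():
            if p.data.shape != state[name].shape:
                raise ValueError(f"shape mismatch for {name}")
            p.data = np.asarray(state[name], dtype=np.float64).copy()
        for name, b in bufs.items():
            b[...] = state[name]

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)


class ModuleList(Module):
    def __init__(self, modules=()):
        super().__init__()
        self._list: list[Module] = []
        for m in modules:
            self.append(m)

    def append(self, module: Module) -> None:
        self._modules[str(len(self._list))] = module
        self._list.append(module)

    def __iter__(self):
        return iter(self._list)

    def __len__(self):
        return len(self._list)

    def __getitem__(self, i):
        return self._list[i]

    def train(self, mode: bool = True):
        object.__setattr__(self, "training", mode)
        for m in self._list:
            m.train(mode)
        return self


def trunc_normal_(shape, rng: np.random.Generator, std: float = 0.02) -> np.ndarray:
    """Truncated normal init (+-2 std), the ConvNeXt convention."""
    vals = rng.standard_normal(size=shape)
    bad = np.abs(vals) > 2.0
    while bad.any():
        vals[bad] = rng.standard_normal(size=int(bad.sum()))
        bad = np.abs(vals) > 2.0
    return vals * std


class Conv2d(Module):
    def __init__(self, cin: int, cout: int, kernel: int, *, stride: int = 1,
                 padding: int = 0, groups: int = 1, bias: bool = True,
                 rng: np.random.Generator | None = None):
        super().__init__()
        rng = rng or np.random.default_rng()
        self.stride, self.padding, self.groups = stride, padding, groups
        self.weight = Parameter(trunc_normal_((cout, cin // groups, kernel, kernel), rng))
        self.bias = Parameter(np.zeros(cout)) if bias else None

    def forward(self, x: Tensor) -> Tensor:
        return F.conv2d(x, self.weight, self.bias, stride=self.stride,
                        padding=self.padding, groups=self.groups)


class ConvTranspose2x2(Module):
    """2x2/stride-2 transposed convolution (learned x2 upsampling)."""

    def __init__(self, cin: int, cout: int, *, rng: np.random.Generator | None = None):
        super().__init__()
        rng = rng or np.random.default_rng()
        self.weight = Parameter(trunc_normal_((cin, cout, 2, 2), rng))
        self.bias = Parameter(np.zeros(cout))

    def forward(self, x: Tensor) -> Tensor:
        return F.conv_transpose2x2(x, self.weight, self.bias)


class ChannelLayerNorm(Module):
    """LayerNorm across channels of (N, C, H, W)."""

    def __init__(self, channels: int, eps: float = 1e-6):
        super().__init__()
        self.eps = eps
        self.weight = Parameter(np.ones(channels))
        self.bias = Parameter(np.zeros(channels))

    def forward(self, x: Tensor) -> Tensor:
        return F.layer_norm_channels(x, self.weight, self.bias, self.eps)


class BatchNorm2d(Module):
    def __init__(self, channels: int, eps: float = 1e-5, momentum: float = 0.1):
        super().__init__()
        self.eps, self.momentum = eps, momentum
        self.weight = Parameter(np.ones(channels))
        self.bias = Parameter(np.zeros(channels))
        self._buffers["running_mean"] = np.zeros(channels)
        self._buffers["running_var"] = np.ones(channels)

    def forward(self, x: Tensor) -> Tensor:
        return F.batch_norm2d(x, self.weight, self.bias,
                              self._buffers["running_mean"],
                              self._buffers["running_var"],
                              training=self.training, momentum=self.momentum,
                              eps=self.eps)
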