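"""Layer/module abstractions over the autodiff tensors."""

from __future__ import annotations

from typing import Iterator

import numpy as np

from .tensor import (
    Tensor,
    batch_norm,
    conv2d,
    dropout,
    maxpool2d,
    resize_bilinear,
    softmax,
)

__all__ = [
    "Parameter",
    "Module",
    "ModuleList",
    "Sequential",
    "Conv2d",
    "Linear",
    "BatchNorm2d",
    "MaxPool2d",
    "Dropout",
    "ReLU",
    "UpsampleBilinear",
    "Softmax",
    "Flatten",
]


class Parameter(Tensor):
    """A trainable tensor."""

    def __init__(self, data):
        super().__init__(np.asarray(data), requires_grad=True)


class Module:
    """Base class; children are discovered through instance attributes."""

    def __init__(self):
        self.training = True

    def _children(self) -> Iterator[tuple[str, "Module"]]:
        for name, value in vars(self).items():
            if isinstance(value, Module):
                yield name, value

    def named_parameters(self, prefix: str = "") -> Iterator[tuple[str, Parameter]]:
        for name, value in vars(self).items():
            full = f"{prefix}{name}"
            if isinstance(value, Parameter):
                yield full, value
            elif isinstance(value, Module):
                yield from value.named_parameters(f"{full}.")

    def parameters(self) -> list[Parameter]:
        return [p for _, p in self.named_parameters()]

    def named_buffers(self, prefix: str = "") -> Iterator[tuple[str, np.ndarray]]:
        for name in getattr(self, "_buffer_names", ()):
            yield f"{prefix}{name}", getattr(self, name)
        for name, child in self._children():
            yield from child.named_buffers(f"{prefix}{name}.")

    def train(self, mode: bool = True) -> "Module":
        self.training = mode
        for _, child in self._children():
            child.train(mode)
        return self

    def eval(self) -> "Module":
        return self.train(False)

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.grad = None

    def num_parameters(self) -> int:
        return sum(p.data.size for p in self.parameters())

    # -- (de)serialisation ---------------------------------------------------
    def state_dict(self) -> dict[str, np.ndarray]:
        state = {name: p.data.copy() for name, p in self.named_parameters()}
        for name, buf in self.named_buffers():
            state[name] = np.asarray(buf).copy()
        return state

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        params = dict(self.named_parameters())
        buffers = dict(self.named_buffers())
        for name, value in state.items():
            if name in params:
                if params[name].data.shape != value.shape:
                    raise ValueError(f"shape mismatch for {name}")
                params[name].data = value.astype(params[name].data.dtype).copy()
            elif name in buffers:
                buf = buffers[name]
                np.copyto(buf, value)
            else:
                raise KeyError(f"unknown state entry {name}")

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)


class ModuleList(Module):
    def __init__(self, modules=()):
        super().__init__()
        self._modules = list(modules)
        for i, m in enumerate(self._modules):
            setattr(self, str(i), m)

    def append(self, module: Module) -> None:
        setattr(self, str(len(self._modules)), module)
        self._modules.append(module)

    def __iter__(self):
        return iter(self._modules)

    def __len__(self):
        return len(self._modules)

    def __getitem__(self, i):
        return self._modules[i]


class Sequential(Module):
    def __init__(self, *modules: Module):
        super().__init__()
        self.layers = ModuleList(modules)

    def forward(self, x: Tensor) -> Tensor:
        for layer in self.layers:
            x = layer(x)
        return x

    def __iter__(self):
        return iter(self.layers)

    def __getitem__(self, i):
        return self.layers[i]


class Conv2d(Module):
    def __init__(self, in_channels: int, out_channels: int, kernel_size: int = 3,
                 padding: int | None = None, rng: np.random.Generator | None = None,
                 dtype=np.float32):
        super().__init__()
        rng = rng or np.random.default_rng()
        if padding is None:
            padding = kernel_size // 2
        self.in_channels = in_channels
        self.out_channels = out_channels
        self.kernel_size = kernel_size
        self.padding = padding
        fan_in = in_channels * kernel_size * kernel_size
        std = np.sqrt(2.0 / fan_in)  # He init for ReLU nets
        self.weight = Parameter(
            (rng.standard_normal((out_channels, in_channels, kernel_size, kernel_size)) * std).astype(dtype)
        )
        self.bias = Parameter(np.zeros(out_channels, dtype=dtype))

    def forward(self, x: Tensor) -> Tensor:
        return conv2d(x, self.weight, self.bias, padding=self.padding)


class Linear(Module):
    def __init__(self, in_features: int, out_features: int,
                 rng: np.random.Generator | None = None, dtype=np.float32):
        super().__init__()
        rng = rng or np.random.default_rng()
        self.in_features = in_features
        self.out_features = out_features
        std = np.sqrt(2.0 / in_features)
        self.weight = Parameter((rng.standard_normal((in_features, out_features)) * std).astype(dtype))
        self.bias = Parameter(np.zeros(out_features, dtype=dtype))

    def forward(self, x: Tensor) -> Tensor:
        return x @ self.weight + self.bias


class BatchNorm2d(Module):
    _buffer_names = ("running_mean", "running_var")

    def __init__(self, channels: int, momentum: float = 0.1, eps: float = 1e-5, dtype=np.float32):
        super().__init__()
        self.channels = channels
        self.momentum = momentum
        self.eps = eps
        self.weight = Parameter(np.ones(channels, dtype=dtype))
        self.bias = Parameter(np.zeros(channels, dtype=dtype))
        self.running_mean = np.zeros(channels, dtype=np.float64)
        self.running_var = np.ones(channels, dtype=np.float64)
        # When frozen, batch statistics are never used nor updated even in
        # train mode (frozen blocks in transfer learning stay truly frozen).
        self.frozen = False

    def forward(self, x: Tensor) -> Tensor:
        training = self.training and not self.frozen
        return batch_norm(x, self.weight, self.bias, self.running_mean,
                          self.running_var, training, self.momentum, self.eps)


class MaxPool2d(Module):
    def __init__(self, kernel_size: int = 2):
        super().__init__()
        self.kernel_size = kernel_size

    def forward(self, x: Tensor) -> Tensor:
        return maxpool2d(x, self.kernel_size)


class Dropout(Module):
    def __init__(self, p: float, rng: np.random.Generator | None = None):
        super().__init__()
        if not 0.0 <= p < 1.0:
            raise ValueError("dropout probability must be in [0, 1)")
        self.p = p
        self.rng = rng or np.random.default_rng()

    def forward(self, x: Tensor) -> Tensor:
        return dropout(x, self.p, self.rng, self.training)


class ReLU(Module):
    def forward(self, x: Tensor) -> Tensor:
        return x.relu()


class Softmax(Module):
    def __init__(self, axis: int = 1):
        super().__init__()
        self.axis = axis

    def forward(self, x: Tensor) -> Tensor:
        return softmax(x, self.axis)


class Flatten(Module):
    def forward(self, x: Tensor) -> Tensor:
        return x.flatten_batch()


class UpsampleBilinear(Module):
    """Doubles the spatial dims (or resizes to an explicit target)."""

    def __init__(self, scale: int = 2):
        super().__init__()
        self.scale = scale

    def forward(self, x: Tensor, target_hw: tuple[int, int] | None = None) -> Tensor:
        if target_hw is None:
            target_hw = (x.shape[2] * self.scale, x.shape[3] * self.scale)
        return resize_bilinear(x, target_hw)
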