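"""Layer/module abstractions over the autograd engine."""

from __future__ import annotations

import numpy as np

from . import autograd as ag
from .autograd import DTYPE, Tensor


class Module:
    """Base class: tracks parameters and child modules by attribute."""

    def parameters(self) -> list[Tensor]:
        params: list[Tensor] = []
        for value in self.__dict__.values():
            if isinstance(value, Tensor) and value.requires_grad:
                params.append(value)
            elif isinstance(value, Module):
                params.extend(value.parameters())
            elif isinstance(value, (list, tuple)):
                for item in value:
                    if isinstance(item, Module):
                        params.extend(item.parameters())
        return params

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.grad = None

    def state_arrays(self) -> list[np.ndarray]:
        return [p.data.copy() for p in self.parameters()]

    def load_state_arrays(self, arrays: list[np.ndarray]) -> None:
        params = self.parameters()
        if len(arrays) != len(params):
            raise ValueError(f"expected {len(params)} arrays, got {len(arrays)}")
        for p, a in zip(params, arrays):
            if p.data.shape != a.shape:
                raise ValueError(f"shape mismatch: {p.data.shape} vs {a.shape}")
            p.data = a.astype(DTYPE)

    def freeze(self) -> None:
        for p in self.parameters():
            p.requires_grad = False


class Conv2d(Module):
    def __init__(
        self,
        in_channels: int,
        out_channels: int,
        kernel_size: int = 3,
        stride: int = 1,
        pad: int | None = None,
        rng: np.random.Generator | None = None,
        gain: float = 1.0,
        bias: bool = True,
    ):
        rng = rng or np.random.default_rng(0)
        fan_in = in_channels * kernel_size * kernel_size
        scale = gain * np.sqrt(2.0 / fan_in)
        self.weight = Tensor(
            rng.standard_normal((out_channels, in_channels, kernel_size, kernel_size))
            * scale,
            requires_grad=True,
        )
        self.bias = Tensor(np.zeros(out_channels), requires_grad=True) if bias else None
        self.stride = stride
        self.pad = kernel_size // 2 if pad is None else pad

    def __call__(self, x: Tensor) -> Tensor:
        return ag.conv2d(x, self.weight, self.bias, stride=self.stride, pad=self.pad)


class Linear(Module):
    def __init__(
        self,
        in_features: int,
        out_features: int,
        rng: np.random.Generator | None = None,
        gain: float = 1.0,
    ):
        rng = rng or np.random.default_rng(0)
        scale = gain * np.sqrt(2.0 / in_features)
        self.weight = Tensor(
            rng.standard_normal((in_features, out_features)) * scale, requires_grad=True
        )
        self.bias = Tensor(np.zeros(out_features), requires_grad=True)

    def __call__(self, x: Tensor) -> Tensor:
        return ag.matmul(x, self.weight) + self.bias


def save_modules(path, modules: dict[str, Module], meta: dict | None = None) -> None:
    """Serialize named modules (and optional JSON-able metadata) to .npz."""
    import json

    payload: dict[str, np.ndarray] = {}
    for name, module in modules.items():
        for i, arr in enumerate(module.state_arrays()):
            payload[f"{name}__{i}"] = arr
    payload["__meta__"] = np.frombuffer(
        json.dumps(meta or {}).encode(), dtype=np.uint8
    )
    np.savez(path, **payload)


def load_modules(path, modules: dict[str, Module]) -> dict:
    import json

    with np.load(path) as data:
        for name, module in modules.items():
            arrays = []
            i = 0
            while f"{name}__{i}" in data:
                arrays.append(data[f"{name}__{i}"])
                i += 1
            module.load_state_arrays(arrays)
        meta = json.loads(bytes(data["__meta__"].tolist()).decode())
    return meta
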