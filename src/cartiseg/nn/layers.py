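"""Parameterised layers and a light module container for the autodiff engine."""

from __future__ import annotations

import numpy as np

from .tensor import Tensor, conv2d, conv_transpose2d_2x2

__all__ = ["Module", "Conv2d", "ConvTranspose2x2", "init_std"]


def init_std(fan_in: int, scheme: str) -> float:
    """Weight-init standard deviation: LeCun normal (1/fan_in) pairs with
    SELU, He normal (2/fan_in) with ReLU."""
    if scheme == "lecun":
        return float(np.sqrt(1.0 / fan_in))
    if scheme == "he":
        return float(np.sqrt(2.0 / fan_in))
    raise ValueError(f"unknown init scheme {scheme!r} (expected 'lecun' or 'he')")


class Module:
    """Minimal container: collects parameter tensors from attributes."""

    def parameters(self) -> list[Tensor]:
        params: list[Tensor] = []
        seen: set[int] = set()
        self._collect(self, params, seen)
        return params

    @staticmethod
    def _collect(obj, params: list[Tensor], seen: set[int]) -> None:
        if id(obj) in seen:
            return
        seen.add(id(obj))
        if isinstance(obj, Tensor):
            if obj.requires_grad:
                params.append(obj)
            return
        if isinstance(obj, Module):
            for v in vars(obj).values():
                Module._collect(v, params, seen)
        elif isinstance(obj, (list, tuple)):
            for v in obj:
                Module._collect(v, params, seen)
        elif isinstance(obj, dict):
            for v in obj.values():
                Module._collect(v, params, seen)

    def state_dict(self) -> list[np.ndarray]:
        return [p.data.copy() for p in self.parameters()]

    def load_state_dict(self, state: list[np.ndarray]) -> None:
        params = self.parameters()
        if len(params) != len(state):
            raise ValueError(
                f"state has {len(state)} arrays, module has {len(params)} parameters")
        for p, arr in zip(params, state):
            if p.data.shape != arr.shape:
                raise ValueError(f"shape mismatch {p.data.shape} vs {arr.shape}")
            p.data = np.ascontiguousarray(arr, dtype=np.float32)

    def parameter_count(self) -> int:
        return int(sum(p.data.size for p in self.parameters()))


class Conv2d(Module):
    def __init__(self, cin: int, cout: int, kernel: int, stride: int = 1,
                 init: str = "lecun", rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng()
        std = init_std(cin * kernel * kernel, init)
        self.weight = Tensor(
            rng.normal(0.0, std, (cout, cin, kernel, kernel)), requires_grad=True)
        self.bias = Tensor(np.zeros(cout), requires_grad=True)
        self.stride = stride

    def __call__(self, x: Tensor) -> Tensor:
        return conv2d(x, self.weight, self.bias, stride=self.stride)


class ConvTranspose2x2(Module):
    """Kernel-2, stride-2 transposed convolution (doubles H and W)."""

    def __init__(self, cin: int, cout: int, init: str = "lecun",
                 rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng()
        std = init_std(cin, init)  # each output pixel sees cin inputs
        self.weight = Tensor(
            rng.normal(0.0, std, (cin, cout, 2, 2)), requires_grad=True)
        self.bias = Tensor(np.zeros(cout), requires_grad=True)

    def __call__(self, x: Tensor) -> Tensor:
        return conv_transpose2d_2x2(x, self.weight, self.bias)
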