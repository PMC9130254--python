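"""Adam optimizer with the AMSGrad variant."""

from __future__ import annotations

import numpy as np

from .tensor import Tensor

__all__ = ["Adam"]


class Adam:
    """Adam with optional AMSGrad (max of second-moment estimates).

    Defaults mirror the training configuration used throughout the package:
    lr 1e-4, AMSGrad enabled.
    """

    def __init__(self, params: list[Tensor], lr: float = 1e-4,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8,
                 amsgrad: bool = True):
        if lr <= 0:
            raise ValueError("learning rate must be positive")
        self.params = list(params)
        self.lr = float(lr)
        self.b1, self.b2 = betas
        self.eps = eps
        self.amsgrad = amsgrad
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]
        self.vhat = [np.zeros_like(p.data) for p in self.params] if amsgrad else None

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None

    def step(self) -> None:
        self.t += 1
        bc1 = 1.0 - self.b1 ** self.t
        bc2 = 1.0 - self.b2 ** self.t
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            self.m[i] = self.b1 * self.m[i] + (1.0 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1.0 - self.b2) * g * g
            if self.amsgrad:
                np.maximum(self.vhat[i], self.v[i], out=self.vhat[i])
                v = self.vhat[i]
            else:
                v = self.v[i]
            p.data -= (self.lr / bc1) * self.m[i] / (np.sqrt(v / bc2) + self.eps)
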