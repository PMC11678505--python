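"""Adam optimizer for the numpy autodiff engine."""

from __future__ import annotations

import numpy as np

__all__ = ["Adam", "EmaWeights"]


class EmaWeights:
    """Exponential moving average of parameters; stabilises small-batch runs.

    Call :meth:`update` after each optimizer step; :meth:`copy_to` installs
    the averaged weights (typically at the end of training, for evaluation).
    """

    def __init__(self, params, decay: float = 0.995):
        self.params = list(params)
        self.decay = decay
        self.t = 0
        self.shadow = [np.zeros_like(p.data) for p in self.params]

    def update(self) -> None:
        d = self.decay
        self.t += 1
        for s, p in zip(self.shadow, self.params):
            s *= d
            s += (1.0 - d) * p.data

    def copy_to(self) -> None:
        # bias-corrected average (valid from the first step)
        corr = 1.0 - self.decay**self.t
        for s, p in zip(self.shadow, self.params):
            p.data = s / corr


class Adam:
    """Adam with optional global-norm gradient clipping."""

    def __init__(self, params, lr: float = 1e-3, betas=(0.9, 0.999),
                 eps: float = 1e-8, clip_norm: float | None = None):
        self.params = list(params)
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.clip_norm = clip_norm
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def step(self) -> None:
        self.t += 1
        if self.clip_norm is not None:
            total = np.sqrt(sum(
                float((p.grad**2).sum()) for p in self.params if p.grad is not None
            ))
            if total > self.clip_norm:
                scale = self.clip_norm / (total + 1e-12)
                for p in self.params:
                    if p.grad is not None:
                        p.grad = p.grad * scale
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            mhat = self.m[i] / (1 - self.b1**self.t)
            vhat = self.v[i] / (1 - self.b2**self.t)
            p.data = p.data - self.lr * mhat / (np.sqrt(vhat) + self.eps)

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None
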