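"""Adam optimizer with global-norm gradient clipping and a linear
warmup / linear decay learning-rate schedule."""

from __future__ import annotations

import numpy as np

from .autograd import Tensor

__all__ = ["LinearWarmupSchedule", "Adam", "clip_global_norm"]


class LinearWarmupSchedule:
    """lr ramps linearly to *base_lr* over *warmup_steps*, then decays
    linearly to 0 at *total_steps* (flat if total_steps is unknown)."""

    def __init__(self, base_lr: float, warmup_steps: int, total_steps: int | None):
        self.base_lr = base_lr
        self.warmup_steps = max(int(warmup_steps), 0)
        self.total_steps = total_steps

    def __call__(self, step: int) -> float:
        if self.warmup_steps and step < self.warmup_steps:
            return self.base_lr * (step + 1) / self.warmup_steps
        if self.total_steps is None or self.total_steps <= self.warmup_steps:
            return self.base_lr
        frac = (self.total_steps - step) / (self.total_steps - self.warmup_steps)
        return self.base_lr * max(frac, 0.0)


def clip_global_norm(params: list[Tensor], clip_norm: float) -> float:
    """Scale all gradients so their global L2 norm is at most *clip_norm*."""
    total = 0.0
    for p in params:
        if p.grad is not None:
            total += float((p.grad**2).sum())
    norm = float(np.sqrt(total))
    if clip_norm > 0 and norm > clip_norm:
        scale = clip_norm / (norm + 1e-12)
        for p in params:
            if p.grad is not None:
                p.grad *= scale
    return norm


class Adam:
    def __init__(
        self,
        params: list[Tensor],
        schedule: LinearWarmupSchedule,
        beta1: float = 0.9,
        beta2: float = 0.999,
        eps: float = 1e-8,
        clip_norm: float = 1.0,
    ):
        self.params = params
        self.schedule = schedule
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.clip_norm = clip_norm
        self.step_count = 0
        self.m = [np.zeros_like(p.data) for p in params]
        self.v = [np.zeros_like(p.data) for p in params]

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None

    def step(self) -> float:
        """Apply one update; returns the learning rate used."""
        clip_global_norm(self.params, self.clip_norm)
        lr = self.schedule(self.step_count)
        self.step_count += 1
        t = self.step_count
        b1, b2 = self.beta1, self.beta2
        for i, p in enumerate(self.params):
            g = p.grad
            if g is None:
                continue
            self.m[i] = b1 * self.m[i] + (1 - b1) * g
            self.v[i] = b2 * self.v[i] + (1 - b2) * g * g
            mhat = self.m[i] / (1 - b1**t)
            vhat = self.v[i] / (1 - b2**t)
            p.data -= lr * mhat / (np.sqrt(vhat) + self.eps)
        return lr
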