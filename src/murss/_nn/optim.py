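"""Parameter update rules."""

from __future__ import annotations

import numpy as np

__all__ = ["Adam", "SGD"]


class Adam:
    """Adaptive-moment estimation (bias-corrected first/second moments)."""

    def __init__(self, params, lr=1e-4, betas=(0.9, 0.999), eps=1e-8,
                 total_steps=None, min_lr_frac=0.1):
        self.params = list(params)
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        # optional cosine decay to min_lr_frac * lr over total_steps; large
        # early steps learn the features, small late steps let the
        # coverage/risk balance settle instead of oscillating
        self.total_steps = total_steps
        self.min_lr_frac = min_lr_frac
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def current_lr(self):
        if not self.total_steps:
            return self.lr
        frac = min(self.t / self.total_steps, 1.0)
        scale = self.min_lr_frac + (1 - self.min_lr_frac) * 0.5 * (
            1 + np.cos(np.pi * frac)
        )
        return self.lr * scale

    def step(self):
        lr = self.current_lr()
        self.t += 1
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            mhat = self.m[i] / (1 - self.b1**self.t)
            vhat = self.v[i] / (1 - self.b2**self.t)
            p.data -= lr * mhat / (np.sqrt(vhat) + self.eps)

    def zero_grad(self):
        for p in self.params:
            p.zero_grad()


class SGD:
    def __init__(self, params, lr=1e-2):
        self.params = list(params)
        self.lr = lr

    def step(self):
        for p in self.params:
            if p.grad is not None:
                p.data -= self.lr * p.grad

    def zero_grad(self):
        for p in self.params:
            p.zero_grad()
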