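"""Optimizers. RAdam (rectified Adam) is the default for pre-training."""

from __future__ import annotations

import numpy as np

__all__ = ["RAdam", "SGD"]


class SGD:
    def __init__(self, params, lr=1e-2):
        self.params = list(params)
        self.lr = lr

    def zero_grad(self):
        for p in self.params:
            p.grad = None

    def step(self):
        for p in self.params:
            if p.grad is not None:
                p.data -= self.lr * p.grad


class RAdam:
    """Rectified Adam: variance-rectified adaptive step (Liu et al. 2020).

    Falls back to an un-adapted momentum step while the second-moment
    estimate's variance is untrustworthy (rho_t <= 4).
    """

    def __init__(self, params, lr=4e-4, betas=(0.9, 0.999), eps=1e-8):
        self.params = list(params)
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]
        self.rho_inf = 2.0 / (1.0 - self.b2) - 1.0

    def zero_grad(self):
        for p in self.params:
            p.grad = None

    def step(self):
        self.t += 1
        t, b1, b2 = self.t, self.b1, self.b2
        rho = self.rho_inf - 2.0 * t * b2**t / (1.0 - b2**t)
        if rho > 4.0:
            r = np.sqrt(
                ((rho - 4.0) * (rho - 2.0) * self.rho_inf)
                / ((self.rho_inf - 4.0) * (self.rho_inf - 2.0) * rho)
            )
        else:
            r = None
        for p, m, v in zip(self.params, self.m, self.v):
            if p.grad is None:
                continue
            g = p.grad
            m *= b1
            m += (1 - b1) * g
            v *= b2
            v += (1 - b2) * g * g
            mhat = m / (1.0 - b1**t)
            if r is not None:
                vhat = np.sqrt(v / (1.0 - b2**t)) + self.eps
                p.data -= self.lr * r * mhat / vhat
            else:
                p.data -= self.lr * mhat
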