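"""Rectified Adam (RAdam) and the softmax cross-entropy loss.

RAdam rectifies the variance of the adaptive learning rate in Adam's early
steps: while the approximated second-moment SNR ``rho_t`` is at most 4 the
update falls back to plain momentum, afterwards the adaptive step is scaled
by the rectification term ``r_t``.
"""

from __future__ import annotations

import numpy as np

__all__ = ["RAdam", "softmax", "softmax_cross_entropy"]


class RAdam:
    def __init__(self, params, lr=1e-4, betas=(0.9, 0.999), eps=1e-6):
        self.params = list(params)
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.value) for p in self.params]
        self.v = [np.zeros_like(p.value) for p in self.params]
        self.rho_inf = 2.0 / (1.0 - self.b2) - 1.0

    def zero_grad(self):
        for p in self.params:
            p.grad[...] = 0.0

    def step(self):
        self.t += 1
        t = self.t
        b1t = self.b1**t
        b2t = self.b2**t
        rho_t = self.rho_inf - 2.0 * t * b2t / (1.0 - b2t)
        if rho_t > 4.0:
            r = np.sqrt(
                ((rho_t - 4.0) * (rho_t - 2.0) * self.rho_inf)
                / ((self.rho_inf - 4.0) * (self.rho_inf - 2.0) * rho_t)
            )
        else:
            r = None
        for p, m, v in zip(self.params, self.m, self.v):
            g = p.grad
            m *= self.b1
            m += (1 - self.b1) * g
            v *= self.b2
            v += (1 - self.b2) * g * g
            mhat = m / (1 - b1t)
            if r is not None:
                vhat = np.sqrt(v / (1 - b2t))
                p.value -= self.lr * r * mhat / (vhat + self.eps)
            else:
                p.value -= self.lr * mhat


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def softmax_cross_entropy(logits: np.ndarray, y: np.ndarray):
    """Mean categorical cross-entropy; returns (loss, dlogits)."""
    n = logits.shape[0]
    p = softmax(logits.astype(np.float64))
    loss = -np.mean(np.log(p[np.arange(n), y] + 1e-12))
    dlogits = p
    dlogits[np.arange(n), y] -= 1.0
    return float(loss), (dlogits / n).astype(np.float32)
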