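"""Optimisers for the training harness."""

from __future__ import annotations

import numpy as np


class Adam:
    """Standard Adam with optional decoupled weight decay and grad clipping."""

    def __init__(self, params, lr=1e-3, betas=(0.9, 0.999), eps=1e-8,
                 weight_decay=0.0, clip_norm=None):
        self.params = list(params)
        self.lr, self.betas, self.eps = lr, betas, eps
        self.weight_decay = weight_decay
        self.clip_norm = clip_norm
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def zero_grad(self):
        for p in self.params:
            p.grad = None

    def step(self):
        self.t += 1
        b1, b2 = self.betas
        if self.clip_norm is not None:
            total = 0.0
            for p in self.params:
                if p.grad is not None:
                    total += float((p.grad.astype(np.float64) ** 2).sum())
            norm = np.sqrt(total)
            scale = min(1.0, self.clip_norm / (norm + 1e-12))
        else:
            scale = 1.0
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad * scale
            if self.weight_decay:
                p.data *= 1.0 - self.lr * self.weight_decay
            self.m[i] = b1 * self.m[i] + (1 - b1) * g
            self.v[i] = b2 * self.v[i] + (1 - b2) * g * g
            mhat = self.m[i] / (1 - b1**self.t)
            vhat = self.v[i] / (1 - b2**self.t)
            p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
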