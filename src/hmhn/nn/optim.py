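"""Optimisers and learning-rate scheduling.

AdamW uses decoupled weight decay (decay applied directly to the weights,
not through the gradient moments). ``ReduceLROnPlateau`` multiplies the
learning rate by ``factor`` when the monitored metric stops improving.
"""

from __future__ import annotations

import numpy as np

__all__ = ["AdamW", "ReduceLROnPlateau"]


class AdamW:
    def __init__(self, params, lr: float = 1e-3, betas=(0.9, 0.999),
                 eps: float = 1e-8, weight_decay: float = 1e-2):
        self.params = list(params)
        self.lr = lr
        self.betas = betas
        self.eps = eps
        self.weight_decay = weight_decay
        self._m = [np.zeros_like(p.data) for p in self.params]
        self._v = [np.zeros_like(p.data) for p in self.params]
        self._t = 0

    def zero_grad(self):
        for p in self.params:
            p.zero_grad()

    def step(self):
        self._t += 1
        b1, b2 = self.betas
        bc1 = 1.0 - b1 ** self._t
        bc2 = 1.0 - b2 ** self._t
        for p, m, v in zip(self.params, self._m, self._v):
            if p.grad is None:
                continue
            g = p.grad
            m *= b1
            m += (1 - b1) * g
            v *= b2
            np.square(g, out=g)              # grad is consumed here
            g *= (1 - b2)
            v += g
            if self.weight_decay:
                p.data *= (1.0 - self.lr * self.weight_decay)
            # update = lr * (m/bc1) / (sqrt(v/bc2) + eps), built in-place in g
            np.divide(v, bc2, out=g)
            np.sqrt(g, out=g)
            g += self.eps
            np.divide(m, g, out=g)
            g *= self.lr / bc1
            p.data -= g
            p.grad = None


class ReduceLROnPlateau:
    """Decay ``optimizer.lr`` by ``factor`` after ``patience`` epochs without
    improvement of the monitored quantity (lower is better)."""

    def __init__(self, optimizer: AdamW, factor: float = 0.1, patience: int = 3,
                 min_lr: float = 1e-6):
        self.optimizer = optimizer
        self.factor = factor
        self.patience = patience
        self.min_lr = min_lr
        self.best = np.inf
        self.bad_epochs = 0

    def step(self, metric: float) -> bool:
        """Returns True if the learning rate was decayed this call."""
        if metric < self.best - 1e-12:
            self.best = metric
            self.bad_epochs = 0
            return False
        self.bad_epochs += 1
        if self.bad_epochs > self.patience:
            self.optimizer.lr = max(self.optimizer.lr * self.factor, self.min_lr)
            self.bad_epochs = 0
            return True
        return False
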