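"""Optimization: RMSProp and a reduce-on-plateau learning-rate schedule."""

from __future__ import annotations

import numpy as np

from .autograd import Tensor


class RMSProp:
    """RMSProp with exponentially-weighted squared-gradient normalization.

    Update: ``s <- alpha*s + (1-alpha)*g^2``; ``p <- p - lr * g / (sqrt(s)+eps)``.
    """

    def __init__(self, params: list[Tensor], lr: float = 1e-5,
                 alpha: float = 0.99, eps: float = 1e-8):
        self.params = list(params)
        self.lr = float(lr)
        self.alpha = float(alpha)
        self.eps = float(eps)
        self.square_avg = [np.zeros_like(p.data) for p in self.params]

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None

    def step(self) -> None:
        for p, s in zip(self.params, self.square_avg):
            if p.grad is None:
                continue
            g = p.grad
            s *= self.alpha
            s += (1.0 - self.alpha) * g * g
            p.data -= self.lr * g / (np.sqrt(s) + self.eps)

    def state_dict(self) -> dict:
        return {
            "lr": self.lr,
            "alpha": self.alpha,
            "eps": self.eps,
            "square_avg": [s.copy() for s in self.square_avg],
        }

    def load_state_dict(self, state: dict) -> None:
        self.lr = state["lr"]
        self.alpha = state["alpha"]
        self.eps = state["eps"]
        self.square_avg = [np.asarray(s, dtype=np.float64).copy() for s in state["square_avg"]]


class ReduceLROnPlateau:
    """Multiply the learning rate by ``factor`` after ``patience`` epochs
    without improvement of the monitored loss, floored at ``min_lr``."""

    def __init__(self, optimizer: RMSProp, factor: float = 0.1,
                 patience: int = 3, min_lr: float = 1e-8, threshold: float = 1e-6):
        if not (0.0 < factor < 1.0):
            raise ValueError("factor must be in (0, 1)")
        self.optimizer = optimizer
        self.factor = factor
        self.patience = patience
        self.min_lr = min_lr
        self.threshold = threshold
        self.best = np.inf
        self.num_bad = 0

    @property
    def lr(self) -> float:
        return self.optimizer.lr

    def step(self, metric: float) -> None:
        if metric < self.best - self.threshold:
            self.best = metric
            self.num_bad = 0
        else:
            self.num_bad += 1
            if self.num_bad > self.patience:
                self.optimizer.lr = max(self.optimizer.lr * self.factor, self.min_lr)
                self.num_bad = 0

    def state_dict(self) -> dict:
        return {"best": self.best, "num_bad": self.num_bad, "lr": self.optimizer.lr}

    def load_state_dict(self, state: dict) -> None:
        self.best = state["best"]
        self.num_bad = state["num_bad"]
        self.optimizer.lr = state["lr"]
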