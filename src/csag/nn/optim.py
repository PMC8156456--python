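"""Momentum SGD with decoupled-from-nothing, classic L2 weight decay."""

from __future__ import annotations

import numpy as np

__all__ = ["SGD"]


class SGD:
    """v <- momentum*v + grad + wd*param;  param <- param - lr*v."""

    def __init__(self, params, lr: float, momentum: float = 0.0, weight_decay: float = 0.0):
        self.params = list(params)
        self.lr = float(lr)
        self.momentum = float(momentum)
        self.weight_decay = float(weight_decay)
        self.velocity = [np.zeros_like(p.data) for p in self.params]

    def step(self):
        for p, v in zip(self.params, self.velocity):
            if p.grad is None:
                continue
            g = p.grad
            if self.weight_decay:
                g = g + self.weight_decay * p.data
            v *= self.momentum
            v += g
            p.data = p.data - self.lr * v

    def zero_grad(self):
        for p in self.params:
            p.grad = None

    def state_dict(self) -> dict:
        return {
            "lr": self.lr,
            "momentum": self.momentum,
            "weight_decay": self.weight_decay,
            "velocity": [v.copy() for v in self.velocity],
        }

    def load_state_dict(self, state: dict):
        self.lr = float(state["lr"])
        self.momentum = float(state["momentum"])
        self.weight_decay = float(state["weight_decay"])
        vel = state["velocity"]
        if len(vel) != len(self.velocity):
            raise ValueError("optimizer state does not match parameter list")
        self.velocity = [np.array(v) for v in vel]
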