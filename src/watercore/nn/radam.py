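"""Rectified Adam optimizer (variance-rectified adaptive moments).

When the rectification term rho_t <= 4 the adaptive denominator is skipped
and the update falls back to momentum SGD, as in the published algorithm.
Weight decay is applied L2-style (added to the gradient).
"""

from __future__ import annotations

import numpy as np


class RAdam:
    def __init__(
        self,
        parameters,
        lr: float = 1e-3,
        betas: tuple[float, float] = (0.9, 0.999),
        eps: float = 1e-8,
        weight_decay: float = 0.0,
    ):
        self.parameters = list(parameters)  # (layer, key) pairs
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.weight_decay = weight_decay
        self.t = 0
        self.m = [np.zeros_like(layer.params[key]) for layer, key in self.parameters]
        self.v = [np.zeros_like(layer.params[key]) for layer, key in self.parameters]
        self.rho_inf = 2.0 / (1.0 - self.b2) - 1.0

    def step(self) -> None:
        self.t += 1
        t = self.t
        b1t = self.b1**t
        b2t = self.b2**t
        rho = self.rho_inf - 2.0 * t * b2t / (1.0 - b2t)
        if rho > 4.0:
            r = np.sqrt(
                ((rho - 4.0) * (rho - 2.0) * self.rho_inf)
                / ((self.rho_inf - 4.0) * (self.rho_inf - 2.0) * rho)
            )
        else:
            r = None
        for i, (layer, key) in enumerate(self.parameters):
            g = layer.grads.get(key)
            if g is None:
                continue
            if self.weight_decay:
                g = g + self.weight_decay * layer.params[key]
            self.m[i] = self.b1 * self.m[i] + (1.0 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1.0 - self.b2) * g * g
            m_hat = self.m[i] / (1.0 - b1t)
            if r is not None:
                v_hat = np.sqrt(self.v[i] / (1.0 - b2t))
                layer.params[key] -= self.lr * r * m_hat / (v_hat + self.eps)
            else:
                layer.params[key] -= self.lr * m_hat
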