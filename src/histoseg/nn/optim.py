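"""Adam optimizer operating in place on a list of layers."""

from __future__ import annotations

import numpy as np

from .layers import Layer, iter_layers


class Adam:
    def __init__(
        self,
        root: Layer,
        lr: float = 1e-3,
        beta1: float = 0.9,
        beta2: float = 0.999,
        eps: float = 1e-8,
    ):
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.t = 0
        self._slots: list[tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]] = []
        for layer in iter_layers(root):
            for name, param in layer.params.items():
                grad = layer.grads[name]
                self._slots.append(
                    (param, grad, np.zeros_like(param), np.zeros_like(param))
                )

    def step(self) -> None:
        self.t += 1
        b1c = 1.0 - self.beta1**self.t
        b2c = 1.0 - self.beta2**self.t
        for param, grad, m, v in self._slots:
            m *= self.beta1
            m += (1.0 - self.beta1) * grad
            v *= self.beta2
            v += (1.0 - self.beta2) * grad * grad
            param -= self.lr * (m / b1c) / (np.sqrt(v / b2c) + self.eps)

    def zero_grad(self) -> None:
        for _, grad, _, _ in self._slots:
            grad[...] = 0.0
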