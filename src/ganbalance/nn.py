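"""Fully-connected building blocks on the autodiff engine.

Self-normalising networks: SELU activations, Kaiming-normal weight
initialisation (std = 1/sqrt(fan_in)) and alpha-dropout, so no batch
normalisation layers are needed.
"""

from __future__ import annotations

import numpy as np

from .autodiff import Tensor, selu

__all__ = ["Dense", "AlphaDropout", "SGD", "selu"]

_SELU_ALPHA = 1.6732632423543772
_SELU_SCALE = 1.0507009873554805
_DROP_VALUE = -_SELU_SCALE * _SELU_ALPHA  # saturation value alpha-dropout injects


class Dense:
    """Affine layer ``x @ W + b`` with Kaiming-normal initialisation."""

    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator):
        std = 1.0 / np.sqrt(n_in)
        self.W = Tensor(rng.normal(0.0, std, size=(n_in, n_out)), requires_grad=True)
        self.b = Tensor(np.zeros((1, n_out)), requires_grad=True)

    def __call__(self, x: Tensor) -> Tensor:
        return x @ self.W + self.b

    @property
    def parameters(self):
        return [self.W, self.b]

    @property
    def n_parameters(self) -> int:
        return self.W.data.size + self.b.data.size

    def state(self):
        return {"W": self.W.data.copy(), "b": self.b.data.copy()}

    def load_state(self, state):
        self.W.data = np.array(state["W"], dtype=np.float64)
        self.b.data = np.array(state["b"], dtype=np.float64)


class AlphaDropout:
    """Dropout variant matched to SELU: dropped units are set to the SELU
    saturation value and the layer output is re-standardised."""

    def __init__(self, p: float):
        if not 0.0 <= p < 1.0:
            raise ValueError(f"dropout probability must be in [0, 1), got {p}")
        self.p = float(p)

    def __call__(self, x: Tensor, rng: np.random.Generator, training: bool) -> Tensor:
        if not training or self.p == 0.0:
            return x
        q = 1.0 - self.p
        keep = (rng.random(x.shape) < q).astype(np.float64)
        a = (q + _DROP_VALUE ** 2 * q * self.p) ** -0.5
        b = -a * self.p * _DROP_VALUE
        return (x * Tensor(keep) + Tensor((1.0 - keep) * _DROP_VALUE)) * a + b


class SGD:
    """Plain stochastic gradient descent with optional momentum."""

    def __init__(self, parameters, lr: float, momentum: float = 0.0):
        self.parameters = list(parameters)
        self.lr = float(lr)
        self.momentum = float(momentum)
        self._velocity = [np.zeros_like(p.data) for p in self.parameters]

    def step(self, grads):
        for p, v, g in zip(self.parameters, self._velocity, grads):
            gd = g.data if isinstance(g, Tensor) else g
            if self.momentum:
                v *= self.momentum
                v += gd
                gd = v
            p.data = p.data - self.lr * gd
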