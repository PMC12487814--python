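"""Dense layers, multilayer perceptrons and the Adam optimiser.

Built on the in-repo autodiff engine (:mod:`chronovae._autodiff`); parameter
initialisation is Glorot-uniform and fully determined by the supplied
``numpy.random.Generator``.
"""

from __future__ import annotations

import numpy as np

from ._autodiff import Tensor


class Dense:
    """Affine map ``x @ W + b`` with optional pointwise activation."""

    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator,
                 activation: str | None = None):
        limit = np.sqrt(6.0 / (n_in + n_out))
        self.W = Tensor(rng.uniform(-limit, limit, size=(n_in, n_out)),
                        requires_grad=True)
        self.b = Tensor(np.zeros(n_out), requires_grad=True)
        self.activation = activation

    def __call__(self, x: Tensor, frozen: bool = False) -> Tensor:
        W, b = (self.W.detach(), self.b.detach()) if frozen else (self.W, self.b)
        h = x @ W + b
        if self.activation == "relu":
            h = h.relu()
        elif self.activation == "tanh":
            h = h.tanh()
        elif self.activation is not None:
            raise ValueError(f"unknown activation {self.activation!r}")
        return h

    @property
    def parameters(self) -> list[Tensor]:
        return [self.W, self.b]


class MLP:
    """Stack of Dense layers; hidden layers share one activation."""

    def __init__(self, sizes: list[int], rng: np.random.Generator,
                 activation: str = "relu", final_activation: str | None = None):
        acts = [activation] * (len(sizes) - 2) + [final_activation]
        self.layers = [Dense(a, b, rng, activation=act)
                       for a, b, act in zip(sizes[:-1], sizes[1:], acts)]

    def __call__(self, x: Tensor, frozen: bool = False) -> Tensor:
        for layer in self.layers:
            x = layer(x, frozen=frozen)
        return x

    @property
    def parameters(self) -> list[Tensor]:
        return [p for layer in self.layers for p in layer.parameters]


def hidden_width(n_in: int, n_latent: int) -> int:
    """Hidden-layer width: geometric mean of input and latent dims, rounded."""
    return max(2, int(round(np.sqrt(n_in * n_latent))))


class Adam:
    """Adam optimiser over an explicit parameter list."""

    def __init__(self, params: list[Tensor], lr: float = 1e-3,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8):
        self.params = list(params)
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self._m = [np.zeros_like(p.data) for p in self.params]
        self._v = [np.zeros_like(p.data) for p in self.params]

    def zero_grad(self) -> None:
        for p in self.params:
            p.zero_grad()

    def step(self) -> None:
        self.t += 1
        for p, m, v in zip(self.params, self._m, self._v):
            if p.grad is None:
                continue
            g = p.grad
            m *= self.b1
            m += (1 - self.b1) * g
            v *= self.b2
            v += (1 - self.b2) * g * g
            mhat = m / (1 - self.b1**self.t)
            vhat = v / (1 - self.b2**self.t)
            p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


def get_state(params: list[Tensor]) -> list[np.ndarray]:
    return [p.data.copy() for p in params]


def set_state(params: list[Tensor], state: list[np.ndarray]) -> None:
    for p, s in zip(params, state):
        p.data[...] = s
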