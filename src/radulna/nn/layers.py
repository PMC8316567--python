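"""Dense layers and multilayer perceptrons on the autodiff core."""

from __future__ import annotations

import numpy as np

from .autodiff import Tensor

_ACTIVATIONS = {
    "relu": lambda t: t.relu(),
    "leaky_relu": lambda t: t.leaky_relu(),
    "sigmoid": lambda t: t.sigmoid(),
    "tanh": lambda t: t.tanh(),
    "softplus": lambda t: t.softplus(),
    None: lambda t: t,
    "linear": lambda t: t,
}


class Parameter(Tensor):
    __slots__ = ()

    def __init__(self, data):
        super().__init__(data, requires_grad=True)


class Dense:
    """Affine layer ``x @ W + b`` with He-style initialization."""

    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator):
        scale = np.sqrt(2.0 / n_in)
        self.W = Parameter(rng.normal(0.0, scale, size=(n_in, n_out)))
        self.b = Parameter(np.zeros(n_out))

    def __call__(self, x: Tensor) -> Tensor:
        return x.matmul(self.W) + self.b

    def parameters(self) -> list:
        return [self.W, self.b]


class MLP:
    """Chain of Dense layers with a shared hidden activation.

    ``sizes`` lists layer widths input-first; the output layer applies
    ``out_activation`` (linear by default, i.e. raw logits).
    """

    def __init__(
        self,
        sizes: list,
        rng: np.random.Generator,
        activation: str = "relu",
        out_activation: str | None = None,
    ):
        if len(sizes) < 2:
            raise ValueError("MLP needs at least input and output sizes")
        self.layers = [Dense(a, b, rng) for a, b in zip(sizes, sizes[1:])]
        self.activation = _ACTIVATIONS[activation]
        self.out_activation = _ACTIVATIONS[out_activation]
        self.sizes = list(sizes)

    def __call__(self, x) -> Tensor:
        t = x if isinstance(x, Tensor) else Tensor(x)
        for layer in self.layers[:-1]:
            t = self.activation(layer(t))
        return self.out_activation(self.layers[-1](t))

    def parameters(self) -> list:
        return [p for layer in self.layers for p in layer.parameters()]

    def state_bytes(self) -> bytes:
        """Concatenated parameter bytes, for freeze-contract checks."""
        return b"".join(p.data.tobytes() for p in self.parameters())
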