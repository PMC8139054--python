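"""Minimal neural-network layers and Adam optimizer on the autodiff engine.

Layers follow the conventions of the MLP architectures used throughout the
package: fully connected layers, batch normalization, leaky-ReLU activations
and dropout. All randomness (init, dropout masks) is drawn from an explicit
``numpy.random.Generator``.
"""

from __future__ import annotations

import numpy as np

from ._autodiff import Tensor

__all__ = ["Dense", "BatchNorm", "Dropout", "LeakyReLU", "Sequential", "Adam"]


class Module:
    training = True

    def parameters(self):
        return []

    def train(self, mode: bool = True):
        self.training = mode
        for m in getattr(self, "_children", []):
            m.train(mode)
        return self

    def eval(self):
        return self.train(False)

    def __call__(self, x, rng=None):
        return self.forward(x, rng)

    def state_arrays(self):
        """Flat list of numpy arrays fully describing the module state."""
        return [p.data for p in self.parameters()]

    def load_state_arrays(self, arrays: list) -> None:
        """Restore state from :meth:`state_arrays` output (same order)."""
        own = self.state_arrays()
        if len(arrays) != len(own):
            raise ValueError(f"expected {len(own)} arrays, got {len(arrays)}")
        self._assign_state(list(arrays))

    def _assign_state(self, arrays: list) -> None:
        for p, a in zip(self.parameters(), arrays):
            p.data = np.asarray(a, dtype=p.data.dtype).reshape(p.data.shape)


class Dense(Module):
    """Affine layer, He-uniform initialisation (suits leaky-ReLU nets)."""

    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator):
        bound = np.sqrt(6.0 / n_in)
        self.W = Tensor(rng.uniform(-bound, bound, size=(n_in, n_out)),
                        requires_grad=True)
        self.b = Tensor(np.zeros((1, n_out)), requires_grad=True)

    def forward(self, x, rng=None):
        return x @ self.W + self.b

    def parameters(self):
        return [self.W, self.b]


class BatchNorm(Module):
    """Batch normalization with affine parameters and running statistics."""

    def __init__(self, n: int, momentum: float = 0.9, eps: float = 1e-5):
        self.gamma = Tensor(np.ones((1, n)), requires_grad=True)
        self.beta = Tensor(np.zeros((1, n)), requires_grad=True)
        self.running_mean = np.zeros((1, n))
        self.running_var = np.ones((1, n))
        self.momentum = momentum
        self.eps = eps

    def forward(self, x, rng=None):
        if not self.training:
            istd = 1.0 / np.sqrt(self.running_var + self.eps)
            scale = Tensor(istd)
            shift = Tensor(-self.running_mean * istd)
            return (x * scale + shift) * self.gamma + self.beta
        # fused training path with a hand-written backward (first-order
        # only; nothing differentiated twice in this package uses BN)
        xd = x.data
        mu = xd.mean(axis=0, keepdims=True)
        var = xd.var(axis=0, keepdims=True)
        m = self.momentum
        self.running_mean = m * self.running_mean + (1 - m) * mu
        self.running_var = m * self.running_var + (1 - m) * var
        istd = 1.0 / np.sqrt(var + self.eps)
        xhat = (xd - mu) * istd
        out = xhat * self.gamma.data + self.beta.data
        gamma, beta = self.gamma, self.beta

        def vjp_x(g):
            gd = g.data
            gxhat = gd * gamma.data
            dx = istd * (gxhat - gxhat.mean(axis=0, keepdims=True)
                         - xhat * (gxhat * xhat).mean(axis=0, keepdims=True))
            return Tensor(dx)

        def vjp_gamma(g):
            return Tensor((g.data * xhat).sum(axis=0, keepdims=True))

        def vjp_beta(g):
            return Tensor(g.data.sum(axis=0, keepdims=True))

        return Tensor._make(out, [(x, vjp_x), (gamma, vjp_gamma),
                                  (beta, vjp_beta)])

    def parameters(self):
        return [self.gamma, self.beta]

    def state_arrays(self):
        return [self.gamma.data, self.beta.data,
                self.running_mean, self.running_var]

    def _assign_state(self, arrays):
        self.gamma.data = np.asarray(arrays[0], dtype=self.gamma.data.dtype)
        self.beta.data = np.asarray(arrays[1], dtype=self.beta.data.dtype)
        self.running_mean = np.asarray(arrays[2], dtype=float)
        self.running_var = np.asarray(arrays[3], dtype=float)


class Dropout(Module):
    def __init__(self, p: float):
        if not 0.0 <= p < 1.0:
            raise ValueError("dropout probability must be in [0, 1)")
        self.p = p

    def forward(self, x, rng=None):
        if not self.training or self.p == 0.0:
            return x
        if rng is None:
            raise ValueError("Dropout in training mode needs an rng")
        mask = (rng.random(x.shape) >= self.p) / (1.0 - self.p)
        return x * Tensor(mask)


class LeakyReLU(Module):
    def __init__(self, slope: float = 0.2):
        self.slope = slope

    def forward(self, x, rng=None):
        return x.leaky_relu(self.slope)


class Sequential(Module):
    def __init__(self, *layers):
        self._children = list(layers)

    def forward(self, x, rng=None):
        for layer in self._children:
            x = layer(x, rng)
        return x

    def parameters(self):
        out = []
        for layer in self._children:
            out.extend(layer.parameters())
        return out

    def state_arrays(self):
        out = []
        for layer in self._children:
            out.extend(layer.state_arrays())
        return out

    def _assign_state(self, arrays):
        pos = 0
        for layer in self._children:
            n = len(layer.state_arrays())
            layer._assign_state(arrays[pos:pos + n])
            pos += n


def mlp(n_in: int, hidden: list[int], n_out: int, rng: np.random.Generator,
        *, batchnorm: bool = True, dropout: float = 0.0,
        slope: float = 0.2) -> Sequential:
    """Standard MLP: [Dense -> (BatchNorm) -> LeakyReLU -> (Dropout)]* -> Dense."""
    layers: list[Module] = []
    prev = n_in
    for h in hidden:
        layers.append(Dense(prev, h, rng))
        if batchnorm:
            layers.append(BatchNorm(h))
        layers.append(LeakyReLU(slope))
        if dropout > 0:
            layers.append(Dropout(dropout))
        prev = h
    layers.append(Dense(prev, n_out, rng))
    return Sequential(*layers)


class Adam:
    """Adam optimizer; operates in place on Tensor parameters."""

    def __init__(self, params, lr: float = 1e-3, betas=(0.9, 0.999),
                 eps: float = 1e-8):
        self.params = list(params)
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]
        self.t = 0

    def step(self, grads):
        self.t += 1
        b1, b2 = self.b1, self.b2
        c1 = 1.0 / (1 - b1**self.t)
        c2 = 1.0 / (1 - b2**self.t)
        for i, (p, g) in enumerate(zip(self.params, grads)):
            gd = g.data if isinstance(g, Tensor) else g
            m, v = self.m[i], self.v[i]
            m *= b1
            m += (1 - b1) * gd
            v *= b2
            v += (1 - b2) * (gd * gd)
            denom = np.sqrt(v * c2)
            denom += self.eps
            p.data -= self.lr * c1 * m / denom
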