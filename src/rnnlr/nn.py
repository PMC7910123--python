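"""Shared neural-network building blocks: parameter init, Adam, losses.

Everything operates on :class:`rnnlr._autodiff.Tensor` graphs; parameters are
plain Tensors with ``requires_grad=True`` collected into dicts so they can be
serialised to NPZ checkpoints.
"""

from __future__ import annotations

import math

import numpy as np

from ._autodiff import Tensor

__all__ = ["glorot", "Adam", "softmax_probs", "logsumexp_rows", "dropout_mask"]


def glorot(rng: np.random.Generator, fan_in: int, fan_out: int) -> Tensor:
    """Glorot/Xavier-uniform weight matrix as a trainable Tensor."""
    limit = math.sqrt(6.0 / (fan_in + fan_out))
    return Tensor(rng.uniform(-limit, limit, size=(fan_in, fan_out)), requires_grad=True)


def logsumexp_rows(logits: Tensor) -> Tensor:
    """Row-wise log-sum-exp, numerically stabilised with a detached max."""
    m = Tensor(logits.data.max(axis=1, keepdims=True))  # constant shift
    return (logits - m).exp().sum(axis=1, keepdims=True).log() + m


def softmax_probs(logits: Tensor) -> Tensor:
    """Row-stochastic softmax as a differentiable composition."""
    return (logits - logsumexp_rows(logits)).exp()


def dropout_mask(rng: np.random.Generator, shape, rate: float) -> np.ndarray:
    """Inverted-dropout multiplier: 0 with prob ``rate``, else 1/(1-rate)."""
    if rate <= 0.0:
        return np.ones(shape)
    keep = rng.random(shape) >= rate
    return keep / (1.0 - rate)


class Adam:
    """Adam with optional coupled L2 weight decay and per-step learning rate.

    ``weight_decay`` is added to the raw gradient before the moment updates,
    matching the conventional (non-decoupled) formulation.
    """

    def __init__(self, params: list[Tensor], lr: float = 1e-3,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8,
                 weight_decay: float = 0.0):
        self.params = params
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.weight_decay = weight_decay
        self.t = 0
        self._m = [np.zeros_like(p.data) for p in params]
        self._v = [np.zeros_like(p.data) for p in params]

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None

    def step(self, lr: float | None = None) -> None:
        lr = self.lr if lr is None else lr
        self.t += 1
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            if self.weight_decay:
                g = g + self.weight_decay * p.data
            self._m[i] = self.b1 * self._m[i] + (1 - self.b1) * g
            self._v[i] = self.b2 * self._v[i] + (1 - self.b2) * g * g
            mhat = self._m[i] / (1 - self.b1 ** self.t)
            vhat = self._v[i] / (1 - self.b2 ** self.t)
            p.data -= lr * mhat / (np.sqrt(vhat) + self.eps)
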