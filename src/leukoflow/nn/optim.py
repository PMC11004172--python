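"""Optimizers: Adam, RAdam, and Lookahead; Ranger = Lookahead(RAdam).

Ranger is the published composition of RAdam (variance-rectified Adam warmup)
with Lookahead (slow weights updated toward the fast weights every ``k``
steps). Parameters are referenced as (layer, name) pairs so freshly assigned
gradient arrays are always picked up.
"""

from __future__ import annotations

import numpy as np

from ..errors import ConfigError
from .layers import Layer, iter_layers


def trainable_parameters(net: Layer) -> list[tuple[Layer, str]]:
    return [
        (layer, name) for layer in iter_layers(net) for name in sorted(layer.params)
    ]


class Adam:
    def __init__(
        self,
        params: list[tuple[Layer, str]],
        lr: float = 1e-3,
        betas: tuple[float, float] = (0.9, 0.999),
        eps: float = 1e-8,
        weight_decay: float = 0.0,
    ):
        self.params = params
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.weight_decay = weight_decay
        self.t = 0
        self.m = [np.zeros_like(layer.params[n]) for layer, n in params]
        self.v = [np.zeros_like(layer.params[n]) for layer, n in params]

    def _moments(self, i, g):
        self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
        self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
        m_hat = self.m[i] / (1 - self.b1**self.t)
        v_hat = self.v[i] / (1 - self.b2**self.t)
        return m_hat, v_hat

    def step(self) -> None:
        self.t += 1
        for i, (layer, name) in enumerate(self.params):
            g = layer.grads.get(name)
            if g is None:
                continue
            if self.weight_decay:
                g = g + self.weight_decay * layer.params[name]
            m_hat, v_hat = self._moments(i, g)
            layer.params[name] -= self.lr * m_hat / (np.sqrt(v_hat) + self.eps)


class RAdam(Adam):
    """Rectified Adam: switches to unadapted SGD-with-momentum while the
    variance estimate is untrustworthy (few steps), then rectifies it."""

    def step(self) -> None:
        self.t += 1
        t = self.t
        rho_inf = 2.0 / (1.0 - self.b2) - 1.0
        rho_t = rho_inf - 2.0 * t * self.b2**t / (1.0 - self.b2**t)
        if rho_t > 4.0:
            r_t = np.sqrt(
                ((rho_t - 4.0) * (rho_t - 2.0) * rho_inf)
                / ((rho_inf - 4.0) * (rho_inf - 2.0) * rho_t)
            )
        else:
            r_t = None
        for i, (layer, name) in enumerate(self.params):
            g = layer.grads.get(name)
            if g is None:
                continue
            if self.weight_decay:
                g = g + self.weight_decay * layer.params[name]
            m_hat, v_hat = self._moments(i, g)
            if r_t is not None:
                layer.params[name] -= (
                    self.lr * r_t * m_hat / (np.sqrt(v_hat) + self.eps)
                )
            else:
                layer.params[name] -= self.lr * m_hat


class Lookahead:
    """Slow/fast weight wrapper: every k inner steps, slow += alpha (fast - slow)."""

    def __init__(self, inner: Adam, k: int = 6, alpha: float = 0.5):
        self.inner = inner
        self.k = k
        self.alpha = alpha
        self._step = 0
        self.slow = [layer.params[n].copy() for layer, n in inner.params]

    def step(self) -> None:
        self.inner.step()
        self._step += 1
        if self._step % self.k == 0:
            for i, (layer, name) in enumerate(self.inner.params):
                self.slow[i] += self.alpha * (layer.params[name] - self.slow[i])
                layer.params[name][...] = self.slow[i]


def make_optimizer(name: str, params: list[tuple[Layer, str]], lr: float):
    """Build an optimizer by name: 'ranger' (default) or 'adam-fallback'."""
    if name == "ranger":
        return Lookahead(RAdam(params, lr=lr), k=6, alpha=0.5)
    if name in ("adam", "adam-fallback"):
        return Adam(params, lr=lr)
    raise ConfigError(f"unknown optimizer {name!r}")
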