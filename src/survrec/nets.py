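"""Minimal feed-forward network substrate with hand-written backprop.

Two activation families are supported, matching the two network styles
used by the risk models:

* ``rectified`` — ReLU with He-normal initialization and standard
  (inverted) dropout;
* ``self_normalizing`` — SELU with LeCun-normal initialization and alpha
  dropout, the combination whose fixed point keeps layer activations near
  zero mean and unit variance on standardized inputs.

Training uses Adam.  Everything is seeded and CPU-only; at the cohort
sizes this package targets, dense numpy forward/backward passes are more
than fast enough.
"""

from __future__ import annotations

import numpy as np

__all__ = ["MLP", "Adam", "SELU_SCALE", "SELU_ALPHA"]

SELU_SCALE = 1.0507009873554805
SELU_ALPHA = 1.6732632423543772


class MLP:
    """Fully-connected net: ``dims = [in, h1, ..., out]``.  The final layer
    is linear (no activation, no dropout)."""

    def __init__(self, dims, activation: str = "rectified",
                 dropout: float = 0.0, rng: np.random.Generator | None = None):
        if activation not in ("rectified", "self_normalizing"):
            raise ValueError(f"unknown activation family {activation!r}")
        if rng is None:
            rng = np.random.default_rng(0)
        self.dims = list(dims)
        self.activation = activation
        self.dropout = float(dropout)
        self.W, self.b = [], []
        for fan_in, fan_out in zip(dims[:-1], dims[1:]):
            if activation == "self_normalizing":
                std = np.sqrt(1.0 / fan_in)          # LeCun normal
            else:
                std = np.sqrt(2.0 / fan_in)          # He normal
            self.W.append(rng.normal(0.0, std, (fan_in, fan_out)))
            self.b.append(np.zeros(fan_out))

    # -- parameter plumbing -------------------------------------------------
    @property
    def params(self) -> list[np.ndarray]:
        return self.W + self.b

    def set_params(self, params: list[np.ndarray]) -> None:
        k = len(self.W)
        self.W = [p.copy() for p in params[:k]]
        self.b = [p.copy() for p in params[k:]]

    # -- forward / backward -------------------------------------------------
    def _act(self, z: np.ndarray) -> np.ndarray:
        if self.activation == "rectified":
            return np.maximum(z, 0.0)
        return SELU_SCALE * np.where(z > 0, z, SELU_ALPHA * (np.exp(z) - 1.0))

    def _act_grad(self, z: np.ndarray) -> np.ndarray:
        if self.activation == "rectified":
            return (z > 0).astype(float)
        return SELU_SCALE * np.where(z > 0, 1.0, SELU_ALPHA * np.exp(z))

    def forward(self, X: np.ndarray, train: bool = False,
                rng: np.random.Generator | None = None,
                return_hidden: bool = False):
        """Forward pass.  In training mode dropout is applied after each
        hidden activation (alpha dropout for the self-normalizing family).
        Returns the output, and stores caches for :meth:`backward`."""
        h = np.asarray(X, float)
        caches = []
        hidden = []
        n_layers = len(self.W)
        for i, (W, b) in enumerate(zip(self.W, self.b)):
            z = h @ W + b
            if i == n_layers - 1:
                caches.append({"input": h, "z": z, "linear": True})
                h = z
                break
            a = self._act(z)
            cache = {"input": h, "z": z, "linear": False}
            if train and self.dropout > 0:
                p = self.dropout
                keep = rng.random(a.shape) >= p
                if self.activation == "self_normalizing":
                    # alpha dropout: dropped units are set to the SELU
                    # negative saturation value, then affinely corrected so
                    # mean/variance are preserved
                    ap = -SELU_SCALE * SELU_ALPHA
                    q = 1.0 - p
                    corr_a = (q + ap * ap * q * p) ** -0.5
                    corr_b = -corr_a * p * ap
                    a = np.where(keep, a, ap)
                    a = corr_a * a + corr_b
                    cache["drop"] = (keep, corr_a)
                else:
                    a = np.where(keep, a / (1.0 - p), 0.0)
                    cache["drop"] = (keep, 1.0 / (1.0 - p))
            caches.append(cache)
            hidden.append(a)
            h = a
        self._caches = caches
        if return_hidden:
            return h, hidden
        return h

    def backward(self, grad_out: np.ndarray):
        """Backprop ``grad_out`` (d loss / d output) through the cached
        forward pass.  Returns ``(grads, grad_input)`` with ``grads``
        ordered like :attr:`params`."""
        gW = [None] * len(self.W)
        gb = [None] * len(self.b)
        g = np.asarray(grad_out, float)
        for i in range(len(self.W) - 1, -1, -1):
            cache = self._caches[i]
            if not cache["linear"]:
                if "drop" in cache:
                    keep, scale = cache["drop"]
                    g = np.where(keep, g * scale, 0.0) \
                        if self.activation != "self_normalizing" \
                        else g * scale * keep
                g = g * self._act_grad(cache["z"])
            gW[i] = cache["input"].T @ g
            gb[i] = g.sum(axis=0)
            g = g @ self.W[i].T
        return gW + gb, g


class Adam:
    """Plain Adam over a list of parameter arrays."""

    def __init__(self, params: list[np.ndarray], lr: float = 1e-3,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self, params: list[np.ndarray], grads: list[np.ndarray]) -> None:
        self.t += 1
        lr_t = self.lr * np.sqrt(1 - self.b2 ** self.t) / (1 - self.b1 ** self.t)
        for p, g, m, v in zip(params, grads, self.m, self.v):
            m *= self.b1
            m += (1 - self.b1) * g
            v *= self.b2
            v += (1 - self.b2) * g * g
            p -= lr_t * m / (np.sqrt(v) + self.eps)
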