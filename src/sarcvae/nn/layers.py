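"""Dense layers, Gaussian-mixture densities, and the Adam optimizer."""

from __future__ import annotations

import math

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor

LOG2PI = math.log(2.0 * math.pi)
#: symmetric bound on predicted log-variances (see autodiff.bounded)
LOGVAR_LIMIT = 8.0


class Dense:
    """Affine layer with He-scaled Gaussian initialization."""

    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator):
        self.w = Tensor(rng.normal(0.0, math.sqrt(2.0 / n_in), (n_in, n_out)))
        self.b = Tensor(np.zeros(n_out))

    def __call__(self, x: Tensor) -> Tensor:
        return ad.add(ad.matmul(x, self.w), self.b)

    @property
    def params(self) -> list[Tensor]:
        return [self.w, self.b]


class MLP:
    """Stack of Dense layers with ReLU between (linear final layer)."""

    def __init__(self, sizes: list[int], rng: np.random.Generator):
        self.layers = [Dense(a, b, rng) for a, b in zip(sizes[:-1], sizes[1:])]

    def __call__(self, x: Tensor) -> Tensor:
        for i, layer in enumerate(self.layers):
            x = layer(x)
            if i < len(self.layers) - 1:
                x = ad.relu(x)
        return x

    @property
    def params(self) -> list[Tensor]:
        return [p for l in self.layers for p in l.params]


# ---------------------------------------------------------------------------
# densities

def gaussian_logpdf(x: Tensor, mu: Tensor, logvar: Tensor) -> Tensor:
    """Diagonal Gaussian log-density, summed over the last axis."""
    d = ad.add(x, ad.mul(mu, -1.0))
    q = ad.add(ad.mul(ad.mul(ad.square(d), ad.exp(ad.mul(logvar, -1.0))), 1.0),
               logvar)
    return ad.mul(ad.add(ad.sum(q, axis=-1), x.shape[-1] * LOG2PI), -0.5)


def gmm_logpdf(x: Tensor, mu: Tensor, logvar: Tensor, logw: Tensor) -> Tensor:
    """Gaussian-mixture log-density.

    ``x``: (B, d); ``mu``/``logvar``: (B, m, d); ``logw``: (B, m)
    un-normalized log-weights (log-softmax applied internally).
    Returns (B,).
    """
    logw_n = ad.add(logw, ad.mul(ad.logsumexp(logw, axis=-1, keepdims=True), -1.0))
    xb = ad.reshape(x, (x.shape[0], 1, x.shape[-1]))
    d = ad.add(xb, ad.mul(mu, -1.0))
    comp = ad.mul(ad.add(ad.sum(ad.add(ad.mul(ad.square(d),
                                              ad.exp(ad.mul(logvar, -1.0))),
                                       logvar), axis=-1),
                         x.shape[-1] * LOG2PI), -0.5)
    return ad.logsumexp(ad.add(logw_n, comp), axis=-1)


def gmm_logpdf_np(x: np.ndarray, mu: np.ndarray, logvar: np.ndarray,
                  logw: np.ndarray) -> np.ndarray:
    """Numpy-only mixture log-density (inference path, no graph)."""
    logw_n = logw - _np_logsumexp(logw, axis=-1, keepdims=True)
    d = x[..., None, :] - mu
    comp = -0.5 * ((d * d * np.exp(-logvar) + logvar).sum(axis=-1)
                   + x.shape[-1] * LOG2PI)
    return _np_logsumexp(logw_n + comp, axis=-1)


def _np_logsumexp(a, axis=-1, keepdims=False):
    m = np.max(a, axis=axis, keepdims=True)
    out = m + np.log(np.exp(a - m).sum(axis=axis, keepdims=True))
    return out if keepdims else np.squeeze(out, axis=axis)


def sample_gmm(mu: np.ndarray, logvar: np.ndarray, logw: np.ndarray,
               rng: np.random.Generator) -> np.ndarray:
    """One draw per batch row from a diagonal-covariance mixture."""
    b, m, d = mu.shape
    w = np.exp(logw - _np_logsumexp(logw, axis=-1, keepdims=True))
    cum = np.cumsum(w, axis=-1)
    k = (rng.random((b, 1)) < cum).argmax(axis=-1)
    rows = np.arange(b)
    return mu[rows, k] + rng.standard_normal((b, d)) * np.exp(
        0.5 * logvar[rows, k])


# ---------------------------------------------------------------------------
# optimizer

class Adam:
    """Adaptive-moment gradient descent."""

    def __init__(self, params: list[Tensor], lr: float = 1e-3,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.params = params
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p.value) for p in params]
        self.v = [np.zeros_like(p.value) for p in params]
        self.t = 0

    def step(self) -> None:
        self.t += 1
        for i, p in enumerate(self.params):
            g = p.grad
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            mhat = self.m[i] / (1 - self.b1 ** self.t)
            vhat = self.v[i] / (1 - self.b2 ** self.t)
            p.value -= self.lr * mhat / (np.sqrt(vhat) + self.eps)

    def state_dict(self) -> dict:
        return {"m": [m.copy() for m in self.m],
                "v": [v.copy() for v in self.v], "t": self.t}

    def load_state_dict(self, state: dict) -> None:
        self.m = [m.copy() for m in state["m"]]
        self.v = [v.copy() for v in state["v"]]
        self.t = state["t"]
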