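"""Conditional variational autoencoder for amortized posterior inference.

Three sub-networks share one fully connected feature trunk over the
(average-pooled, standardized) twitch trace:

* ``Q1`` — recognition encoder: trace features + true (scaled) rate factors
  -> unimodal diagonal Gaussian over the latent z (training only);
* ``R1`` — prior encoder: trace features -> m-component Gaussian mixture
  over z (used at inference);
* ``R2`` — decoder: trace features + z -> m-component Gaussian mixture over
  the rate-factor space.

The training loss is ``-L + alpha * KL`` where ``L`` is the R2 log-density
at the true factors, ``KL`` the single-sample Monte-Carlo estimate of
``KL(Q1 || R1)`` at the reparameterized draw, and ``alpha`` follows the
annealing schedule (0 for the first ``flat_epochs``, then a linear ramp to
1 over ``ramp_epochs``) that protects against posterior collapse.
Ancestral sampling (R1 -> z -> R2 -> r), repeated n times, yields the
posterior over rate factors conditioned on a target twitch.

The estimator follows scikit-learn conventions (``get_params``/
``set_params``, fitted attributes with trailing underscores).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
from sklearn.base import BaseEstimator

from .nn import autodiff as ad
from .nn.autodiff import Tensor, bounded
from .nn.layers import (LOGVAR_LIMIT, MLP, Adam, gaussian_logpdf, gmm_logpdf,
                        gmm_logpdf_np, sample_gmm, _np_logsumexp)


def kl_weight(epoch: int, flat_epochs: int = 30, ramp_epochs: int = 60) -> float:
    """Annealing weight alpha(epoch): 0, then a linear ramp to 1."""
    if epoch < flat_epochs:
        return 0.0
    if epoch < flat_epochs + ramp_epochs:
        return (epoch - flat_epochs) / ramp_epochs
    return 1.0


@dataclass
class PosteriorSampleSet:
    """Draws from the amortized posterior over rate factors."""

    samples: np.ndarray                   # (n, n_factors) log10 scale
    names: tuple[str, ...]
    target_id: str = ""
    model_hash: str = ""
    prior_bounds: tuple[float, float] = (-1.0, 2.0)

    def __post_init__(self):
        self.samples = np.asarray(self.samples, dtype=float)
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("posterior samples must be finite")

    @property
    def n(self) -> int:
        return self.samples.shape[0]

    def multipliers(self) -> np.ndarray:
        return 10.0 ** self.samples

    def outside_prior_fraction(self) -> float:
        """Diagnostic: mass outside the prior box (kept, not clipped)."""
        lo, hi = self.prior_bounds
        out = (self.samples < lo) | (self.samples > hi)
        return float(out.any(axis=1).mean())

    def marginal_cdf_at(self, truth: np.ndarray) -> np.ndarray:
        """Per-dimension fraction of samples strictly below the truth."""
        truth = np.asarray(truth, dtype=float)
        return (self.samples < truth[None, :]).mean(axis=0)


class CVAEPosterior(BaseEstimator):
    """Mixture-density CVAE over rate factors conditioned on a twitch.

    Parameters
    ----------
    n_factors : output dimensionality (9 for the full factor set).
    latent_dim, n_components : latent size nz and mixture components m.
    pool : average-pooling width applied to the input trace.
    hidden, head_hidden : trunk and head layer widths.
    flat_epochs, ramp_epochs : KL annealing schedule.
    epochs : maximum training epochs (early stopping after the ramp via
        ``patience`` epochs without validation improvement).
    """

    def __init__(self, n_factors: int = 9, latent_dim: int = 8,
                 n_components: int = 16, pool: int = 10, hidden: int = 128,
                 head_hidden: int = 64, batch_size: int = 256,
                 lr: float = 1e-3, epochs: int = 200, flat_epochs: int = 30,
                 ramp_epochs: int = 60, patience: int = 20,
                 random_state: int = 0):
        self.n_factors = n_factors
        self.latent_dim = latent_dim
        self.n_components = n_components
        self.pool = pool
        self.hidden = hidden
        self.head_hidden = head_hidden
        self.batch_size = batch_size
        self.lr = lr
        self.epochs = epochs
        self.flat_epochs = flat_epochs
        self.ramp_epochs = ramp_epochs
        self.patience = patience
        self.random_state = random_state

    # -- construction ------------------------------------------------------
    def _build(self, n_inputs: int) -> None:
        rng = np.random.default_rng(self.random_state)
        nz, m, nr = self.latent_dim, self.n_components, self.n_factors
        self.n_inputs_ = n_inputs
        n_feat = n_inputs // self.pool
        self.trunk_ = MLP([n_feat, self.hidden, self.hidden], rng)
        self.q1_ = MLP([self.hidden + nr, self.head_hidden, 2 * nz], rng)
        self.r1_ = MLP([self.hidden, self.head_hidden, m * (2 * nz) + m], rng)
        self.r2_ = MLP([self.hidden + nz, self.head_hidden, self.head_hidden,
                        m * (2 * nr) + m], rng)
        self.params_ = (self.trunk_.params + self.q1_.params
                        + self.r1_.params + self.r2_.params)
        self.opt_ = Adam(self.params_, lr=self.lr)
        self.rng_ = rng
        self.epoch_ = 0
        self.loss_history_ = []
        self.val_history_ = []
        self._best_val = np.inf
        self._stall = 0

    # -- pieces ------------------------------------------------------------
    def _pool(self, x: np.ndarray) -> np.ndarray:
        x = np.atleast_2d(np.asarray(x, dtype=float))
        n = (x.shape[1] // self.pool) * self.pool
        return x[:, :n].reshape(x.shape[0], -1, self.pool).mean(axis=2)

    def _features(self, x: np.ndarray) -> Tensor:
        return ad.relu(self.trunk_(Tensor(self._pool(x), requires_grad=False)))

    def _split_gmm(self, out: Tensor, d: int):
        m = self.n_components
        b = out.shape[0]
        mu = ad.reshape(out[:, :m * d], (b, m, d))
        lv = bounded(ad.reshape(out[:, m * d:2 * m * d], (b, m, d)),
                     LOGVAR_LIMIT)
        logw = out[:, 2 * m * d:]
        return mu, lv, logw

    # -- encoder/decoder surfaces --------------------------------------------
    def encode_q1(self, trace: np.ndarray, factors_scaled: np.ndarray):
        """Unimodal Gaussian (mu, logvar) over z given trace + true factors."""
        self._warn_unstandardized(trace)
        h = self._features(trace)
        out = self.q1_(ad.concat([h, Tensor(np.atleast_2d(factors_scaled),
                                            requires_grad=False)], axis=1))
        nz = self.latent_dim
        mu = out.value[:, :nz]
        lv = LOGVAR_LIMIT * np.tanh(out.value[:, nz:] / LOGVAR_LIMIT)
        return mu.squeeze(0), lv.squeeze(0)

    def encode_r1(self, trace: np.ndarray):
        """Latent mixture (mu, logvar, logw) given the trace alone."""
        self._warn_unstandardized(trace)
        h = self._features(trace)
        mu, lv, logw = self._split_gmm(self.r1_(h), self.latent_dim)
        logw_n = logw.value - _np_logsumexp(logw.value, axis=-1, keepdims=True)
        return mu.value.squeeze(0), lv.value.squeeze(0), logw_n.squeeze(0)

    def decode_r2(self, trace: np.ndarray, z: np.ndarray):
        """Factor-space mixture (mu, logvar, logw) given trace + latent z."""
        z = np.atleast_2d(z)
        if z.shape[-1] != self.latent_dim:
            raise ValueError("latent dimension mismatch")
        h = self._features(trace)
        if h.shape[0] == 1 and z.shape[0] > 1:
            h = Tensor(np.repeat(h.value, z.shape[0], axis=0),
                       requires_grad=False)
        out = self.r2_(ad.concat([h, Tensor(z, requires_grad=False)], axis=1))
        mu, lv, logw = self._split_gmm(out, self.n_factors)
        logw_n = logw.value - _np_logsumexp(logw.value, axis=-1, keepdims=True)
        return mu.value.squeeze(), lv.value.squeeze(), logw_n.squeeze()

    @staticmethod
    def _warn_unstandardized(trace: np.ndarray) -> None:
        import warnings
        t = np.asarray(trace, dtype=float)
        if np.abs(t).max(initial=0.0) > 25.0:
            warnings.warn("input trace looks unstandardized; apply the "
                          "training statistics first", stacklevel=3)

    # -- loss ---------------------------------------------------------------
    def loss(self, x: np.ndarray, y: np.ndarray, epoch: int | None = None,
             eps: np.ndarray | None = None) -> Tensor:
        """Batch loss ``mean(-L + alpha(epoch) * KL)`` (training mode:
        z is drawn from Q1 by reparameterization)."""
        x = np.atleast_2d(x)
        y = np.atleast_2d(y)
        alpha = kl_weight(self.epoch_ if epoch is None else epoch,
                          self.flat_epochs, self.ramp_epochs)
        nz = self.latent_dim
        h = self._features(x)
        yt = Tensor(y, requires_grad=False)
        q1 = self.q1_(ad.concat([h, yt], axis=1))
        mu_q = q1[:, :nz]
        lv_q = bounded(q1[:, nz:], LOGVAR_LIMIT)
        if eps is None:
            eps = self.rng_.standard_normal((x.shape[0], nz))
        z = ad.add(mu_q, ad.mul(ad.exp(ad.mul(lv_q, 0.5)),
                                Tensor(eps, requires_grad=False)))
        mu1, lv1, lw1 = self._split_gmm(self.r1_(h), nz)
        mu2, lv2, lw2 = self._split_gmm(
            self.r2_(ad.concat([h, z], axis=1)), self.n_factors)
        log_l = gmm_logpdf(yt, mu2, lv2, lw2)
        log_q = gaussian_logpdf(z, mu_q, lv_q)
        log_r1 = gmm_logpdf(z, mu1, lv1, lw1)
        kl_mc = ad.add(log_q, ad.mul(log_r1, -1.0))
        per = ad.add(ad.mul(log_l, -1.0), ad.mul(kl_mc, alpha))
        val = ad.mean(per)
        if not np.isfinite(val.value):
            raise FloatingPointError("non-finite CVAE loss")
        return val

    # -- training ------------------------------------------------------------
    def fit(self, X: np.ndarray, y: np.ndarray,
            X_val: np.ndarray | None = None,
            y_val: np.ndarray | None = None,
            verbose: bool = False) -> "CVAEPosterior":
        """Train on standardized traces ``X`` and unit-box factors ``y``."""
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float)
        if y.shape[1] != self.n_factors:
            raise ValueError("y has wrong number of factors")
        self._build(X.shape[1])
        return self.fit_epochs(X, y, self.epochs, X_val, y_val, verbose)

    def fit_epochs(self, X, y, n_epochs, X_val=None, y_val=None,
                   verbose=False) -> "CVAEPosterior":
        """Continue training for up to ``n_epochs`` more epochs."""
        n = X.shape[0]
        for _ in range(n_epochs):
            order = self.rng_.permutation(n)
            ep_loss = 0.0
            for lo in range(0, n, self.batch_size):
                idx = order[lo:lo + self.batch_size]
                loss = self.loss(X[idx], y[idx])
                for p in self.params_:
                    p.grad = None
                loss.backward()
                self.opt_.step()
                ep_loss += float(loss.value) * idx.size
            self.loss_history_.append(ep_loss / n)
            if X_val is not None:
                vl = float(self.loss(X_val, y_val,
                                     eps=np.zeros((X_val.shape[0],
                                                   self.latent_dim))).value)
                self.val_history_.append(vl)
            if verbose:
                print(f"epoch {self.epoch_}: train {self.loss_history_[-1]:.4f}"
                      + (f" val {self.val_history_[-1]:.4f}" if X_val is not None
                         else ""))
            self.epoch_ += 1
            # early stopping only once the KL ramp is complete
            if (X_val is not None
                    and self.epoch_ > self.flat_epochs + self.ramp_epochs):
                if self.val_history_[-1] < self._best_val - 1e-4:
                    self._best_val = self.val_history_[-1]
                    self._stall = 0
                else:
                    self._stall += 1
                    if self._stall >= self.patience:
                        break
        return self

    # -- inference -----------------------------------------------------------
    def sample_posterior(self, trace: np.ndarray, n: int = 5000,
                         seed: int | tuple | None = None) -> np.ndarray:
        """Ancestral draws (R1 -> z -> R2 -> r), shape (n, n_factors).

        Returns factors on the network's own (unit-box) scale; use the
        dataset's ``unscale_factors`` for log10 multipliers.  R1 conditions
        on the target twitch; Q1 is never used at inference.
        """
        rng = np.random.default_rng(np.random.SeedSequence(seed))
        trace = np.asarray(trace, dtype=float).reshape(1, -1)
        if trace.shape[1] != self.n_inputs_:
            raise ValueError("trace length does not match the trained model")
        h = self._features(trace).value
        mu1, lv1, lw1 = (v for v in self._split_r1_np(h))
        z = sample_gmm(np.repeat(mu1, n, axis=0), np.repeat(lv1, n, axis=0),
                       np.repeat(lw1, n, axis=0), rng)
        hrep = np.repeat(h, n, axis=0)
        out = self._np_mlp(self.r2_, np.concatenate([hrep, z], axis=1))
        mu2, lv2, lw2 = self._split_gmm_np(out, self.n_factors)
        return sample_gmm(mu2, lv2, lw2, rng)

    def predict(self, X: np.ndarray, n: int = 500,
                seed: int | tuple | None = 0) -> np.ndarray:
        """Posterior-mean factors (scaled) per trace — sklearn-style."""
        X = np.atleast_2d(np.asarray(X, dtype=float))
        return np.stack([self.sample_posterior(x, n=n, seed=seed).mean(axis=0)
                         for x in X])

    # numpy-only forward passes for the hot inference path
    @staticmethod
    def _np_mlp(mlp: MLP, x: np.ndarray) -> np.ndarray:
        for i, layer in enumerate(mlp.layers):
            x = x @ layer.w.value + layer.b.value
            if i < len(mlp.layers) - 1:
                x = np.maximum(x, 0.0)
        return x

    def _split_r1_np(self, h: np.ndarray):
        out = self._np_mlp(self.r1_, h)
        return self._split_gmm_np(out, self.latent_dim)

    def _split_gmm_np(self, out: np.ndarray, d: int):
        m = self.n_components
        b = out.shape[0]
        mu = out[:, :m * d].reshape(b, m, d)
        lv = LOGVAR_LIMIT * np.tanh(out[:, m * d:2 * m * d].reshape(b, m, d)
                                    / LOGVAR_LIMIT)
        lw = out[:, 2 * m * d:]
        return mu, lv, lw

    # -- persistence -----------------------------------------------------------
    def save(self, path: str | Path, extra_meta: dict | None = None) -> None:
        """Self-describing checkpoint: ``<base>.npz`` (weights + optimizer
        moments) and ``<base>.json`` (config, histories, rng state)."""
        base = str(path).removesuffix(".npz")
        arrays = {f"p{i}": p.value for i, p in enumerate(self.params_)}
        for i, (m, v) in enumerate(zip(self.opt_.m, self.opt_.v)):
            arrays[f"m{i}"] = m
            arrays[f"v{i}"] = v
        meta = {"params": self.get_params(), "n_inputs": self.n_inputs_,
                "epoch": self.epoch_, "opt_t": self.opt_.t,
                "loss_history": self.loss_history_,
                "val_history": self.val_history_,
                "best_val": self._best_val, "stall": self._stall,
                "rng_state": self.rng_.bit_generator.state,
                "extra": extra_meta or {}}
        np.savez(base + ".npz", **arrays)
        Path(base + ".json").write_text(json.dumps(meta))

    @classmethod
    def load(cls, path: str | Path) -> "CVAEPosterior":
        base = str(path).removesuffix(".npz")
        meta = json.loads(Path(base + ".json").read_text())
        est = cls(**meta["params"])
        est._build(meta["n_inputs"])
        data = np.load(base + ".npz")
        for i, p in enumerate(est.params_):
            p.value = data[f"p{i}"]
            est.opt_.m[i] = data[f"m{i}"]
            est.opt_.v[i] = data[f"v{i}"]
        est.opt_.t = meta["opt_t"]
        est.epoch_ = meta["epoch"]
        est.loss_history_ = list(meta["loss_history"])
        est.val_history_ = list(meta["val_history"])
        est._best_val = float(meta["best_val"])
        est._stall = int(meta["stall"])
        est.rng_.bit_generator.state = meta["rng_state"]
        return est
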