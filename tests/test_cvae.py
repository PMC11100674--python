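"""CVAE architecture, annealed loss, training and posterior sampling.

Functional tests run on a fast analytic toy problem (2 parameters mapped to
a noisy exponential decay); the full simulator-in-the-loop recovery study
lives in the acceptance suite.
"""

import numpy as np
import pytest

from sarcvae.cvae import CVAEPosterior, PosteriorSampleSet, kl_weight
from sarcvae.nn.layers import gmm_logpdf_np


def toy_problem(n=1200, seed=1):
    rng = np.random.default_rng(seed)
    y = rng.uniform(0, 1, (n, 2))
    t = np.linspace(0, 1, 100)
    x = y[:, 0:1] * np.exp(-t[None, :] / (0.1 + 0.6 * y[:, 1:2]))
    x = x + 0.03 * rng.standard_normal((n, 100))
    x = (x - x.mean()) / x.std()
    return x, y


@pytest.fixture(scope="module")
def toy_model():
    x, y = toy_problem()
    est = CVAEPosterior(n_factors=2, latent_dim=4, n_components=8, pool=2,
                        hidden=48, head_hidden=32, epochs=80, batch_size=256,
                        lr=1e-3, random_state=0)
    est.fit(x[:1000], y[:1000], x[1000:], y[1000:])
    return est, x, y


class TestAnnealingSchedule:
    @pytest.mark.parametrize("epoch,alpha", [
        (0, 0.0), (29, 0.0), (30, 0.0), (60, 0.5), (89, 59 / 60),
        (90, 1.0), (500, 1.0)])
    def test_printed_schedule(self, epoch, alpha):
        assert kl_weight(epoch, 30, 60) == pytest.approx(alpha)


class TestArchitecture:
    def test_encoder_decoder_shapes_at_initialization(self, toy_model):
        est, x, y = toy_model
        mu, lv = est.encode_q1(x[0], y[0])
        assert mu.shape == (4,) and lv.shape == (4,)
        assert np.all(np.isfinite(mu)) and np.all(np.isfinite(lv))
        mu1, lv1, lw1 = est.encode_r1(x[0])
        assert mu1.shape == (8, 4) and lv1.shape == (8, 4) and lw1.shape == (8,)
        assert np.exp(lw1).sum() == pytest.approx(1.0)
        mu2, lv2, lw2 = est.decode_r2(x[0], np.zeros(4))
        assert mu2.shape == (8, 2) and lw2.shape == (8,)
        assert np.exp(lw2).sum() == pytest.approx(1.0)

    def test_latent_dimension_mismatch_rejected(self, toy_model):
        est, x, _ = toy_model
        with pytest.raises(ValueError):
            est.decode_r2(x[0], np.zeros(7))

    def test_unstandardized_input_warns(self, toy_model):
        est, x, _ = toy_model
        with pytest.warns(UserWarning, match="unstandardized"):
            est.encode_r1(1e3 * np.ones_like(x[0]))

    def test_r2_density_normalizes_on_grid(self, toy_model):
        """Grid quadrature of the 2-factor mixture integrates to ~1."""
        est, x, _ = toy_model
        mu2, lv2, lw2 = est.decode_r2(x[5], np.zeros(4))
        g = np.linspace(-6, 7, 400)
        xx, yy = np.meshgrid(g, g)
        pts = np.column_stack([xx.ravel(), yy.ravel()])
        logp = gmm_logpdf_np(pts, np.tile(mu2, (pts.shape[0], 1, 1)),
                             np.tile(lv2, (pts.shape[0], 1, 1)),
                             np.tile(lw2, (pts.shape[0], 1)))
        integral = np.exp(logp).sum() * (g[1] - g[0]) ** 2
        assert integral == pytest.approx(1.0, abs=0.02)

    def test_density_peaks_at_component_means(self, toy_model):
        est, x, _ = toy_model
        mu2, lv2, lw2 = est.decode_r2(x[5], np.zeros(4))
        for k in range(mu2.shape[0]):
            at_mean = gmm_logpdf_np(mu2[k][None, :], mu2[None], lv2[None],
                                    lw2[None])[0]
            away = mu2[k] + 5.0 * np.exp(0.5 * lv2[k])
            at_away = gmm_logpdf_np(away[None, :], mu2[None], lv2[None],
                                    lw2[None])[0]
            assert at_mean >= at_away


class TestLoss:
    def test_kl_estimate_nonnegative_in_expectation(self, toy_model):
        """Monte-Carlo KL(Q1 || R1) respects Gibbs' inequality."""
        est, x, y = toy_model
        from sarcvae.nn.layers import gaussian_logpdf
        rng = np.random.default_rng(0)
        mu, lv = est.encode_q1(x[0], y[0])
        mu1, lv1, lw1 = est.encode_r1(x[0])
        z = mu[None] + rng.standard_normal((4000, 4)) * np.exp(lv / 2)[None]
        log_q = (-0.5 * (((z - mu) ** 2) * np.exp(-lv) + lv
                         + np.log(2 * np.pi)).sum(axis=1))
        log_r = gmm_logpdf_np(z, np.tile(mu1, (z.shape[0], 1, 1)),
                              np.tile(lv1, (z.shape[0], 1, 1)),
                              np.tile(lw1, (z.shape[0], 1)))
        kl = np.mean(log_q - log_r)
        assert kl > -0.05

    def test_loss_finite_and_alpha_scaling(self, toy_model):
        est, x, y = toy_model
        eps = np.zeros((8, est.latent_dim))
        l0 = float(est.loss(x[:8], y[:8], epoch=0, eps=eps).value)
        l1 = float(est.loss(x[:8], y[:8], epoch=1000, eps=eps).value)
        assert np.isfinite(l0) and np.isfinite(l1)


class TestTraining:
    def test_validation_loss_decreases(self, toy_model):
        est, _, _ = toy_model
        assert est.val_history_[-1] < est.val_history_[0]

    def test_posterior_recovers_toy_truth(self, toy_model):
        est, x, y = toy_model
        hits = 0
        for i in range(1000, 1020):
            s = est.sample_posterior(x[i], n=400, seed=(1, i))
            lo, hi = np.percentile(s, [0.5, 99.5], axis=0)
            hits += np.all((y[i] >= lo) & (y[i] <= hi))
        assert hits >= 15  # truth inside the 99% box in >= 75% of cases

    def test_sampling_deterministic_given_seed(self, toy_model):
        est, x, _ = toy_model
        a = est.sample_posterior(x[3], n=100, seed=(42,))
        b = est.sample_posterior(x[3], n=100, seed=(42,))
        assert np.array_equal(a, b)

    def test_checkpoint_resume_matches_uninterrupted(self, tmp_path):
        x, y = toy_problem(n=600, seed=2)
        kw = dict(n_factors=2, latent_dim=3, n_components=4, pool=4,
                  hidden=24, head_hidden=16, batch_size=128, lr=1e-3,
                  random_state=7)
        full = CVAEPosterior(epochs=4, **kw)
        full.fit(x[:500], y[:500], x[500:], y[500:])

        half = CVAEPosterior(epochs=2, **kw)
        half.fit(x[:500], y[:500], x[500:], y[500:])
        half.save(tmp_path / "ckpt")
        resumed = CVAEPosterior.load(tmp_path / "ckpt")
        resumed.fit_epochs(x[:500], y[:500], 2, x[500:], y[500:])

        assert np.allclose(resumed.loss_history_, full.loss_history_,
                           atol=1e-6)
        for pa, pb in zip(resumed.params_, full.params_):
            assert np.allclose(pa.value, pb.value, atol=1e-6)


class TestPosteriorSampleSet:
    def test_outside_prior_flagged_not_clipped(self):
        s = PosteriorSampleSet(samples=np.array([[0.0, 0.5], [3.0, 0.5]]),
                               names=("a", "b"))
        assert s.outside_prior_fraction() == pytest.approx(0.5)
        assert s.samples[1, 0] == 3.0

    def test_nonfinite_samples_rejected(self):
        with pytest.raises(ValueError):
            PosteriorSampleSet(samples=np.array([[np.inf, 0.0]]),
                               names=("a", "b"))
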