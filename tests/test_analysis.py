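"""PP calibration, corner summaries, signed KS, hybrid/intervention logic."""

import numpy as np
import pytest

import sarcvae as sv
from sarcvae.analysis import (CornerSummary, corner_summary,
                              make_hybrid_factors, pp_curve_from_cdf,
                              signed_ks)
from sarcvae.cvae import PosteriorSampleSet
from sarcvae.kinetics import RateFactors


class _ConjugateModel:
    """Exactly calibrated synthetic posterior for theta ~ N(0,1),
    x = theta + noise: p(theta|x) = N(x/2, 1/2)."""

    def __init__(self, narrow=1.0):
        self.narrow = narrow

    def sample_posterior(self, x, n, seed):
        rng = np.random.default_rng(np.random.SeedSequence(seed))
        return (x[None, :] / 2.0
                + rng.standard_normal((n, x.size))
                * np.sqrt(0.5) * self.narrow)


def _simulate_cdf_values(narrow, n_records=400, seed=0):
    rng = np.random.default_rng(seed)
    model = _ConjugateModel(narrow)
    rows = []
    for i in range(n_records):
        theta = rng.standard_normal(2)
        x = theta + rng.standard_normal(2)
        s = model.sample_posterior(x, 800, (3, i))
        rows.append((s < theta[None, :]).mean(axis=0))
    return np.array(rows)


class TestPPCurve:
    def test_calibrated_posterior_within_kolmogorov_band(self):
        cdf = _simulate_cdf_values(narrow=1.0)
        pp = pp_curve_from_cdf(cdf, names=("a", "b"))
        # 99% two-sided Kolmogorov band for n=400
        band = 1.63 / np.sqrt(cdf.shape[0])
        assert np.all(pp.max_deviation() < band)

    def test_overconfident_posterior_under_covers(self):
        """Variance shrunk x0.1: central credible intervals under-cover."""
        cdf_narrow = _simulate_cdf_values(narrow=np.sqrt(0.1))
        cdf_good = _simulate_cdf_values(narrow=1.0)
        for level in (0.5, 0.8, 0.9):
            half = level / 2
            cov_n = np.mean(np.abs(cdf_narrow - 0.5) <= half, axis=0)
            cov_g = np.mean(np.abs(cdf_good - 0.5) <= half, axis=0)
            assert np.all(cov_n < level - 0.1)     # below the diagonal
            assert np.all(np.abs(cov_g - level) < 0.1)

    def test_curve_endpoints_and_monotonicity(self):
        pp = pp_curve_from_cdf(_simulate_cdf_values(1.0, 50), ("a", "b"))
        assert np.all(pp.coverage[0] == 0.0)
        assert np.all(pp.coverage[-1] == 1.0)
        assert np.all(np.diff(pp.coverage, axis=0) >= 0)

    def test_empty_validation_rejected(self):
        from sarcvae.analysis import pp_curve
        with pytest.raises(ValueError):
            pp_curve(_ConjugateModel(), np.empty((0, 3)), np.empty((0, 2)))


class TestCornerSummary:
    def make_samples(self, n=4000, seed=0):
        rng = np.random.default_rng(seed)
        mean = np.array([0.3, 1.1, -0.2])
        x = mean[None, :] + 0.25 * rng.standard_normal((n, 3))
        return PosteriorSampleSet(samples=x, names=("rt12", "rx34", "rx16")), mean

    def test_peak_near_gaussian_mean(self):
        samples, mean = self.make_samples()
        cs = corner_summary(samples)
        assert np.all(np.abs(cs.joint_peak - mean) < 0.1)
        assert np.all(np.abs(cs.marginal_modes - mean) < 0.1)

    def test_permutation_invariance(self):
        samples, _ = self.make_samples()
        rng = np.random.default_rng(9)
        shuffled = PosteriorSampleSet(
            samples=samples.samples[rng.permutation(samples.n)],
            names=samples.names)
        a = corner_summary(samples)
        b = corner_summary(shuffled)
        assert np.allclose(a.joint_peak, b.joint_peak)
        assert np.allclose(a.marginal_modes, b.marginal_modes)

    def test_degenerate_dimension_becomes_point_mass(self):
        rng = np.random.default_rng(1)
        x = np.column_stack([rng.standard_normal(2000),
                             np.full(2000, 0.7)])
        cs = corner_summary(PosteriorSampleSet(samples=x, names=("a", "b")))
        assert cs.marginal_modes[1] == pytest.approx(0.7)

    def test_axis_limits_default_to_prior_box(self):
        samples, _ = self.make_samples()
        cs = corner_summary(samples)
        assert cs.axis_limits == (-1.0, 2.0)

    def test_peak_factors_round_trip(self):
        samples, _ = self.make_samples()
        cs = corner_summary(samples)
        fac = cs.peak_factors()
        assert getattr(fac, "rt12") == pytest.approx(10 ** cs.joint_peak[0])
        assert fac.rt41 == 1.0  # untouched coordinate


class TestSignedKS:
    def test_identical_samples_zero(self):
        x = np.random.default_rng(0).standard_normal((100, 3))
        assert np.allclose(signed_ks(x, x), 0.0)

    def test_hand_built_example(self):
        # {1,2} vs {3,4}: sup|dCDF| = 1 at x=2 where the control CDF is
        # larger -> positive sign under the stated convention
        ks = signed_ks(np.array([[1.0], [2.0]]), np.array([[3.0], [4.0]]))
        assert ks[0] == pytest.approx(1.0)
        ks = signed_ks(np.array([[3.0], [4.0]]), np.array([[1.0], [2.0]]))
        assert ks[0] == pytest.approx(-1.0)

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(5)
        for _ in range(50):
            a = rng.standard_normal((37, 2))
            b = 0.3 + rng.standard_normal((29, 2))
            ks = signed_ks(a, b)
            for k in range(2):
                pts = np.concatenate([a[:, k], b[:, k]])
                diffs = [(np.mean(a[:, k] <= p) - np.mean(b[:, k] <= p))
                         for p in pts]
                i = int(np.argmax(np.abs(diffs)))
                assert ks[k] == pytest.approx(diffs[i], abs=1e-12)

    def test_magnitude_matches_scipy(self):
        from scipy.stats import ks_2samp
        rng = np.random.default_rng(8)
        a = rng.standard_normal((200, 1))
        b = rng.standard_normal((150, 1)) * 1.4
        assert abs(signed_ks(a, b)[0]) == pytest.approx(
            ks_2samp(a[:, 0], b[:, 0]).statistic, abs=1e-12)


class TestHybridFactors:
    def test_empty_swap_returns_control(self):
        c = RateFactors(rt12=2.0, rx34=0.5)
        v = RateFactors(rt12=0.2, rt41=4.0)
        assert make_hybrid_factors(c, v, ()) == c

    def test_full_swap_returns_variant(self):
        c = RateFactors(rt12=2.0)
        v = RateFactors(rt12=0.2, rx16=3.0)
        h = make_hybrid_factors(c, v, tuple(sv.FACTOR_NAMES))
        assert h == v

    def test_default_swap_is_calcium_affinity_pair(self):
        c = RateFactors(rt12=2.0, rt41=0.5, rx34=7.0)
        v = RateFactors(rt12=0.3, rt41=1.5, rx34=0.2)
        h = make_hybrid_factors(c, v)
        assert h.rt12 == v.rt12 and h.rt41 == v.rt41
        assert h.rx34 == c.rx34

    def test_unknown_name_rejected(self):
        with pytest.raises(KeyError):
            make_hybrid_factors(RateFactors(), RateFactors(), ("bogus",))


class TestInterventionInference:
    @pytest.fixture()
    def reduced_space_setup(self):
        """Tiny 2-thick-factor model + dataset with frozen thin factors."""
        from sarcvae.dataset import TrainingDataset, split, standardize
        rng = np.random.default_rng(0)
        hybrid = RateFactors(rt12=0.3, rt41=2.0)
        frozen = {n: getattr(hybrid, n) for n in sv.FACTOR_NAMES
                  if n not in ("rx34", "rx16")}
        ds = TrainingDataset(traces=rng.normal(2.0, 1.0, (60, 80)),
                             factors=rng.uniform(-1, 2, (60, 2)),
                             varied=("rx34", "rx16"), frozen=frozen)
        standardize(split(ds, 0.1, seed=0))
        from sarcvae.cvae import CVAEPosterior
        est = CVAEPosterior(n_factors=2, latent_dim=2, n_components=2,
                            pool=4, hidden=8, head_hidden=8, epochs=1,
                            batch_size=32, random_state=0)
        xt, yt = ds.training()
        est.fit(xt, ds.scale_factors(yt))
        return est, ds, hybrid

    def test_returns_posterior_over_thick_factors(self, reduced_space_setup):
        from sarcvae.analysis import intervention_inference
        est, ds, hybrid = reduced_space_setup
        target = np.full(80, 2.0)
        samples, peak, trace = intervention_inference(
            est, ds, target, hybrid, thick_names=("rx34", "rx16"),
            n=1500, seed=1, simulate_peak=False)
        assert samples.names == ("rx34", "rx16")
        assert samples.n == 1500
        # frozen thin coordinates pass through from the hybrid
        assert peak.rt12 == hybrid.rt12 and peak.rt41 == hybrid.rt41
        assert trace is None

    def test_frozen_set_mismatch_rejected(self, reduced_space_setup):
        from sarcvae.analysis import intervention_inference
        est, ds, hybrid = reduced_space_setup
        wrong_hybrid = hybrid.replace(rt12=5.0)
        with pytest.raises(ValueError, match="mismatch"):
            intervention_inference(est, ds, np.full(80, 2.0), wrong_hybrid,
                                   thick_names=("rx34", "rx16"), n=10,
                                   simulate_peak=False)
        with pytest.raises(ValueError, match="does not match"):
            intervention_inference(est, ds, np.full(80, 2.0), hybrid,
                                   thick_names=("rx12",), n=10,
                                   simulate_peak=False)


class TestInterventionSignature:
    def test_myosin_activator_signature(self, corpus_config):
        """Slower ADP release + more available motors (rx34, rx16 down)
        raise peak stress and prolong relaxation — paired simulations."""
        from sarcvae.simulate import average_replicates, twitch_summary
        base = average_replicates(None, corpus_config, n=20, seed=(31,))
        drug = average_replicates(RateFactors(rx34=0.3, rx16=0.3),
                                  corpus_config, n=20, seed=(31,))
        s0 = twitch_summary(base)
        s1 = twitch_summary(drug)
        assert s1.peak_stress > s0.peak_stress
        assert s1.t50_falling > s0.t50_falling
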