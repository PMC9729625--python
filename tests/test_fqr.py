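"""Decoy generation, mixture fitting, and FQR threshold behavior."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import norm

from glyquant.fqr import (
    em_fit,
    fqr_at_threshold,
    kmeans_init,
    make_decoys,
    posteriors,
    threshold_for_fqr,
)
from glyquant.model import GMMParams

from conftest import simple_gpsm


class TestDecoys:
    def test_mass_shifted_by_ten(self):
        g = simple_gpsm(precursor_mass=2000.0, precursor_mz=1001.007276466, charge=2)
        (d,) = make_decoys([g])
        assert d.precursor_mass == pytest.approx(2010.0)

    def test_mz_shifted_by_ten_over_charge(self):
        g = simple_gpsm(precursor_mass=1999.985447, precursor_mz=1001.0, charge=2)
        (d,) = make_decoys([g])
        assert d.precursor_mz == pytest.approx(1006.0)

    def test_one_decoy_per_target_all_flagged(self):
        targets = [simple_gpsm(spectrum_ref=f"s{i}") for i in range(5)]
        decoys = make_decoys(targets)
        assert len(decoys) == 5
        assert all(d.is_decoy for d in decoys)
        assert not any(t.is_decoy for t in targets)


class TestKmeansInit:
    def test_perfectly_separated_clusters(self):
        params = kmeans_init(np.array([0.0, 0.0, 0.0, 1.0, 1.0, 1.0]))
        assert params.mu0 == pytest.approx(0.0)
        assert params.mu1 == pytest.approx(1.0)
        assert params.pi0 == pytest.approx(0.5)
        assert params.pi1 == pytest.approx(0.5)

    def test_permutation_invariance(self):
        scores = np.array([0.1, 0.9, 0.15, 0.85, 0.2, 0.8])
        a = kmeans_init(scores)
        b = kmeans_init(scores[::-1].copy())
        assert np.allclose(a.as_array(), b.as_array())

    def test_recovers_bimodal_means(self):
        rng = np.random.default_rng(7)
        scores = np.concatenate(
            [rng.normal(0.2, 0.05, 1000), rng.normal(0.8, 0.05, 1000)]
        )
        params = kmeans_init(scores)
        assert abs(params.mu0 - 0.2) < 0.05
        assert abs(params.mu1 - 0.8) < 0.05

    def test_identical_scores_raise(self):
        with pytest.raises(ValueError):
            kmeans_init(np.full(10, 0.5))


class TestEMFit:
    def test_recovers_all_six_parameters(self):
        """2500⊕2500 draws from N(0.25,0.06)⊕N(0.85,0.06): all within ±0.02."""
        rng = np.random.default_rng(12)
        scores = np.concatenate(
            [rng.normal(0.25, 0.06, 2500), rng.normal(0.85, 0.06, 2500)]
        )
        fitted = em_fit(scores, kmeans_init(scores))
        expected = np.array([0.5, 0.5, 0.25, 0.85, 0.06, 0.06])
        assert np.all(np.abs(fitted.as_array() - expected) <= 0.02)

    def test_log_likelihood_never_decreases(self):
        rng = np.random.default_rng(3)
        scores = np.concatenate(
            [rng.normal(0.3, 0.1, 400), rng.normal(0.7, 0.1, 400)]
        )
        trace: list[float] = []
        em_fit(scores, kmeans_init(scores), track_loglik=trace)
        assert len(trace) > 2
        assert all(b >= a - 1e-9 for a, b in zip(trace, trace[1:]))

    def test_posteriors_sum_to_one(self):
        rng = np.random.default_rng(5)
        scores = rng.uniform(0, 1, 100)
        params = GMMParams(0.4, 0.6, 0.3, 0.7, 0.1, 0.1)
        resp = posteriors(scores, params)
        assert np.allclose(resp.sum(axis=0), 1.0)

    def test_one_component_degenerate_limit(self):
        rng = np.random.default_rng(9)
        scores = rng.normal(0.6, 0.05, 2000)
        init = GMMParams(0.05, 0.95, 0.0, 0.6, 0.05, 0.05)
        fitted = em_fit(scores, init)
        assert fitted.pi0 < 0.02
        assert abs(fitted.mu1 - scores.mean()) < 0.01
        assert abs(fitted.sigma1 - scores.std()) < 0.01


class TestFqrAtThreshold:
    def test_symmetric_standard_case(self):
        """π=0.5/0.5, μ=∓1, σ=1 at t=0 gives Φ(−1)/(Φ(−1)+Φ(1)) ≈ 0.1587."""
        params = GMMParams(0.5, 0.5, -1.0, 1.0, 1.0, 1.0)
        assert fqr_at_threshold(params, 0.0) == pytest.approx(0.1587, abs=1e-4)

    def test_low_threshold_limit_is_pi0(self):
        params = GMMParams(0.3, 0.7, 0.2, 0.8, 0.1, 0.1)
        assert fqr_at_threshold(params, -1e6) == pytest.approx(0.3, abs=1e-9)

    def test_high_threshold_limit_vanishes(self):
        params = GMMParams(0.5, 0.5, 0.2, 0.8, 0.1, 0.1)
        assert fqr_at_threshold(params, 20.0) == pytest.approx(0.0, abs=1e-6)

    def test_double_pi_reproduces_literal_formula(self):
        params = GMMParams(0.3, 0.7, 0.2, 0.8, 0.1, 0.1)
        t = 0.5
        s0 = norm.sf(t, 0.2, 0.1)
        s1 = norm.sf(t, 0.8, 0.1)
        literal = (0.3**2 * s0) / (0.3**2 * s0 + 0.7**2 * s1)
        assert fqr_at_threshold(params, t, double_pi=True) == pytest.approx(literal)

    @settings(deadline=None, derandomize=True)
    @given(
        st.floats(0.05, 0.95),
        st.floats(-2.0, 0.4),
        st.floats(0.5, 2.0),
        st.floats(0.05, 1.5),
    )
    def test_monotone_nonincreasing_for_equal_sigmas(self, pi0, mu0, gap, sigma):
        params = GMMParams(pi0, 1 - pi0, mu0, mu0 + gap, sigma, sigma)
        ts = np.linspace(mu0 - 3 * sigma, mu0 + gap + 3 * sigma, 50)
        values = [fqr_at_threshold(params, t) for t in ts]
        assert all(b <= a + 1e-12 for a, b in zip(values, values[1:]))


class TestThreshold:
    def _bimodal(self, seed=2, n=2000):
        rng = np.random.default_rng(seed)
        labels = rng.random(n) < 0.5
        scores = np.where(
            labels, rng.normal(0.85, 0.06, n), rng.normal(0.25, 0.06, n)
        )
        return scores, labels

    def test_threshold_lies_between_modes(self):
        scores, _ = self._bimodal()
        params = em_fit(scores, kmeans_init(scores))
        t = threshold_for_fqr(params, scores, 0.01)
        assert 0.25 < t < 0.85

    def test_alpha_one_accepts_from_minimum(self):
        scores, _ = self._bimodal()
        params = em_fit(scores, kmeans_init(scores))
        assert threshold_for_fqr(params, scores, 1.0) == scores.min()

    def test_impossible_alpha_accepts_nothing(self):
        scores, _ = self._bimodal()
        params = em_fit(scores, kmeans_init(scores))
        with pytest.warns(UserWarning):
            assert threshold_for_fqr(params, scores, 0.0) is None

    def test_realized_false_fraction_matches_nominal_level(self):
        """Among accepted scores the true-false fraction stays ≤ 1.5×alpha."""
        for seed in (2, 3, 4):
            scores, labels = self._bimodal(seed=seed, n=4000)
            params = em_fit(scores, kmeans_init(scores))
            t = threshold_for_fqr(params, scores, 0.01)
            accepted = scores > t
            false_fraction = (~labels & accepted).sum() / max(accepted.sum(), 1)
            assert false_fraction <= 1.5 * 0.01
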