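import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from specloc.grids import make_elevation_grid, make_frequency_grid
from specloc.model import (
    LikelihoodFunction,
    ModelConfig,
    PosteriorDistribution,
    SpatialPrior,
    WeightingParams,
    apply_prior,
    cross_correlate,
    decide,
    localize,
    rectify_to_likelihood,
    sensory_spectrum,
    weighting_function,
)
from specloc.stimulus import make_stimulus


class TestWeightingFunction:
    def test_zero_at_and_outside_support(self, grid):
        w = weighting_function(WeightingParams(), grid)
        f = grid.values
        assert np.all(w[(f <= 3.5) | (f >= 12.0)] == 0.0)
        assert np.all(w[(f > 3.5) & (f < 12.0)] > 0.0)

    def test_peak_location_matches_closed_form(self):
        p = WeightingParams()
        assert p.argmax_khz == pytest.approx(9.875)
        dense = make_frequency_grid(3.5, 12.0, 4096)
        w = weighting_function(p, dense)
        assert dense.values[np.argmax(w)] == pytest.approx(9.875, abs=2e-3)
        assert w.max() == pytest.approx(1.0, abs=1e-6)

    def test_symmetric_exponents_peak_at_midpoint(self):
        p = WeightingParams(alpha1=2.0, alpha2=2.0, f_min=4.0, f_max=10.0)
        assert p.argmax_khz == pytest.approx(7.0)

    @pytest.mark.parametrize("a1,a2", [(0.0, 1.5), (4.5, -1.0)])
    def test_nonpositive_exponents_rejected(self, a1, a2):
        with pytest.raises(ValueError):
            WeightingParams(alpha1=a1, alpha2=a2)


class TestSensorySpectrum:
    def test_identity_with_unit_weights_and_silent_source(self, hrtfs):
        h = hrtfs.gains[0]
        out = sensory_spectrum(h, np.zeros_like(h), np.ones_like(h))
        np.testing.assert_array_equal(out, h)

    def test_single_bin_arithmetic(self):
        out = sensory_spectrum(np.array([-10.0]), np.array([47.0]), np.array([0.5]))
        assert out[0] == pytest.approx(18.5)

    def test_zero_outside_weighting_support(self, hrtfs, grid):
        w = weighting_function(WeightingParams(), grid)
        x = make_stimulus(65.0, 29.0, grid)
        out = sensory_spectrum(hrtfs.gains[10], x, w)
        f = grid.values
        assert np.all(out[(f <= 3.5) | (f >= 12.0)] == 0.0)

    def test_grid_mismatch_rejected(self):
        with pytest.raises(ValueError):
            sensory_spectrum(np.zeros(5), np.zeros(4), np.zeros(5))


class TestCrossCorrelation:
    def test_template_self_correlation_is_one(self, hrtfs):
        """A sensory spectrum equal to a stored row correlates 1 there."""
        c = cross_correlate(hrtfs.gains[20], hrtfs, weights=None,
                            weight_templates=False)
        assert c.values[20] == pytest.approx(1.0)

    def test_flat_source_is_veridical_for_every_elevation(self, hrtfs):
        """Zero-contrast sound at any level: correlation max at the true
        elevation for all 59 grid elevations (template uniqueness at work)."""
        cfg = ModelConfig()
        for level in (29.0, 47.0, 65.0):
            x = make_stimulus(level, level, hrtfs.grid)
            resp = np.array(
                [localize(x, e, hrtfs, cfg) for e in hrtfs.elevations.values]
            )
            np.testing.assert_array_equal(resp, hrtfs.elevations.values)

    def test_high_positive_contrast_biases_upward(self, hrtfs):
        """A 6-9 kHz block masquerades as an upward source: for low true
        elevations the correlation argmax lands in the upper hemifield."""
        cfg = ModelConfig()
        x = make_stimulus(65.0, 29.0, hrtfs.grid)
        low = [e for e in hrtfs.elevations.values if e <= -20.0]
        resp = np.array([localize(x, e, hrtfs, cfg) for e in low])
        assert np.all(resp > 40.0)

    def test_correlation_values_bounded(self, hrtfs, rng):
        w = weighting_function(WeightingParams(), hrtfs.grid)
        s = rng.normal(0, 10, hrtfs.grid.n)
        c = cross_correlate(w * s, hrtfs, weights=w)
        assert np.all(c.values >= -1.0) and np.all(c.values <= 1.0)

    def test_empty_band_rejected(self, hrtfs):
        with pytest.raises(ValueError):
            cross_correlate(hrtfs.gains[0], hrtfs, band=(7.0, 7.001))


class TestLikelihoodAndPrior:
    def test_rectification(self, elevations):
        c_vals = np.linspace(-1, 1, elevations.n)
        from specloc.model import CorrelationFunction

        like = rectify_to_likelihood(
            CorrelationFunction(elevations=elevations, values=c_vals)
        )
        np.testing.assert_array_equal(like.values, np.maximum(c_vals, 0.0))
        assert np.all(like.values >= 0)

    def test_uniform_prior_posterior_proportional_to_likelihood(self, elevations):
        vals = np.abs(np.sin(np.linspace(0, 3, elevations.n)))
        like = LikelihoodFunction(elevations=elevations, values=vals)
        post = apply_prior(like, SpatialPrior(kind="near-uniform"))
        np.testing.assert_allclose(post.mass, vals / vals.sum(), atol=1e-12)

    def test_zero_likelihood_falls_back_to_prior(self, elevations):
        like = LikelihoodFunction(elevations=elevations,
                                  values=np.zeros(elevations.n))
        post = apply_prior(like, SpatialPrior(kind="gaussian", mean=0.0, sigma=10.0))
        assert elevations.values[np.argmax(post.mass)] == pytest.approx(0.0)
        assert post.mass.sum() == pytest.approx(1.0)

    def test_gaussian_prior_favors_peak_nearer_its_mean(self, elevations):
        e = elevations.values
        two_peak = (np.exp(-0.5 * ((e - 10) / 5) ** 2)
                    + 1.05 * np.exp(-0.5 * ((e - 70) / 5) ** 2))
        like = LikelihoodFunction(elevations=elevations, values=two_peak)
        wide = apply_prior(like, SpatialPrior(kind="gaussian", sigma=500.0))
        narrow = apply_prior(like, SpatialPrior(kind="gaussian", sigma=20.0))
        assert e[np.argmax(wide.mass)] == pytest.approx(70.0)
        assert e[np.argmax(narrow.mass)] == pytest.approx(10.0)

    @given(seed=st.integers(0, 10_000))
    @settings(max_examples=50, deadline=None)
    def test_posterior_always_normalized(self, elevations, seed):
        r = np.random.default_rng(seed)
        vals = np.maximum(r.normal(0, 1, elevations.n), 0.0)
        like = LikelihoodFunction(elevations=elevations, values=vals)
        prior = SpatialPrior(kind="gaussian", mean=float(r.uniform(-30, 30)),
                             sigma=float(r.uniform(5, 100)))
        post = apply_prior(like, prior)
        assert post.mass.sum() == pytest.approx(1.0, abs=1e-9)
        assert np.all(post.mass >= 0)


class TestDecision:
    def test_map_is_brute_force_argmax_on_random_posteriors(self, elevations):
        r = np.random.default_rng(42)
        for _ in range(1000):
            mass = r.dirichlet(np.full(elevations.n, 0.3))
            post = PosteriorDistribution(elevations=elevations, mass=mass)
            assert decide(post, "map") == elevations.values[np.argmax(mass)]

    def test_exact_tie_broken_toward_center_then_down(self, elevations):
        e = elevations.values
        mass = np.zeros(e.size)
        mass[e == -20.0] = 0.5
        mass[e == 20.0] = 0.5
        post = PosteriorDistribution(elevations=elevations, mass=mass)
        assert decide(post, "map") == -20.0

    def test_sampling_matches_posterior_mass(self, elevations):
        """Empirical frequencies of the sampling rule agree with the mass
        (chi-square goodness of fit at n = 10^4)."""
        r = np.random.default_rng(5)
        mass = r.dirichlet(np.full(8, 2.0))
        small = make_elevation_grid(0, 35, 5)
        post = PosteriorDistribution(elevations=small, mass=mass)
        draws = np.array([decide(post, "sample", r) for _ in range(10_000)])
        counts = np.array([(draws == v).sum() for v in small.values])
        stat, p = stats.chisquare(counts, mass * 10_000)
        assert p > 1e-4

    def test_prior_shrinkage_pulls_percept_toward_prior_mean(self, elevations):
        """On a fixed likelihood, tightening the prior never moves the MAP
        percept away from the prior mean."""
        r = np.random.default_rng(9)
        vals = np.maximum(r.normal(0.2, 0.5, elevations.n), 0.0)
        like = LikelihoodFunction(elevations=elevations, values=vals)
        dists = []
        for sigma in (200.0, 100.0, 50.0, 25.0, 12.0, 6.0, 3.0):
            post = apply_prior(like, SpatialPrior(kind="gaussian", sigma=sigma))
            dists.append(abs(decide(post, "map")))
        assert all(b <= a + 1e-9 for a, b in zip(dists, dists[1:]))
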