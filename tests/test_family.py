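"""The convolution family: quadrature rule, density, CDF, sampler, moments."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import integrate, stats

from lognnc.family import (
    DistParamTriple,
    gauss_hermite_rule,
    lognnc_cdf,
    lognnc_logpdf,
    lognnc_mean_var,
    lognnc_sample,
    lognnc_score_eta,
    lognnc_score_hess_eta,
    lognormal_logpdf,
)

LATTICE = [(mu, sig, lam) for mu in (-1.0, 0.0, 1.0)
           for sig in (0.2, 0.8, 1.5) for lam in (0.3, 0.6, 1.2)]


def oracle_pdf(yt, mu, sig, lam):
    """Adaptive numerical convolution in z-space (independent of the
    package's segmented fixed-node scheme)."""
    f = lambda z: stats.norm.pdf(z) * stats.norm.pdf(yt - np.exp(mu + sig * z), 0, lam)  # noqa: E731
    pts = [0.0] + ([(np.log(yt) - mu) / sig] if yt > 0 else [])
    bounds = sorted(set([-40.0, 40.0] + [p for p in pts if -40 < p < 40]))
    return sum(integrate.quad(f, a, b, limit=800, epsabs=0, epsrel=1e-11)[0]
               for a, b in zip(bounds[:-1], bounds[1:]))


class TestQuadRule:
    def test_two_point_rule_is_probabilists(self):
        r = gauss_hermite_rule(2)
        assert np.allclose(sorted(r.nodes), [-1.0, 1.0])
        assert np.allclose(r.weights, [0.5, 0.5])

    @pytest.mark.parametrize("n", [2, 8, 31, 64])
    def test_normalization_and_symmetry(self, n):
        r = gauss_hermite_rule(n)
        assert r.weights.sum() == pytest.approx(1.0, abs=1e-12)
        assert np.sum(r.weights * r.nodes) == pytest.approx(0.0, abs=1e-12)
        assert np.allclose(np.sort(r.nodes), -np.sort(-r.nodes)[::-1])

    def test_second_moment(self, rule64):
        assert np.sum(rule64.weights * rule64.nodes**2) == pytest.approx(1.0, abs=1e-10)

    def test_rejects_single_node(self):
        with pytest.raises(ValueError):
            gauss_hermite_rule(1)


class TestLogpdf:
    def test_lam_zero_reduces_to_lognormal(self, rule64):
        p = DistParamTriple(0.3, 0.9, 0.0)
        y = np.array([0.2, 1.0, 1.7, 5.0])
        assert np.allclose(lognnc_logpdf(y, p, rule64),
                           stats.lognorm.logpdf(y, 0.9, scale=np.exp(0.3)))
        assert lognnc_logpdf(-0.5, p, rule64) == -np.inf
        # value at y = exp(mu): -log(exp(mu) sigma sqrt(2 pi))
        assert lognnc_logpdf(np.exp(0.3), p, rule64) == pytest.approx(
            -np.log(np.exp(0.3) * 0.9 * np.sqrt(2 * np.pi)))

    def test_degenerate_signal_limit(self, rule64):
        # sigma ~ 0: Y degenerates at exp(mu)=1, so Y~ ~ N(1, lam^2)
        p = DistParamTriple(0.0, 1e-6, 0.5)
        assert lognnc_logpdf(1.0, p, rule64) == pytest.approx(
            np.log(1.0 / (0.5 * np.sqrt(2 * np.pi))), abs=1e-6)

    def test_matches_adaptive_convolution_spec_point(self, rule64):
        p = DistParamTriple(0.2, 0.8, 0.6)
        for yt in (-1.0, 0.0, 0.5, 2.0, 10.0):
            mine = np.exp(lognnc_logpdf(yt, p, rule64))
            assert mine == pytest.approx(oracle_pdf(yt, 0.2, 0.8, 0.6), rel=1e-6)

    @pytest.mark.parametrize("mu,sig,lam", LATTICE)
    def test_matches_adaptive_convolution_lattice(self, rule64, mu, sig, lam):
        p = DistParamTriple(mu, sig, lam)
        for yt in (-1.0, 0.0, 0.5, 2.0, 10.0):
            mine = np.exp(lognnc_logpdf(yt, p, rule64))
            assert mine == pytest.approx(oracle_pdf(yt, mu, sig, lam), rel=1e-6)

    @pytest.mark.parametrize("mu,sig,lam", LATTICE + [(m, s, 0.0) for m in (-1.0, 0.0, 1.0)
                                                      for s in (0.2, 0.8, 1.5)])
    def test_density_integrates_to_one(self, rule64, mu, sig, lam):
        p = DistParamTriple(mu, sig, lam)
        hi = np.exp(mu + 8 * sig) + 8 * lam
        grid = np.concatenate([np.linspace(-8 * lam - 1, 1e-9, 3000),
                               np.geomspace(1e-9, hi, 20000)])
        pdf = np.exp(lognnc_logpdf(grid, DistParamTriple(
            np.full(grid.size, mu), np.full(grid.size, sig), np.full(grid.size, lam)), rule64))
        mass = np.trapezoid(pdf, grid)
        assert mass == pytest.approx(1.0, abs=1e-4)

    def test_lam_to_zero_continuity(self, rule64):
        y = np.array([0.3, 1.0, 2.5])
        near = lognnc_logpdf(y, DistParamTriple(0.1, 0.7, 1e-8), rule64)
        exact = lognormal_logpdf(y, 0.1, 0.7)
        assert np.allclose(near, exact, atol=1e-4)

    def test_rejects_bad_arguments(self, rule64):
        with pytest.raises(ValueError):
            DistParamTriple(0.0, -1.0, 0.5)
        with pytest.raises(ValueError):
            DistParamTriple(np.nan, 1.0, 0.5)
        with pytest.raises(ValueError):
            lognnc_logpdf(np.inf, DistParamTriple(0.0, 1.0, 0.5), rule64)


class TestCdf:
    def test_limits(self, rule64):
        p = DistParamTriple(0.2, 0.8, 0.6)
        assert lognnc_cdf(-40.0, p, rule64) == pytest.approx(0.0, abs=1e-12)
        assert lognnc_cdf(1e4, p, rule64) == pytest.approx(1.0, abs=1e-12)

    def test_symmetric_degenerate_case(self, rule64):
        assert lognnc_cdf(1.0, DistParamTriple(0.0, 1e-6, 1.0), rule64) == pytest.approx(0.5, abs=1e-9)

    def test_against_monte_carlo(self, rule64):
        p = DistParamTriple(0.2, 0.8, 0.6)
        draws = np.sort(lognnc_sample(10**6, p, seed=1234))
        grid = np.linspace(-1.0, 5.0, 25)
        emp = np.searchsorted(draws, grid) / draws.size
        assert np.max(np.abs(emp - lognnc_cdf(grid, p, rule64))) <= 0.002

    def test_monotone_nondecreasing(self, rule64):
        p = DistParamTriple(-0.5, 1.2, 0.4)
        grid = np.linspace(-3.0, 12.0, 400)
        F = lognnc_cdf(grid, p, rule64)
        assert np.all(np.diff(F) >= -1e-12)

    def test_consistent_with_pdf(self, rule64):
        p = DistParamTriple(0.2, 0.8, 0.6)
        ys = np.linspace(-1.5, 6.0, 40)
        h = 1e-4
        fd = (lognnc_cdf(ys + h, p, rule64) - lognnc_cdf(ys - h, p, rule64)) / (2 * h)
        pdf = np.exp(lognnc_logpdf(ys, p, rule64))
        assert np.max(np.abs(fd / pdf - 1.0)) <= 1e-3

    def test_lam_zero_is_lognormal_cdf(self, rule64):
        p = DistParamTriple(0.1, 0.9, 0.0)
        y = np.array([-1.0, 0.5, 2.0])
        expect = stats.lognorm.cdf(y, 0.9, scale=np.exp(0.1))
        assert np.allclose(lognnc_cdf(y, p, rule64), expect)


class TestSampler:
    def test_pure_lognormal_samples_positive(self):
        s = lognnc_sample(5000, DistParamTriple(0.0, 0.8, 0.0), seed=7)
        assert np.all(s > 0)

    def test_mean_matches_lognormal_formula(self):
        # E(Y~) = exp(mu + sigma^2/2): the additive noise has zero mean
        p = DistParamTriple(0.0, 0.5, 0.6)
        s = lognnc_sample(10**6, p, seed=99)
        mean, var = lognnc_mean_var(p)
        assert mean == pytest.approx(np.exp(0.125))
        se = np.sqrt(var / s.size)
        assert abs(s.mean() - mean) < 3 * se

    def test_negative_fraction_matches_cdf(self, rule64):
        p = DistParamTriple(-1.0, 0.3, 0.6)
        s = lognnc_sample(10**6, p, seed=5)
        assert abs(np.mean(s < 0) - lognnc_cdf(0.0, p, rule64)) <= 0.002

    def test_reproducible(self):
        p = DistParamTriple(0.2, 0.7, 0.5)
        assert np.array_equal(lognnc_sample(100, p, seed=3), lognnc_sample(100, p, seed=3))

    def test_rejects_bad_n(self):
        with pytest.raises(ValueError):
            lognnc_sample(0, DistParamTriple(0, 1, 0.1), seed=0)


class TestMoments:
    def test_degenerate(self):
        mean, var = lognnc_mean_var(DistParamTriple(0.0, 1e-9, 0.0))
        assert mean == pytest.approx(1.0)
        assert var == pytest.approx(0.0, abs=1e-12)

    def test_lognormal_mean(self):
        mean, _ = lognnc_mean_var(DistParamTriple(0.0, 1.0, 0.0))
        assert mean == pytest.approx(np.exp(0.5))

    def test_against_simulation(self):
        p = DistParamTriple(0.2, 0.8, 0.6)
        s = lognnc_sample(10**7, p, seed=11)
        mean, var = lognnc_mean_var(p)
        assert s.mean() == pytest.approx(mean, abs=4 * np.sqrt(var / s.size))
        assert s.var() == pytest.approx(var, rel=0.01)


class TestProperties:
    @settings(max_examples=40, deadline=None, derandomize=True)
    @given(mu=st.floats(-2, 2), sig=st.floats(0.1, 2.0), lam=st.floats(0.05, 1.5))
    def test_cdf_monotone_and_density_finite(self, mu, sig, lam):
        p = DistParamTriple(mu, sig, lam)
        grid = np.linspace(-4 * lam, np.exp(mu + 3 * sig) + 4 * lam, 60)
        lp = lognnc_logpdf(grid, p)
        assert np.all(np.isfinite(lp))
        F = lognnc_cdf(grid, p)
        assert np.all(np.diff(F) >= -1e-12)
        assert np.all((F >= 0) & (F <= 1))

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(mu=st.floats(-1.5, 1.5), sig=st.floats(0.2, 1.5), lam=st.floats(0.1, 1.0),
           seed=st.integers(0, 10_000))
    def test_sampler_quantiles_consistent_with_cdf(self, mu, sig, lam, seed):
        p = DistParamTriple(mu, sig, lam)
        s = lognnc_sample(4000, p, seed=seed)
        med = float(np.median(s))
        assert lognnc_cdf(med, p) == pytest.approx(0.5, abs=0.03)


class TestDerivatives:
    def test_score_matches_finite_differences(self, rule24):
        y = np.array([-0.5, 0.3, 2.0, 10.0])
        mu = np.array([0.1, 0.2, -0.3, 0.2])
        sig = np.array([0.5, 0.8, 1.2, 0.8])
        lam = np.array([0.4, 0.6, 0.9, 0.6])
        du, ds, dl = lognnc_score_eta(y, mu, sig, lam, rule24)
        h = 1e-6

        def ll(mu_, sig_, lam_):
            return lognnc_logpdf(y, DistParamTriple(mu_, sig_, lam_), rule24)

        assert np.allclose((ll(mu + h, sig, lam) - ll(mu - h, sig, lam)) / (2 * h), du, atol=1e-6)
        assert np.allclose((ll(mu, sig * np.exp(h), lam) - ll(mu, sig * np.exp(-h), lam)) / (2 * h), ds, atol=1e-6)
        assert np.allclose((ll(mu, sig, lam * np.exp(h)) - ll(mu, sig, lam * np.exp(-h))) / (2 * h), dl, atol=1e-6)

    def test_curvature_matches_finite_differences(self, rule24):
        y = np.array([0.3, 2.0])
        mu = np.array([0.2, -0.3])
        sig = np.array([0.8, 1.2])
        lam = np.array([0.6, 0.9])
        _, (wm, wsg, wl) = lognnc_score_hess_eta(y, mu, sig, lam, rule24)
        h = 1e-4

        def ll(mu_, sig_, lam_):
            return lognnc_logpdf(y, DistParamTriple(mu_, sig_, lam_), rule24)

        fd = -(ll(mu + h, sig, lam) - 2 * ll(mu, sig, lam) + ll(mu - h, sig, lam)) / h**2
        assert np.allclose(wm, fd, atol=1e-4)


class TestFastPath:
    def test_compiled_path_matches_reference(self, rule24):
        from lognnc._fastpath import HAVE_NUMBA, FastLogNNC

        if not HAVE_NUMBA:
            # the fallback is the reference itself; nothing to compare
            return
        rng = np.random.default_rng(8)
        n = 500
        mu = rng.normal(0, 1, n)
        sig = np.exp(rng.normal(-0.3, 0.3, n))
        lam = np.exp(rng.normal(-0.5, 0.2, n))
        y = np.exp(mu + sig * rng.standard_normal(n)) + lam * rng.standard_normal(n)
        fast = FastLogNNC(24)
        assert np.allclose(fast.logpdf(y, mu, sig, lam),
                           lognnc_logpdf(y, DistParamTriple(mu, sig, lam), rule24),
                           atol=1e-10)
        u, w = fast.score_weights(y, mu, sig, lam)
        un, wn = lognnc_score_hess_eta(y, mu, sig, lam, rule24)
        for a, b in zip(u, un):
            assert np.allclose(a, b, atol=1e-8)
        for a, b in zip(w, wn):
            assert np.allclose(a, b, atol=1e-5)
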