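"""Quantile residuals, Q-Q summaries, autocorrelation, deconvolution, and
the variance-explained thought experiment."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from lognnc.design import Intercept, ModelSpec
from lognnc.diagnostics import (
    ResidualSet,
    deconvolved_density,
    qq_summary,
    quantile_residuals,
    residual_acf,
    variance_explained_share,
)
from lognnc.family import DistParamTriple, lognnc_sample
from lognnc.fit import SamplerSettings, fit_map, run_mcmc

INT_SPEC3 = ModelSpec(mu=[Intercept()], sigma=[Intercept()], lam=[Intercept()])


def rset(r, rounds=None):
    n = len(r)
    return ResidualSet(r=np.asarray(r, float), time=np.arange(n) * 10.0,
                       round_id=np.asarray(rounds if rounds is not None else ["r0"] * n),
                       segment_id=np.array(["s0"] * n), finite_mask=np.ones(n, bool))


class TestQuantileResiduals:
    def test_median_observation_has_zero_residual(self):
        y = lognnc_sample(4000, DistParamTriple(0.1, 0.6, 0.5), seed=1)
        rec = pd.DataFrame({"value": y})
        fit = fit_map(rec, INT_SPEC3, "lognnc")
        pars = fit.predict_params()
        # an artificial record exactly at the fitted conditional median
        from lognnc.family import lognnc_cdf

        grid = np.linspace(-2, 8, 4001)
        F = lognnc_cdf(grid, DistParamTriple(pars["mu"][0], pars["sigma"][0], pars["lam"][0]))
        med = grid[np.searchsorted(F, 0.5)]
        rec2 = pd.DataFrame({"value": [med]})
        r = quantile_residuals(fit, rec2)
        assert r.r[0] == pytest.approx(0.0, abs=2e-3)

    def test_standard_normal_under_true_model(self):
        passes = 0
        for rep in range(20):
            y = lognnc_sample(2000, DistParamTriple(0.2, 0.7, 0.6), seed=700 + rep)
            rec = pd.DataFrame({"value": y})
            fit = fit_map(rec, INT_SPEC3, "lognnc")
            r = quantile_residuals(fit, rec).finite
            D = stats.kstest(r, "norm").statistic
            passes += D < 1.63 / np.sqrt(r.size)  # 1% critical value
        assert passes >= 18

    def test_truncated_fit_flags_negatives(self):
        y = lognnc_sample(3000, DistParamTriple(-0.5, 0.5, 0.6), seed=2)
        rec = pd.DataFrame({"value": y})
        pos = rec[rec["value"] > 0].reset_index(drop=True)
        fit = fit_map(pos, ModelSpec(mu=[Intercept()], sigma=[Intercept()]), "lognormal")
        res = quantile_residuals(fit, rec)
        neg = rec["value"].to_numpy() <= 0
        assert neg.any()
        assert not res.finite_mask[neg].any()  # would be -inf; flagged
        assert np.all(res.r[neg] == -8.0)
        assert res.finite_mask[~neg].all()


class TestQQ:
    def test_exact_normal_quantiles_on_line(self):
        probs = np.linspace(0.0005, 0.9995, 9999)
        r = stats.norm.ppf(probs)
        tab = qq_summary(rset(r))
        assert np.max(np.abs(tab["deviation"])) < 0.05

    def test_right_skew_shows_in_upper_tail(self):
        rng = np.random.default_rng(3)
        r = rng.gamma(2.0, 1.0, 20000) - 2.0  # right-skewed, mean 0
        tab = qq_summary(rset(r))
        assert tab.attrs["tail_dev_99"] > 0.5
        assert abs(tab.attrs["tail_dev_1"]) < abs(tab.attrs["tail_dev_99"])

    def test_qq_correlation_for_normal_sample(self):
        rng = np.random.default_rng(4)
        tab = qq_summary(rset(rng.standard_normal(10000)))
        assert tab.attrs["qq_correlation"] >= 0.999

    def test_too_few_residuals(self):
        with pytest.raises(ValueError):
            qq_summary(rset(np.zeros(5)))


class TestACF:
    def test_lag_zero_is_one(self):
        rng = np.random.default_rng(5)
        tab = residual_acf(rset(rng.standard_normal(500)), [0.0, 10.0])
        assert tab.loc[tab["lag_s"] == 0.0, "acf"].iloc[0] == 1.0

    def test_white_noise_is_uncorrelated(self):
        rng = np.random.default_rng(6)
        tab = residual_acf(rset(rng.standard_normal(10000)), [10.0])
        assert abs(tab["acf"].iloc[0]) <= 0.03

    def test_ar1_recovers_phi(self):
        rng = np.random.default_rng(7)
        n, phi = 20000, 0.5
        r = np.empty(n)
        r[0] = rng.standard_normal()
        for i in range(1, n):
            r[i] = phi * r[i - 1] + np.sqrt(1 - phi**2) * rng.standard_normal()
        tab = residual_acf(rset(r), [10.0, 20.0])
        assert tab["acf"].iloc[0] == pytest.approx(phi, abs=0.05)
        assert tab["acf"].iloc[1] == pytest.approx(phi**2, abs=0.05)

    def test_no_cross_round_pairs(self):
        # two rounds of constant but different residuals: within-round
        # lagged pairs are constant, so the acf numerator uses no
        # cross-round information
        r = np.concatenate([np.full(50, 1.0), np.full(50, -1.0)])
        rounds = np.array(["a"] * 50 + ["b"] * 50)
        tab = residual_acf(rset(r, rounds), [10.0])
        assert tab["n_pairs"].iloc[0] == 98  # 49 per round

    def test_non_multiple_lag_warns(self):
        rng = np.random.default_rng(8)
        with pytest.warns(UserWarning, match="multiple"):
            residual_acf(rset(rng.standard_normal(100)), [15.0])


class TestDeconvolution:
    @pytest.fixture(scope="class")
    def nnc_fit(self):
        y = lognnc_sample(3000, DistParamTriple(0.2, 0.6, 0.5), seed=9)
        rec = pd.DataFrame({"value": y})
        s = SamplerSettings(n_iter=200, burn_in=80, thinning=2, seed=3)
        return rec, run_mcmc(rec, INT_SPEC3, "lognnc", settings=s)

    def test_error_component_symmetric(self, nnc_fit):
        rec, fit = nnc_fit
        grid = np.linspace(-4, 4, 161)
        tab = deconvolved_density(fit, rec, grid=grid, n_draws=20)
        e = tab["error"].to_numpy()
        assert np.allclose(e, e[::-1], atol=1e-12)

    def test_convolved_density_integrates_to_one(self, nnc_fit):
        rec, fit = nnc_fit
        grid = np.linspace(-4, 30, 800)
        tab = deconvolved_density(fit, rec, grid=grid, n_draws=0)
        mass = np.trapezoid(tab["convolved"], grid)
        assert mass == pytest.approx(1.0, abs=1e-3)

    def test_zero_noise_conv_equals_signal(self):
        y = np.exp(0.3 + 0.5 * np.random.default_rng(1).standard_normal(1500))
        rec = pd.DataFrame({"value": y})
        fit = fit_map(rec, ModelSpec(mu=[Intercept()], sigma=[Intercept()]), "lognormal")
        grid = np.linspace(0.05, 8, 300)
        tab = deconvolved_density(fit, rec, grid=grid, n_draws=0)
        assert np.allclose(tab["convolved"], tab["signal"])

    def test_empty_subset_rejected(self, nnc_fit):
        rec, fit = nnc_fit
        with pytest.raises(ValueError):
            deconvolved_density(fit, rec, subset=np.zeros(len(rec), bool))


class TestVarianceExplained:
    def test_noise_ceiling_thought_experiment(self):
        # two true concentrations 0.44 and 1.25 ug/m3, noise sd 0.6:
        # a perfect model explains about half the observed variance
        share = variance_explained_share([0.44, 1.25], 0.6)
        assert share == pytest.approx(0.4768, abs=1e-3)
        assert round(share, 1) == 0.5

    def test_zero_noise_gives_one(self):
        assert variance_explained_share([0.44, 1.25], 0.0) == 1.0

    def test_identical_values_give_zero(self):
        assert variance_explained_share([1.0, 1.0], 0.5) == 0.0

    def test_degenerate_case_rejected(self):
        with pytest.raises(ValueError):
            variance_explained_share([1.0, 1.0], 0.0)
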