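"""Design matrices: categorical coding, splines, the constrained traffic
spline, and assembly of the additive predictors."""

import numpy as np
import pandas as pd
import pytest

from lognnc.design import (
    Categorical,
    Intercept,
    LatentTemporal,
    Linear,
    ModelSpec,
    Spline,
    TrafficSpline,
    assemble_design,
    constrained_traffic_spline,
    cubic_spline_basis,
    encode_categorical,
    rome_spec,
)


class TestCategorical:
    def test_reference_rows_are_zero(self):
        blk = encode_categorical(["park", "primary", "residential", "park"], "park",
                                 covariate="strclass")
        assert blk.matrix.shape == (4, 2)
        assert np.all(blk.matrix[[0, 3]] == 0)

    def test_declared_level_order(self):
        lv = ("park", "primary", "secondary", "tertiary", "residential")
        blk = encode_categorical(["primary", "park"], "park", declared=lv, covariate="strclass")
        assert blk.coef_names == ["strclass[primary]", "strclass[secondary]",
                                  "strclass[tertiary]", "strclass[residential]"]
        assert np.array_equal(blk.matrix[0], [1, 0, 0, 0])
        assert np.array_equal(blk.matrix[1], [0, 0, 0, 0])

    def test_single_level_warns_and_is_empty(self):
        with pytest.warns(UserWarning):
            blk = encode_categorical(["a", "a"], "a")
        assert blk.matrix.shape == (2, 0)

    def test_unknown_level_at_prediction_named(self):
        blk = encode_categorical(["a", "b"], "a", covariate="conf")
        with pytest.raises(ValueError, match="zzz"):
            blk.builder(pd.DataFrame({"conf": ["zzz"]}))

    def test_unknown_reference_rejected(self):
        with pytest.raises(ValueError):
            encode_categorical(["a", "b"], "c")


def gcv_fit(blk, y):
    """Penalized least-squares oracle with GCV-chosen smoothing."""
    X, P = blk.matrix, blk.penalty
    X1 = np.column_stack([np.ones(len(y)), X])
    P1 = np.zeros((P.shape[0] + 1,) * 2)
    P1[1:, 1:] = P
    best = None
    for lam in np.geomspace(1e-6, 1e4, 40):
        A = X1.T @ X1 + lam * P1
        beta = np.linalg.solve(A, X1.T @ y)
        H_tr = np.trace(np.linalg.solve(A, X1.T @ X1))
        rss = np.sum((y - X1 @ beta) ** 2)
        gcv = rss / (len(y) * (1 - H_tr / len(y)) ** 2)
        if best is None or gcv < best[0]:
            best = (gcv, beta)
    return X1 @ best[1]


class TestCubicSpline:
    def test_linear_functions_unpenalized(self):
        x = np.linspace(0, 24, 200)
        blk = cubic_spline_basis(x, n_knots=8, covariate="h")
        # a straight line through the centered basis: find coefs by LS,
        # then check the penalty quadratic form vanishes
        target = 2.0 * x - 10.0
        target = target - target.mean()
        beta, *_ = np.linalg.lstsq(blk.matrix, target, rcond=None)
        assert np.allclose(blk.matrix @ beta, target, atol=1e-8)
        assert float(beta @ blk.penalty @ beta) == pytest.approx(0.0, abs=1e-6)

    def test_deterministic_rebuild(self):
        rng = np.random.default_rng(0)
        x = rng.uniform(0, 24, 200)
        blk = cubic_spline_basis(x, n_knots=8, covariate="h")
        again = blk.builder(pd.DataFrame({"h": x}))
        assert np.array_equal(blk.matrix, again)

    def test_centered_columns(self):
        x = np.linspace(0, 10, 150)
        blk = cubic_spline_basis(x, n_knots=8)
        assert np.allclose(blk.matrix.mean(axis=0), 0.0, atol=1e-12)

    def test_recovers_smooth_signal(self):
        rng = np.random.default_rng(42)
        x = np.sort(rng.uniform(0, 24, 400))
        truth = np.sin(2 * np.pi * x / 24)
        y = truth + rng.normal(0, 0.1, x.size)
        blk = cubic_spline_basis(x, n_knots=8, covariate="h")
        fitted = gcv_fit(blk, y)
        rmse = np.sqrt(np.mean((fitted - truth) ** 2))
        assert rmse <= 0.05

    def test_too_few_unique_values(self):
        with pytest.raises(ValueError):
            cubic_spline_basis(np.array([1.0, 2.0, 1.0, 2.0]), n_knots=8)


class TestTrafficSpline:
    def test_constraints_hold(self):
        rng = np.random.default_rng(1)
        n = 300
        prim = rng.uniform(size=n) < 0.4
        count = np.where(prim, rng.uniform(200, 2000, n), np.nan)
        blk = constrained_traffic_spline(count, prim, n_knots=8)
        beta = rng.normal(size=blk.matrix.shape[1])
        fitted = blk.matrix @ beta
        assert np.all(fitted[~prim] == 0.0)
        assert fitted[prim].mean() == pytest.approx(0.0, abs=1e-10)

    def test_recovers_centered_effect(self):
        rng = np.random.default_rng(2)
        n = 600
        prim = rng.uniform(size=n) < 0.5
        count = np.where(prim, rng.uniform(200, 2000, n), np.nan)
        g = np.zeros(n)
        g[prim] = np.tanh((count[prim] - 900) / 400)
        g[prim] -= g[prim].mean()
        y = g + rng.normal(0, 0.05, n)
        blk = constrained_traffic_spline(count, prim, n_knots=8)
        X, P = blk.matrix, blk.penalty
        beta = np.linalg.solve(X.T @ X + 1e-3 * P, X.T @ y)
        rmse = np.sqrt(np.mean((X[prim] @ beta - g[prim]) ** 2))
        assert rmse <= 0.05

    def test_requires_primary_rows(self):
        with pytest.raises(ValueError):
            constrained_traffic_spline(np.array([1.0, 2.0]), np.array([False, False]), 8)


class TestAssembly:
    def test_intercept_only_etas_constant(self, small_campaign):
        _, route, rec, _ = small_campaign
        spec = ModelSpec(mu=[Intercept()], sigma=[Intercept()], lam=[Intercept()])
        d = assemble_design(rec, spec, route=route)
        eta = d.eta({b.label: np.array([2.0]) for _, b in d.all_blocks()})
        for p in ("mu", "sigma", "lam"):
            assert np.all(eta[p] == 2.0)

    def test_rome_coefficient_count(self):
        # intercept + ws + log_amb + (8-1) wd + (5-1) strclass + (3-1) strconf
        # + (3-1) stract + (4-1) traff + (2-1) weekday + spline dimension
        from lognnc.campaign import rome_like, simulate_campaign as sim

        rec, _ = sim(rome_like(seed=3, n_days=2, steps_per_segment=2))
        spec = rome_spec(latent=False, noise_model=True)
        d = assemble_design(rec, spec)
        n_param = sum(b.n_coef for b in d.blocks["mu"] if not b.penalized)
        assert n_param == 1 + 1 + 1 + 7 + 4 + 2 + 2 + 3 + 1
        spline_dims = [b.n_coef for b in d.blocks["mu"] if b.penalized]
        assert spline_dims == [9]  # 8 quantile knots -> 10 B-splines, centered

    def test_evaluator_linear_in_coefficients(self, small_campaign, basic_spec):
        _, route, rec, _ = small_campaign
        d = assemble_design(rec, basic_spec, route=route)
        rng = np.random.default_rng(0)
        c1 = {b.label: rng.normal(size=b.n_coef) for _, b in d.all_blocks()}
        c2 = {b.label: rng.normal(size=b.n_coef) for _, b in d.all_blocks()}
        csum = {k: c1[k] + c2[k] for k in c1}
        e1, e2, es = d.eta(c1), d.eta(c2), d.eta(csum)
        for p in es:
            assert np.allclose(e1[p] + e2[p], es[p], atol=1e-12)

    def test_linear_term_shift(self, small_campaign):
        """Doubling a linear coefficient with the covariate fixed at one
        raises eta by exactly that coefficient."""
        _, route, rec, _ = small_campaign
        rec = rec.copy()
        rec["log_amb"] = 1.0
        spec = ModelSpec(mu=[Intercept(), Linear("log_amb")], sigma=[Intercept()])
        d = assemble_design(rec, spec)
        base = d.eta({"mu:parametric": np.array([0.5, 0.8]), "sigma:parametric": np.array([0.0])})
        shifted = d.eta({"mu:parametric": np.array([0.5, 1.6]), "sigma:parametric": np.array([0.0])})
        assert np.allclose(shifted["mu"] - base["mu"], 0.8)

    def test_fixed_effect_design_full_rank(self, small_campaign, basic_spec):
        _, route, rec, _ = small_campaign
        spec = ModelSpec(mu=list(basic_spec.mu) + [Spline("h", 8), TrafficSpline("count", 8)],
                         sigma=[Intercept()], lam=[Intercept()])
        d = assemble_design(rec, spec, route=route)
        X = np.hstack([b.matrix for b in d.blocks["mu"]])
        assert np.linalg.matrix_rank(X) == X.shape[1]

    def test_missing_covariate_named(self, small_campaign):
        _, route, rec, _ = small_campaign
        spec = ModelSpec(mu=[Intercept(), Linear("nonexistent")], sigma=[Intercept()])
        with pytest.raises(KeyError, match="nonexistent"):
            assemble_design(rec, spec)

    def test_lam_predictor_restricted(self):
        with pytest.raises(ValueError):
            ModelSpec(mu=[Intercept()], sigma=[Intercept()], lam=[Intercept(), Linear("ws")])

    def test_spec_yaml_roundtrip(self, basic_spec):
        import yaml

        spec = ModelSpec(mu=list(basic_spec.mu) + [Spline("h", 8), LatentTemporal()],
                         sigma=list(basic_spec.sigma), lam=[Intercept()])
        blob = yaml.safe_dump(spec.to_dict())
        back = ModelSpec.from_dict(yaml.safe_load(blob))
        assert back.to_dict() == spec.to_dict()
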