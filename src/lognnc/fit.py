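"""Penalized MAP estimation and MCMC for the distributional models.

The posterior combines the family log-likelihood with improper flat priors
on parametric coefficients and Gaussian quadratic-penalty priors on spline
and latent-field blocks (variance hyperparameters get inverse-gamma(0.001,
0.001) priors).  Fitting proceeds in two stages:

1. ``fit_map``: cyclic blockwise Newton updates (backfitting across the mu,
   sigma and lam predictors) with step halving, jointly maximizing the
   penalized log-likelihood; hyperparameters move to their conditional
   posterior mode each cycle.
2. ``run_mcmc``: blockwise random-walk Metropolis-Hastings with
   curvature-informed Gaussian proposals (covariance = inverse of the
   block-conditional curvature, IWLS style), initialized at the MAP.
   Proposal covariances and scales adapt during burn-in only, preserving
   detailed balance afterward; variance hyperparameters are updated by
   conjugate inverse-gamma draws.

Credibility intervals are empirical 2.5/97.5 posterior percentiles; an
effect is flagged significant when its 95% interval excludes zero.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal

import numpy as np
import pandas as pd
from scipy.linalg import cho_factor, cho_solve, cholesky, LinAlgError
from scipy.special import ndtr

from .design import Design, ModelSpec, assemble_design
from .family import (
    DistParamTriple,
    QuadRule,
    gauss_hermite_rule,
    lognnc_cdf,
    lognnc_logpdf,
    lognnc_score_eta,
    lognnc_score_hess_eta,
)

__all__ = ["SamplerSettings", "FitResult", "fit_map", "run_mcmc", "summarize_effects",
           "get_family"]

_LOG_SQRT_2PI = 0.5 * np.log(2.0 * np.pi)
IG_A = 0.001
IG_B = 0.001

FamilyName = Literal["lognormal", "lognnc", "gaussian"]


# ------------------------------------------------------------- families


class _Family:
    name: str
    params: tuple[str, ...]

    def check(self, y: np.ndarray) -> None:  # pragma: no cover - trivial
        pass

    def loglik(self, y, eta) -> float:
        raise NotImplementedError

    def score(self, y, eta) -> dict[str, np.ndarray]:
        raise NotImplementedError

    def weights(self, y, eta, param: str) -> np.ndarray:
        raise NotImplementedError

    def score_weights(self, y, eta) -> tuple[dict[str, np.ndarray], dict[str, np.ndarray]]:
        """Score and positive curvature weights for every parameter at once."""
        u = self.score(y, eta)
        w = {p: self.weights(y, eta, p) for p in self.params}
        return u, w

    def cdf(self, y, eta) -> np.ndarray:
        raise NotImplementedError


class LognormalFamily(_Family):
    """Z = log Y ~ N(mu, sigma^2); requires strictly positive responses."""

    name = "lognormal"
    params = ("mu", "sigma")

    def check(self, y):
        if np.any(y <= 0):
            raise ValueError(
                "lognormal family requires positive values; truncate "
                "non-positive records first (the 'model2' variant does this)"
            )

    def _z(self, y):
        return np.log(y)

    def loglik(self, y, eta):
        z = self._z(y)
        sig = np.exp(eta["sigma"])
        resid = (z - eta["mu"]) / sig
        return float(np.sum(-np.log(y) - eta["sigma"] - _LOG_SQRT_2PI - 0.5 * resid**2))

    def score(self, y, eta):
        z = self._z(y)
        sig = np.exp(eta["sigma"])
        r = (z - eta["mu"]) / sig
        return {"mu": r / sig, "sigma": r**2 - 1.0}

    def weights(self, y, eta, param):
        sig = np.exp(eta["sigma"])
        if param == "mu":
            return 1.0 / sig**2
        return np.full(y.size, 2.0)  # Fisher weight for the log-sd predictor

    def cdf(self, y, eta):
        out = np.zeros(y.size)
        pos = y > 0
        sig = np.exp(eta["sigma"])
        out[pos] = ndtr((np.log(y[pos]) - eta["mu"][pos]) / sig[pos])
        return out


class GaussianFamily(LognormalFamily):
    """Y ~ N(mu, sigma^2) on the original scale (the 'model3' variant)."""

    name = "gaussian"
    params = ("mu", "sigma")

    def check(self, y):
        pass

    def _z(self, y):
        return y

    def loglik(self, y, eta):
        sig = np.exp(eta["sigma"])
        resid = (y - eta["mu"]) / sig
        return float(np.sum(-eta["sigma"] - _LOG_SQRT_2PI - 0.5 * resid**2))

    def cdf(self, y, eta):
        return ndtr((y - eta["mu"]) / np.exp(eta["sigma"]))


class LogNNCFamily(_Family):
    """Lognormal signal plus independent N(0, lam^2) instrument noise.

    Evaluation goes through the fused compiled path when numba is
    importable (numerically equivalent to the reference implementation in
    family.py, which remains the fallback and the tested oracle).
    """

    name = "lognnc"
    params = ("mu", "sigma", "lam")

    def __init__(self, rule: QuadRule | None = None):
        self.rule = rule or gauss_hermite_rule(24)
        self._fast = None
        from ._fastpath import HAVE_NUMBA, FastLogNNC

        if HAVE_NUMBA:
            self._fast = FastLogNNC(self.rule.nodes.size)

    def _p(self, eta):
        return eta["mu"], np.exp(eta["sigma"]), np.exp(eta["lam"])

    def loglik(self, y, eta):
        mu, sig, lam = self._p(eta)
        if self._fast is not None:
            return float(np.sum(self._fast.logpdf(y, mu, sig, lam)))
        return float(np.sum(lognnc_logpdf(y, DistParamTriple(mu, sig, lam), self.rule)))

    def score(self, y, eta):
        mu, sig, lam = self._p(eta)
        du, ds, dl = lognnc_score_eta(y, mu, sig, lam, self.rule)
        return {"mu": du, "sigma": ds, "lam": dl}

    def weights(self, y, eta, param):
        return self.score_weights(y, eta)[1][param]

    def score_weights(self, y, eta):
        mu, sig, lam = self._p(eta)
        if self._fast is not None:
            u, w = self._fast.score_weights(y, mu, sig, lam)
        else:
            u, w = lognnc_score_hess_eta(y, mu, sig, lam, self.rule)
        keys = ("mu", "sigma", "lam")
        return dict(zip(keys, u)), dict(zip(keys, w))

    def cdf(self, y, eta):
        mu, sig, lam = self._p(eta)
        return lognnc_cdf(y, DistParamTriple(mu, sig, lam))


def get_family(name: str, rule: QuadRule | None = None) -> _Family:
    if name == "lognormal":
        return LognormalFamily()
    if name == "gaussian":
        return GaussianFamily()
    if name == "lognnc":
        return LogNNCFamily(rule)
    raise ValueError(f"unknown family {name!r}")


# ------------------------------------------------------------- settings


@dataclass(frozen=True)
class SamplerSettings:
    n_iter: int = 3000
    burn_in: int = 1000
    thinning: int = 2
    seed: int = 0
    map_only: bool = False
    max_map_cycles: int = 40
    map_tol: float = 1e-6
    rule_nodes: int = 24  # quadrature budget during fitting

    def __post_init__(self):
        if not self.map_only and self.burn_in >= self.n_iter:
            raise ValueError("burn_in must be smaller than n_iter")

    @property
    def n_draws(self) -> int:
        return (self.n_iter - self.burn_in) // self.thinning


# ------------------------------------------------------------- fit state


@dataclass
class _BlockState:
    param: str
    label: str
    X: np.ndarray
    K: np.ndarray
    rank: int
    beta: np.ndarray
    tau2: float | None  # None for unpenalized blocks


@dataclass
class FitResult:
    """Posterior (or MAP) fit of one distributional model."""

    family: str
    design: Design
    blocks: list[_BlockState]
    coef_summary: pd.DataFrame
    map_coefs: dict[str, np.ndarray]
    draws: dict[str, np.ndarray] | None
    tau2_draws: dict[str, np.ndarray] | None
    loglik_trace: np.ndarray
    acceptance: dict[str, float]
    settings: SamplerSettings
    converged: bool
    n_used: int
    n_total: int
    warnings: list[str] = field(default_factory=list)

    def coefficients(self) -> dict[str, np.ndarray]:
        """Posterior-mean coefficients per block (MAP if no draws)."""
        if self.draws is None:
            return dict(self.map_coefs)
        return {label: d.mean(axis=0) for label, d in self.draws.items()}

    def eta(self, records: pd.DataFrame | None = None) -> dict[str, np.ndarray]:
        coefs = self.coefficients()
        if records is None:
            return self.design.eta(coefs)
        out: dict[str, np.ndarray] = {}
        for p in self.design.params():
            acc = np.zeros(len(records))
            for b in self.design.blocks[p]:
                if b.builder is None:
                    raise ValueError(f"block {b.label} cannot rebuild for new records")
                acc += b.builder(records) @ coefs[b.label]
            out[p] = acc
        return out

    def predict_params(self, records: pd.DataFrame | None = None) -> dict[str, np.ndarray]:
        """Posterior-mean (mu, sigma, lam) on the natural scale."""
        eta = self.eta(records)
        n = len(next(iter(eta.values())))
        out = {"mu": eta.get("mu", np.zeros(n)),
               "sigma": np.exp(eta["sigma"]) if "sigma" in eta else np.ones(n)}
        out["lam"] = np.exp(eta["lam"]) if "lam" in eta else np.zeros(n)
        return out

    def get_family(self) -> _Family:
        return get_family(self.family, gauss_hermite_rule(self.settings.rule_nodes))


# ------------------------------------------------------------- helpers


def _block_states(design: Design, family: _Family) -> list[_BlockState]:
    states = []
    for p, b in design.all_blocks():
        if p not in family.params:
            continue
        if b.penalized:
            evals = np.linalg.eigvalsh(b.penalty)
            rank = int(np.sum(evals > max(evals.max(), 1e-300) * 1e-10))
            tau2 = 0.1
        else:
            rank, tau2 = 0, None
        states.append(_BlockState(param=p, label=b.label, X=b.matrix, K=b.penalty,
                                  rank=rank, beta=np.zeros(b.n_coef), tau2=tau2))
    return states


def _init_intercepts(y: np.ndarray, family: _Family, states: list[_BlockState],
                     design: Design) -> None:
    pos = y[y > 0]
    z = np.log(pos) if pos.size else np.array([0.0])
    mu0 = float(np.mean(z)) if family.name != "gaussian" else float(np.mean(y))
    sig0 = float(np.log(max(np.std(z) if family.name != "gaussian" else np.std(y), 1e-2)))
    neg = y[y < 0]
    lam0 = float(np.log(max(np.sqrt(np.mean(neg**2)) if neg.size else 0.1, 0.05)))
    for st in states:
        names = next(b.coef_names for b in design.blocks[st.param] if b.label == st.label)
        if "(Intercept)" in names:
            i = names.index("(Intercept)")
            st.beta[i] = {"mu": mu0, "sigma": sig0, "lam": lam0}[st.param]


def _penalty_logprior(states: list[_BlockState]) -> float:
    out = 0.0
    for st in states:
        if st.tau2 is not None:
            out -= 0.5 * float(st.beta @ st.K @ st.beta) / st.tau2
    return out


def _solve_spd(H: np.ndarray, g: np.ndarray) -> np.ndarray:
    for ridge in (0.0, 1e-8, 1e-4, 1e-2, 1.0):
        try:
            return cho_solve(cho_factor(H + ridge * np.eye(H.shape[0])), g)
        except LinAlgError:
            continue
    return np.linalg.lstsq(H, g, rcond=None)[0]


# ------------------------------------------------------------- MAP


def fit_map(records: pd.DataFrame, spec: ModelSpec, family: FamilyName | _Family,
            route=None, settings: SamplerSettings | None = None,
            design: Design | None = None) -> FitResult:
    """Cyclic blockwise Newton maximization of the penalized log-posterior.

    Intercept-only fits reduce to the familiar closed forms (e.g. the
    lognormal MLE mean(log y), sd(log y)); richer predictors are handled by
    backfitting with curvature-based steps and step halving.
    """
    settings = settings or SamplerSettings(map_only=True)
    fam = family if isinstance(family, _Family) else get_family(
        family, gauss_hermite_rule(settings.rule_nodes))
    y = np.asarray(records["value"], float)
    fam.check(y)
    design = design or assemble_design(records, spec, route=route)
    states = _block_states(design, fam)
    _init_intercepts(y, fam, states, design)

    def current_eta() -> dict[str, np.ndarray]:
        eta = {p: np.zeros(design.n_obs) for p in fam.params if design.blocks.get(p)}
        for st in states:
            eta[st.param] = eta[st.param] + st.X @ st.beta
        return eta

    eta = current_eta()
    cur_ll = fam.loglik(y, eta)
    obj = cur_ll + _penalty_logprior(states)
    converged = False
    warnings: list[str] = []
    trace = [obj]
    trace_KS: dict[str, float] = {}
    for _ in range(settings.max_map_cycles):
        for st in states:
            uu, ww = fam.score_weights(y, eta)
            u, w = uu[st.param], ww[st.param]
            H = st.X.T @ (st.X * w[:, None])
            g = st.X.T @ u
            if st.tau2 is not None:
                H = H + st.K / st.tau2
                g = g - st.K @ st.beta / st.tau2
            delta = _solve_spd(H, g)
            if st.tau2 is not None:
                # EM-style expected quadratic form for the tau^2 update below;
                # the trace term prevents the joint-mode collapse at tau^2 = 0
                try:
                    trace_KS[st.label] = float(np.trace(cho_solve(cho_factor(H), st.K)))
                except LinAlgError:
                    trace_KS[st.label] = 0.0
            step = 1.0
            base_eta_p = eta[st.param]
            while step > 1e-3:
                beta_new = st.beta + step * delta
                eta_try = dict(eta)
                eta_try[st.param] = base_eta_p + st.X @ (step * delta)
                pen = 0.0
                if st.tau2 is not None:
                    pen = -0.5 * (float(beta_new @ st.K @ beta_new)
                                  - float(st.beta @ st.K @ st.beta)) / st.tau2
                new_ll = fam.loglik(y, eta_try)
                if new_ll + pen >= cur_ll - 1e-10:
                    st.beta = beta_new
                    eta = eta_try
                    cur_ll = new_ll
                    break
                step /= 2.0
        # empirical-Bayes (EM) update of the variance hyperparameters
        for st in states:
            if st.tau2 is not None:
                quad = float(st.beta @ st.K @ st.beta) + trace_KS.get(st.label, 0.0)
                st.tau2 = max((2.0 * IG_B + quad) / (st.rank + 2.0 * IG_A + 2.0), 1e-8)
        new_obj = cur_ll + _penalty_logprior(states)
        trace.append(new_obj)
        if abs(new_obj - obj) < settings.map_tol * (abs(obj) + 1.0):
            converged = True
            obj = new_obj
            break
        obj = new_obj
    if not converged:
        warnings.append("MAP did not converge within max_map_cycles")

    map_coefs = {st.label: st.beta.copy() for st in states}
    summary = _summary_from_draws(design, states, None, map_coefs)
    return FitResult(
        family=fam.name, design=design, blocks=states, coef_summary=summary,
        map_coefs=map_coefs, draws=None, tau2_draws=None,
        loglik_trace=np.asarray(trace), acceptance={}, settings=settings,
        converged=converged, n_used=len(records), n_total=len(records),
        warnings=warnings,
    )


# ------------------------------------------------------------- MCMC


def run_mcmc(records: pd.DataFrame, spec: ModelSpec, family: FamilyName | _Family,
             settings: SamplerSettings | None = None, route=None,
             map_init: FitResult | None = None) -> FitResult:
    """Blockwise Metropolis-Hastings with curvature-informed proposals.

    Deterministic under a fixed seed and fixed data.  Linear-coefficient
    blocks carry improper flat priors; penalized blocks Gaussian penalty
    priors with conjugate inverse-gamma variance updates.
    """
    settings = settings or SamplerSettings()
    if settings.burn_in >= settings.n_iter:
        raise ValueError("burn_in must be smaller than n_iter")
    fam = family if isinstance(family, _Family) else get_family(
        family, gauss_hermite_rule(settings.rule_nodes))
    y = np.asarray(records["value"], float)
    fam.check(y)
    init = map_init or fit_map(records, spec, family=fam, route=route,
                               settings=SamplerSettings(map_only=True,
                                                        rule_nodes=settings.rule_nodes))
    design = init.design
    states = [
        _BlockState(st.param, st.label, st.X, st.K, st.rank, st.beta.copy(), st.tau2)
        for st in init.blocks
    ]
    rng = np.random.default_rng(settings.seed)

    eta = {p: np.zeros(design.n_obs) for p in fam.params if design.blocks.get(p)}
    for st in states:
        eta[st.param] = eta[st.param] + st.X @ st.beta
    cur_ll = fam.loglik(y, eta)

    def proposal_chol(st: _BlockState) -> np.ndarray:
        w = fam.score_weights(y, eta)[1][st.param]
        H = st.X.T @ (st.X * w[:, None])
        if st.tau2 is not None:
            H = H + st.K / st.tau2
        C = _solve_spd(H, np.eye(H.shape[0]))
        C = 0.5 * (C + C.T)
        for ridge in (0.0, 1e-10, 1e-6):
            try:
                return cholesky(C + ridge * np.eye(C.shape[0]), lower=True)
            except LinAlgError:
                continue
        return np.diag(np.sqrt(np.maximum(np.diag(C), 1e-12)))

    chols = {st.label: proposal_chol(st) for st in states}
    scales = {st.label: 2.38 / max(np.sqrt(st.beta.size), 1.0) for st in states}
    acc_count = {st.label: 0 for st in states}
    win_count = {st.label: [0, 0] for st in states}  # accepted, proposed in window

    draws: dict[str, list[np.ndarray]] = {st.label: [] for st in states}
    tau2_draws: dict[str, list[float]] = {st.label: [] for st in states if st.tau2 is not None}
    trace = []

    for it in range(settings.n_iter):
        for st in states:
            z = rng.standard_normal(st.beta.size)
            delta = scales[st.label] * (chols[st.label] @ z)
            beta_prop = st.beta + delta
            eta_prop = eta[st.param] + st.X @ delta
            eta_try = dict(eta)
            eta_try[st.param] = eta_prop
            new_ll = fam.loglik(y, eta_try)
            dprior = 0.0
            if st.tau2 is not None:
                dprior = -0.5 * (float(beta_prop @ st.K @ beta_prop)
                                 - float(st.beta @ st.K @ st.beta)) / st.tau2
            if np.log(rng.uniform()) < (new_ll - cur_ll + dprior):
                st.beta = beta_prop
                eta = eta_try
                cur_ll = new_ll
                acc_count[st.label] += 1
                win_count[st.label][0] += 1
            win_count[st.label][1] += 1
        # conjugate inverse-gamma updates of the penalty variances
        for st in states:
            if st.tau2 is not None:
                shape = IG_A + 0.5 * st.rank
                rate = IG_B + 0.5 * float(st.beta @ st.K @ st.beta)
                st.tau2 = float(rate / rng.gamma(shape, 1.0))
        if it < settings.burn_in and (it + 1) % 100 == 0:
            # adaptation (burn-in only): refresh curvature, retune scales
            for st in states:
                chols[st.label] = proposal_chol(st)
                a, m = win_count[st.label]
                if m:
                    rate = a / m
                    scales[st.label] *= float(np.exp(1.5 * (rate - 0.25)))
                win_count[st.label] = [0, 0]
        if it >= settings.burn_in and (it - settings.burn_in) % settings.thinning == 0:
            for st in states:
                draws[st.label].append(st.beta.copy())
                if st.tau2 is not None:
                    tau2_draws[st.label].append(st.tau2)
            trace.append(cur_ll)

    draws_arr = {k: np.asarray(v) for k, v in draws.items()}
    tau2_arr = {k: np.asarray(v) for k, v in tau2_draws.items()}
    acceptance = {k: acc_count[k] / settings.n_iter for k in acc_count}
    warnings = [
        f"block {k}: acceptance rate {v:.2f} outside (0.05, 0.95)"
        for k, v in acceptance.items() if not 0.05 < v < 0.95
    ]
    summary = _summary_from_draws(design, states, draws_arr, init.map_coefs)
    return FitResult(
        family=fam.name, design=design, blocks=states, coef_summary=summary,
        map_coefs=init.map_coefs, draws=draws_arr, tau2_draws=tau2_arr,
        loglik_trace=np.asarray(trace), acceptance=acceptance, settings=settings,
        converged=init.converged, n_used=len(records), n_total=len(records),
        warnings=warnings,
    )


def _summary_from_draws(design: Design, states: list[_BlockState],
                        draws: dict[str, np.ndarray] | None,
                        map_coefs: dict[str, np.ndarray]) -> pd.DataFrame:
    rows = []
    name_map = {(p, b.label): b.coef_names for p, b in design.all_blocks()}
    for st in states:
        names = name_map[(st.param, st.label)]
        if draws is not None and st.label in draws and len(draws[st.label]):
            d = draws[st.label]
            mean = d.mean(axis=0)
            lo = np.percentile(d, 2.5, axis=0)
            hi = np.percentile(d, 97.5, axis=0)
            sig = (lo > 0) | (hi < 0)
        else:
            mean = map_coefs[st.label]
            lo = hi = np.full(mean.size, np.nan)
            sig = np.full(mean.size, False)
        for j, nm in enumerate(names):
            rows.append({
                "param": st.param, "block": st.label, "coef": nm,
                "estimate": float(mean[j]), "ci_low": float(lo[j]),
                "ci_high": float(hi[j]),
                "significant": bool(sig[j]) if draws is not None else None,
            })
    return pd.DataFrame(rows)


# ------------------------------------------------------- range profiling

DEFAULT_RANGE_GRID_S = (30.0, 120.0, 600.0, 3600.0)


def profile_gp_range(records: pd.DataFrame, spec: ModelSpec,
                     family: FamilyName | _Family, route=None,
                     ranges_s: tuple[float, ...] = DEFAULT_RANGE_GRID_S,
                     settings: SamplerSettings | None = None) -> tuple[float, pd.DataFrame]:
    """Profile the temporal-GP correlation range over a coarse grid.

    Refits the MAP for each candidate range (every LatentTemporal term gets
    the candidate) and picks the best achieved penalized objective.
    Returns (best range, profile table).  Coarse by design: the range is a
    weakly identified nuisance hyperparameter, and grid profiling keeps the
    sampler stable compared to sampling it.
    """
    from dataclasses import replace as _replace

    from .design import LatentTemporal

    rows = []
    for rho in ranges_s:
        def retag(terms):
            return [(_replace(t, range_s=rho) if isinstance(t, LatentTemporal) else t)
                    for t in terms]

        spec_r = ModelSpec(mu=retag(spec.mu), sigma=retag(spec.sigma),
                           lam=None if spec.lam is None else retag(spec.lam))
        fit = fit_map(records, spec_r, family, route=route, settings=settings)
        rows.append({"range_s": rho, "objective": float(fit.loglik_trace[-1]),
                     "converged": fit.converged})
    table = pd.DataFrame(rows)
    best = float(table.loc[table["objective"].idxmax(), "range_s"])
    return best, table


# ------------------------------------------------------------- effects


def summarize_effects(fit: FitResult, scale: str = "log") -> pd.DataFrame:
    """Effect table on the requested scale.

    log: raw coefficients; log2: beta/log(2) (an effect of 1 doubles the
    expected concentration, all else fixed); percent: 100*(exp(beta)-1).
    """
    if scale not in ("log", "log2", "percent"):
        raise ValueError(f"unknown scale {scale!r}; use log, log2 or percent")

    def tf(x: np.ndarray) -> np.ndarray:
        if scale == "log":
            return x
        if scale == "log2":
            return x / np.log(2.0)
        return 100.0 * (np.exp(x) - 1.0)

    rows = []
    for st in fit.blocks:
        if st.tau2 is not None:  # effect tables report parametric terms
            continue
        names = next(b.coef_names for p, b in fit.design.all_blocks()
                     if b.label == st.label)
        if fit.draws is not None and st.label in fit.draws:
            d = tf(fit.draws[st.label])
            mean, lo, hi = d.mean(axis=0), np.percentile(d, 2.5, axis=0), np.percentile(d, 97.5, axis=0)
            raw = fit.draws[st.label]
            sig = (np.percentile(raw, 2.5, axis=0) > 0) | (np.percentile(raw, 97.5, axis=0) < 0)
        else:
            mean = tf(st.beta)
            lo = hi = np.full(mean.size, np.nan)
            sig = np.full(mean.size, False)
        for j, nm in enumerate(names):
            term, level = (nm[:-1].split("[") + [""])[:2] if "[" in nm else (nm, "")
            rows.append({"param": st.param, "term": term, "level": level,
                         "estimate": float(mean[j]), "ci_low": float(lo[j]),
                         "ci_high": float(hi[j]), "significant": bool(sig[j]),
                         "scale": scale})
    return pd.DataFrame(rows)
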