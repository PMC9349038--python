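"""Lognormal and lognormal-normal convolution (logNNC) distributions.

The logNNC distribution describes a strictly positive lognormal signal
``Y = exp(mu + sigma * Z)`` observed with independent additive Gaussian
instrument noise ``eps ~ N(0, lam**2)``::

    Y_tilde = Y + eps

Its density has no closed form; it is the convolution of a lognormal and a
normal density,

    f(y~) = E_Z[ phi(y~ - exp(mu + sigma*Z); 0, lam^2) ],   Z ~ N(0, 1),

which we approximate by mode-centered segmented Gauss-Legendre quadrature
in z (a peak window sized by the local curvature plus two outer segments
covering the remaining prior mass); a ``QuadRule`` sets the node budget.
All functions broadcast over observation vectors and accept per-observation
parameter vectors, which is what the distributional-regression fitter needs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import logsumexp, ndtr

__all__ = [
    "DistParamTriple",
    "QuadRule",
    "gauss_hermite_rule",
    "lognnc_logpdf",
    "lognnc_cdf",
    "lognnc_sample",
    "lognnc_mean_var",
    "lognormal_logpdf",
    "lognnc_score_eta",
]

# Below this value lam is treated as exactly zero (pure lognormal branch);
# avoids 0/0 in the convolution kernel.
LAM_FLOOR = 1e-8

# exp(mu + sigma*z) is clamped at exp(EXP_CLAMP) so extreme quadrature nodes
# with large sigma cannot overflow; the clamped nodes carry ~zero weight.
EXP_CLAMP = 60.0

_LOG_SQRT_2PI = 0.5 * np.log(2.0 * np.pi)


@dataclass(frozen=True)
class DistParamTriple:
    """The three modeled parameters of one observation.

    mu : mean of the log-concentration (log ug/m3)
    sigma : standard deviation of the log-concentration, > 0
    lam : standard deviation of the additive instrument noise (ug/m3), >= 0
    """

    mu: float | np.ndarray
    sigma: float | np.ndarray
    lam: float | np.ndarray

    def __post_init__(self) -> None:
        mu = np.asarray(self.mu, dtype=float)
        sigma = np.asarray(self.sigma, dtype=float)
        lam = np.asarray(self.lam, dtype=float)
        if not (np.all(np.isfinite(mu)) and np.all(np.isfinite(sigma)) and np.all(np.isfinite(lam))):
            raise ValueError("DistParamTriple requires finite mu, sigma, lam")
        if np.any(sigma <= 0):
            raise ValueError("sigma must be strictly positive")
        if np.any(lam < 0):
            raise ValueError("lam must be non-negative")

    def broadcast(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        return np.broadcast_arrays(
            np.asarray(self.mu, float),
            np.asarray(self.sigma, float),
            np.asarray(self.lam, float),
        )


@dataclass(frozen=True)
class QuadRule:
    """Gauss-Hermite nodes/weights normalized for expectations against N(0,1)."""

    nodes: np.ndarray
    weights: np.ndarray

    def __post_init__(self) -> None:
        if self.nodes.shape != self.weights.shape or self.nodes.ndim != 1:
            raise ValueError("nodes and weights must be 1-d arrays of equal length")
        if self.nodes.size < 2:
            raise ValueError("quadrature rule needs at least 2 nodes")
        if np.any(self.weights <= 0):
            raise ValueError("weights must be positive")


def gauss_hermite_rule(n_nodes: int = 64) -> QuadRule:
    """Probabilists' Gauss-Hermite rule: ``sum w_i g(x_i) ~ E[g(Z)], Z~N(0,1)``.

    Weights are normalized to sum to one so the rule is an expectation
    operator; nodes are symmetric about zero.
    """
    if n_nodes < 2:
        raise ValueError("n_nodes must be >= 2")
    nodes, weights = np.polynomial.hermite_e.hermegauss(n_nodes)
    weights = weights / weights.sum()
    return QuadRule(nodes=nodes, weights=weights)


_DEFAULT_RULE = gauss_hermite_rule(64)


def _as_params(p: DistParamTriple) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    mu, sigma, lam = p.broadcast()
    return mu, sigma, lam


def lognormal_logpdf(y: np.ndarray, mu: np.ndarray, sigma: np.ndarray) -> np.ndarray:
    """Lognormal log-density; -inf for y <= 0."""
    y = np.asarray(y, float)
    shape = np.broadcast_shapes(y.shape, np.shape(mu), np.shape(sigma))
    out = np.full(shape, -np.inf)
    y_b = np.broadcast_to(y, shape)
    pos = y_b > 0
    if np.any(pos):
        logy = np.log(np.where(pos, y_b, 1.0))
        mu_b = np.broadcast_to(mu, shape)
        sig_b = np.broadcast_to(sigma, shape)
        z = (logy - mu_b) / sig_b
        val = -logy - np.log(sig_b) - _LOG_SQRT_2PI - 0.5 * z**2
        out[pos] = val[pos]
    return out


_GL_X, _GL_W = np.polynomial.legendre.leggauss(24)

_LEGGAUSS_CACHE: dict[int, tuple[np.ndarray, np.ndarray]] = {}


def _leggauss_cached(n: int) -> tuple[np.ndarray, np.ndarray]:
    if n not in _LEGGAUSS_CACHE:
        _LEGGAUSS_CACHE[n] = np.polynomial.legendre.leggauss(n)
    return _LEGGAUSS_CACHE[n]

_CDF_GRID: tuple[np.ndarray, np.ndarray] | None = None


def _cdf_grid() -> tuple[np.ndarray, np.ndarray]:
    """Fixed composite-Simpson grid for E_Z[Phi((y - exp(mu+sigma Z))/lam)].

    A fixed grid (rather than a mode-adapted one) keeps the CDF exactly
    non-decreasing in y: it is a positive combination of normal CDFs.
    Step 0.02 over [-9, 9] resolves the sigmoid transition of the integrand
    down to widths of a few hundredths in z.
    """
    global _CDF_GRID
    if _CDF_GRID is None:
        n = 901  # odd -> composite Simpson
        z = np.linspace(-9.0, 9.0, n)
        h = z[1] - z[0]
        w = np.full(n, 2.0)
        w[1::2] = 4.0
        w[0] = w[-1] = 1.0
        w *= h / 3.0
        cw = w * np.exp(-0.5 * z**2) / np.sqrt(2.0 * np.pi)
        _CDF_GRID = (z, cw)
    return _CDF_GRID


def _find_mode(y: np.ndarray, mu: np.ndarray, sigma: np.ndarray,
               lam: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Mode and curvature scale of h(z) = log N(y - e^(mu+sigma z); 0, lam^2) - z^2/2.

    The convolution integrand can be much narrower than the N(0,1) prior
    over z (sharp noise kernel at large signal values), so the quadrature
    rule is recentered at the mode and rescaled by the local curvature.
    A coarse scan plus the signal-matching point z_y = (log y - mu)/sigma
    guards against bimodal integrands before Newton refinement.
    """
    grid = np.linspace(-8.0, 8.0, 17)
    cand = np.broadcast_to(grid, (y.size, grid.size)).copy()
    with np.errstate(divide="ignore", invalid="ignore"):
        zy = np.where(y > 0, (np.log(np.maximum(y, 1e-300)) - mu) / sigma, 0.0)
    cand = np.concatenate([cand, np.clip(zy, -30.0, 30.0)[:, None]], axis=1)
    m = np.exp(np.clip(mu[:, None] + sigma[:, None] * cand, None, EXP_CLAMP))
    h = -0.5 * ((y[:, None] - m) / lam[:, None]) ** 2 - 0.5 * cand**2
    z = np.take_along_axis(cand, np.argmax(h, axis=1)[:, None], axis=1)[:, 0]
    lam2 = lam**2
    for _ in range(15):
        m = np.exp(np.clip(mu + sigma * z, None, EXP_CLAMP))
        h1 = (y - m) * m * sigma / lam2 - z
        h2 = sigma**2 * m * (y - 2.0 * m) / lam2 - 1.0
        step = h1 / np.minimum(h2, -1e-3)
        z = z - np.clip(step, -2.0, 2.0)
    m = np.exp(np.clip(mu + sigma * z, None, EXP_CLAMP))
    h2 = sigma**2 * m * (y - 2.0 * m) / lam2 - 1.0
    s = 1.0 / np.sqrt(np.maximum(-h2, 1e-8))
    return z, np.minimum(s, 3.0)


def _log_kernel(y_tilde: np.ndarray, mu: np.ndarray, sigma: np.ndarray,
                lam: np.ndarray, rule: QuadRule) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Log quadrature terms of the convolution integral f = int phi(z) k(z) dz,
    k(z) = N(y~ - exp(mu + sigma z); 0, lam^2).

    Three Gauss-Legendre segments: one over the mode window
    [z* - 8 s, z* + 8 s] (resolving a peak that may be much narrower than
    the N(0,1) prior over z), and two covering the remaining prior mass on
    either side, where the noise kernel may plateau.  Segmented
    Gauss-Legendre is used rather than a rescaled Gauss-Hermite rule
    because the integrand is strongly skewed (sharp mode, prior-scale
    tail), which defeats the Gaussian-shape assumption of adaptive GH.
    The rule argument sets the mode-window node budget.  Returns
    (logterms, m, z), shapes (n, K_total); the log-density is
    logsumexp(logterms, axis=1).
    """
    zstar, s = _find_mode(y_tilde, mu, sigma, lam)
    s_win = np.minimum(s, 1.0)

    # the mode window gets twice the rule's node budget: the integrand can
    # carry a steep kernel cutoff inside the window on top of the peak
    glx, glw = _leggauss_cached(2 * rule.nodes.size)
    a = zstar - 7.0 * s_win
    b = zstar + 7.0 * s_win
    z_mid = 0.5 * (a + b)[:, None] + 0.5 * (b - a)[:, None] * glx[None, :]
    logc_mid = (np.log(glw)[None, :] + np.log(0.5 * (b - a))[:, None]
                - 0.5 * z_mid**2 - _LOG_SQRT_2PI)
    lo = np.minimum(a - 0.5, -9.0)
    hi = np.maximum(b + 0.5, 9.0)
    t = _GL_X[None, :]
    logW = np.log(_GL_W)[None, :]
    z_lo = 0.5 * (lo + a)[:, None] + 0.5 * (a - lo)[:, None] * t
    z_hi = 0.5 * (b + hi)[:, None] + 0.5 * (hi - b)[:, None] * t
    logc_lo = logW + np.log(0.5 * (a - lo))[:, None] - 0.5 * z_lo**2 - _LOG_SQRT_2PI
    logc_hi = logW + np.log(0.5 * (hi - b))[:, None] - 0.5 * z_hi**2 - _LOG_SQRT_2PI

    z = np.concatenate([z_mid, z_lo, z_hi], axis=1)
    logc = np.concatenate([logc_mid, logc_lo, logc_hi], axis=1)
    m = np.exp(np.clip(mu[:, None] + sigma[:, None] * z, None, EXP_CLAMP))
    r = y_tilde[:, None] - m
    logterms = logc - np.log(lam[:, None]) - _LOG_SQRT_2PI - 0.5 * (r / lam[:, None]) ** 2
    return logterms, m, z


def lognnc_logpdf(y_tilde, p: DistParamTriple, rule: QuadRule | None = None):
    """Log-density of the lognormal-normal convolution.

    For ``lam == 0`` (below the numerical floor) the pure lognormal branch is
    used: finite for positive observations, ``-inf`` otherwise.  For
    ``lam > 0`` the density is finite at every real observation, including
    negative ones, and is computed by a log-sum-exp over quadrature nodes.
    """
    rule = rule or _DEFAULT_RULE
    y = np.atleast_1d(np.asarray(y_tilde, dtype=float))
    if not np.all(np.isfinite(y)):
        raise ValueError("y_tilde must be finite")
    mu, sigma, lam = _as_params(p)
    mu, sigma, lam = np.broadcast_arrays(*np.atleast_1d(mu, sigma, lam))
    shape = np.broadcast_shapes(y.ravel().shape, mu.shape)
    y_b = np.broadcast_to(y.ravel(), shape)
    mu, sigma, lam = (np.broadcast_to(a, shape) for a in (mu, sigma, lam))

    out = np.empty(mu.shape, dtype=float)
    zero = lam < LAM_FLOOR
    if np.any(zero):
        out[zero] = lognormal_logpdf(y_b[zero], mu[zero], sigma[zero])
    conv = ~zero
    if np.any(conv):
        logterms, _, _ = _log_kernel(y_b[conv], mu[conv], sigma[conv], lam[conv], rule)
        out[conv] = logsumexp(logterms, axis=1)
    if np.isscalar(y_tilde) and out.size == 1:
        return float(out[0])
    return out


def lognnc_cdf(y_tilde, p: DistParamTriple, rule: QuadRule | None = None):
    """CDF of the convolution: ``F(y~) = E_Z[Phi((y~ - exp(mu+sigma Z))/lam)]``.

    Reduces to the lognormal CDF when lam == 0.
    """
    rule = rule or _DEFAULT_RULE
    y = np.atleast_1d(np.asarray(y_tilde, dtype=float))
    if not np.all(np.isfinite(y)):
        raise ValueError("y_tilde must be finite")
    mu, sigma, lam = _as_params(p)
    mu, sigma, lam = np.broadcast_arrays(*np.atleast_1d(mu, sigma, lam))
    shape = np.broadcast_shapes(y.ravel().shape, mu.shape)
    y_b = np.broadcast_to(y.ravel(), shape)
    mu, sigma, lam = (np.broadcast_to(a, shape) for a in (mu, sigma, lam))

    out = np.empty(shape, dtype=float)
    zero = lam < LAM_FLOOR
    if np.any(zero):
        val = np.zeros(int(zero.sum()))
        pos = y_b[zero] > 0
        val[pos] = ndtr((np.log(y_b[zero][pos]) - mu[zero][pos]) / sigma[zero][pos])
        out[zero] = val
    conv = ~zero
    if np.any(conv):
        zg, cw = _cdf_grid()
        yc, mc, sc, lc = y_b[conv], mu[conv], sigma[conv], lam[conv]
        vals = np.empty(yc.size)
        for lo_i in range(0, yc.size, 2048):  # bound the n x grid temporaries
            sl = slice(lo_i, lo_i + 2048)
            m = np.exp(np.clip(mc[sl][:, None] + sc[sl][:, None] * zg[None, :], None, EXP_CLAMP))
            vals[sl] = ndtr((yc[sl][:, None] - m) / lc[sl][:, None]) @ cw
        out[conv] = vals
    out = np.clip(out, 0.0, 1.0)
    if np.isscalar(y_tilde) and out.size == 1:
        return float(out[0])
    return out


def lognnc_sample(n: int, p: DistParamTriple, seed: int | np.random.Generator) -> np.ndarray:
    """Draw ``Y~ = exp(mu + sigma Z) + eps`` with ``eps ~ N(0, lam^2)``."""
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    mu, sigma, lam = _as_params(p)
    y = np.exp(mu + sigma * rng.standard_normal(n))
    return y + lam * rng.standard_normal(n)


def lognnc_mean_var(p: DistParamTriple) -> tuple[np.ndarray, np.ndarray]:
    """Mean and variance of the convolution.

    mean = exp(mu + sigma^2/2); the noise is zero-mean so it only adds
    lam^2 to the lognormal variance (exp(sigma^2)-1) exp(2 mu + sigma^2).
    """
    mu, sigma, lam = _as_params(p)
    mean = np.exp(mu + sigma**2 / 2.0)
    var = (np.exp(sigma**2) - 1.0) * np.exp(2.0 * mu + sigma**2) + lam**2
    if mean.ndim == 0:
        return float(mean), float(var)
    return mean, var


def lognnc_score_eta(y_tilde: np.ndarray, mu: np.ndarray, sigma: np.ndarray,
                     lam: np.ndarray, rule: QuadRule | None = None) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-observation score of the logNNC log-likelihood w.r.t. the three
    linear predictors (identity link for mu, log links for sigma and lam).

    Differentiates through the fixed quadrature rule, so the score is exact
    for the quadrature-approximated likelihood the sampler actually uses.
    Returns (d/d eta_mu, d/d eta_sigma, d/d eta_lam), each shape (n,).
    """
    rule = rule or _DEFAULT_RULE
    y = np.asarray(y_tilde, float)
    logterms, m, z = _log_kernel(y, mu, sigma, lam, rule)
    logf = logsumexp(logterms, axis=1)
    pk = np.exp(logterms - logf[:, None])  # posterior node weights, rows sum to 1
    r = y[:, None] - m
    lam2 = (lam**2)[:, None]
    d_mu = np.sum(pk * r * m / lam2, axis=1)
    d_sigma = np.sum(pk * r * m * z / lam2, axis=1)
    d_lam = np.sum(pk * (r**2 / lam2 - 1.0), axis=1) / lam
    # chain rule for the log links
    return d_mu, d_sigma * sigma, d_lam * lam


def lognnc_score_hess_eta(y_tilde: np.ndarray, mu: np.ndarray, sigma: np.ndarray,
                          lam: np.ndarray, rule: QuadRule | None = None
                          ) -> tuple[tuple[np.ndarray, np.ndarray, np.ndarray],
                                     tuple[np.ndarray, np.ndarray, np.ndarray]]:
    """Score and negative second derivative of the log-likelihood w.r.t. the
    three linear predictors, from a single quadrature pass.

    With per-node terms t_k and posterior node weights p_k = t_k / f, the
    score is u = sum_k p_k a_k (a_k = d log t_k / d eta) and the second
    derivative is sum_k p_k (da_k/d eta + a_k^2) - u^2.  Returns
    ((u_mu, u_sig, u_lam), (w_mu, w_sig, w_lam)); the w are clamped to be
    positive so they can serve as IWLS working weights.
    """
    rule = rule or _DEFAULT_RULE
    y = np.asarray(y_tilde, float)
    logterms, m, z = _log_kernel(y, mu, sigma, lam, rule)
    logf = logsumexp(logterms, axis=1)
    pk = np.exp(logterms - logf[:, None])
    r = y[:, None] - m
    lam2 = (lam**2)[:, None]
    sig = sigma[:, None]

    a_mu = r * m / lam2
    a_sig = a_mu * z * sig
    a_lam = r**2 / lam2 - 1.0
    da_mu = m * (r - m) / lam2
    da_sig = sig * z * (m * sig * z * (r - m) + r * m) / lam2
    da_lam = -2.0 * r**2 / lam2

    u, w = [], []
    for a, da in ((a_mu, da_mu), (a_sig, da_sig), (a_lam, da_lam)):
        ui = np.sum(pk * a, axis=1)
        d2 = np.sum(pk * (da + a**2), axis=1) - ui**2
        u.append(ui)
        w.append(np.maximum(-d2, 1e-4))
    return (u[0], u[1], u[2]), (w[0], w[1], w[2])
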