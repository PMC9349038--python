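"""Model criticism for the distributional fits.

Quantile residuals r = Phi^-1(F(y|x)) are standard normal when the model's
conditional distribution F is correct, so normal Q-Q comparisons, KS tests
and autocorrelation functions of r diagnose the fit.  Residuals are
computed at posterior-mean parameters (one Q-Q curve per model); for
truncated lognormal fits evaluated on data containing non-positive values,
those observations have F = 0 and their residuals would be -inf — they are
clipped and flagged instead of silently dropped.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import ndtri
from scipy.stats import norm

from .family import DistParamTriple, lognnc_logpdf, lognormal_logpdf
from .fit import FitResult

__all__ = [
    "ResidualSet",
    "quantile_residuals",
    "qq_summary",
    "residual_acf",
    "deconvolved_density",
    "variance_explained_share",
]

RESID_CLIP = 8.0


@dataclass
class ResidualSet:
    r: np.ndarray
    time: np.ndarray
    round_id: np.ndarray
    segment_id: np.ndarray
    finite_mask: np.ndarray

    def __post_init__(self):
        n = self.r.size
        if not all(a.size == n for a in (self.time, self.round_id, self.segment_id, self.finite_mask)):
            raise ValueError("misaligned residual components")

    @property
    def finite(self) -> np.ndarray:
        return self.r[self.finite_mask]


def quantile_residuals(fit: FitResult, records: pd.DataFrame) -> ResidualSet:
    """Quantile residuals at posterior-mean (or MAP) parameters.

    F values of exactly 0 or 1 (e.g. non-positive observations under a
    truncated lognormal fit) are clipped to +-RESID_CLIP and flagged
    non-finite in the mask.
    """
    fam = fit.get_family()
    y = np.asarray(records["value"], float)
    eta = fit.eta(records)
    F = np.asarray(fam.cdf(y, eta))
    finite = (F > 0.0) & (F < 1.0)
    r = np.empty(y.size)
    tiny = norm.cdf(-RESID_CLIP)
    r[finite] = ndtri(np.clip(F[finite], tiny, 1.0 - tiny))
    r[~finite] = np.where(F[~finite] <= 0.0, -RESID_CLIP, RESID_CLIP)
    return ResidualSet(
        r=r,
        time=np.asarray(records.get("time", pd.RangeIndex(len(records))), float),
        round_id=np.asarray(records.get("round_id", np.zeros(len(records)))).astype(str),
        segment_id=np.asarray(records.get("segment_id", np.zeros(len(records)))).astype(str),
        finite_mask=finite,
    )


def qq_summary(res: ResidualSet, probs: np.ndarray | None = None) -> pd.DataFrame:
    """Empirical vs theoretical standard-normal quantiles of the residuals.

    Includes the 1st/99th percentile rows used to judge whether the bulk of
    the residual distribution follows the reference line.
    """
    r = res.finite
    if r.size < 10:
        raise ValueError("need at least 10 finite residuals for a Q-Q summary")
    if probs is None:
        probs = np.concatenate([[0.01], np.linspace(0.05, 0.95, 19), [0.99]])
    emp = np.quantile(r, probs)
    theo = ndtri(probs)
    out = pd.DataFrame({"prob": probs, "theoretical": theo, "empirical": emp,
                        "deviation": emp - theo})
    out.attrs["qq_correlation"] = float(np.corrcoef(
        np.sort(r), ndtri((np.arange(1, r.size + 1) - 0.5) / r.size))[0, 1])
    out.attrs["tail_dev_1"] = float(out.loc[out["prob"] == 0.01, "deviation"].iloc[0])
    out.attrs["tail_dev_99"] = float(out.loc[out["prob"] == 0.99, "deviation"].iloc[0])
    return out


def residual_acf(res: ResidualSet, lags_s: list[float],
                 sampling_interval_s: float = 10.0) -> pd.DataFrame:
    """Residual autocorrelation at the requested lags (seconds).

    Pairs are formed within rounds only; cross-round pairs would mix
    day-to-day differences into the serial structure.  Lags that are not
    multiples of the sampling interval are rounded with a warning.
    """
    import warnings

    df = pd.DataFrame({"r": res.r, "round": res.round_id}).loc[res.finite_mask]
    out = []
    for lag in lags_s:
        steps = lag / sampling_interval_s
        k = int(round(steps))
        if abs(steps - k) > 1e-9:
            warnings.warn(f"lag {lag}s is not a multiple of {sampling_interval_s}s; using {k * sampling_interval_s}s")
        if k == 0:
            out.append({"lag_s": lag, "acf": 1.0, "n_pairs": len(df)})
            continue
        x = df.groupby("round", sort=False)["r"]
        shifted = x.shift(k)
        valid = shifted.notna()
        a = df.loc[valid, "r"].to_numpy()
        b = shifted[valid].to_numpy()
        mu, sd = df["r"].mean(), df["r"].std()
        acf = float(np.mean((a - mu) * (b - mu)) / sd**2) if valid.any() else np.nan
        out.append({"lag_s": k * sampling_interval_s, "acf": acf, "n_pairs": int(valid.sum())})
    return pd.DataFrame(out)


def deconvolved_density(fit: FitResult, records: pd.DataFrame,
                        subset: np.ndarray | None = None,
                        grid: np.ndarray | None = None,
                        n_draws: int = 500,
                        rng: np.random.Generator | int = 0) -> pd.DataFrame:
    """Model densities for a record subset, deconvolved into components.

    Aggregates per-observation model densities over the subset: the
    lognormal signal component, the zero-mean Gaussian instrument-error
    component, and their convolution (the distribution of the observed
    values).  Posterior uncertainty bands come from recomputing the signal
    curve under posterior coefficient draws.
    """
    if subset is None:
        subset = np.ones(len(records), bool)
    subset = np.asarray(subset, bool)
    if not subset.any():
        raise ValueError("empty record subset")
    if grid is None:
        v = records.loc[subset, "value"]
        grid = np.linspace(float(v.min()) - 1.0, float(v.max()) + 1.0, 201)
    sub = records.loc[subset]
    pars = fit.predict_params(sub)
    mu, sig, lam = pars["mu"], pars["sigma"], pars["lam"]

    def curves(mu, sig, lam):
        signal = np.exp(lognormal_logpdf(grid[:, None], mu[None, :], sig[None, :])).mean(axis=1)
        if np.all(lam < 1e-8):
            return signal, np.zeros_like(grid), signal
        error = norm.pdf(grid[:, None], 0.0, np.maximum(lam, 1e-8)[None, :]).mean(axis=1)
        conv = np.stack([
            np.exp(lognnc_logpdf(grid, DistParamTriple(np.full_like(grid, m), np.full_like(grid, s),
                                                       np.full_like(grid, l))))
            for m, s, l in zip(mu, sig, lam)
        ]).mean(axis=0) if mu.size <= 200 else _conv_curve(grid, mu, sig, lam)
        return signal, error, conv

    signal, error, conv = curves(mu, sig, lam)
    out = pd.DataFrame({"y": grid, "signal": signal, "error": error, "convolved": conv})

    if fit.draws is not None and n_draws > 0:
        rng = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
        some = next(iter(fit.draws.values()))
        take = rng.choice(some.shape[0], size=min(n_draws, some.shape[0]), replace=False)
        sig_draws = []
        for t in take:
            coefs = {lbl: d[t] for lbl, d in fit.draws.items()}
            eta = {p: np.zeros(len(sub)) for p in fit.design.params()}
            for p in fit.design.params():
                for b in fit.design.blocks[p]:
                    eta[p] += b.builder(sub) @ coefs[b.label]
            mu_d, sig_d = eta["mu"], np.exp(eta["sigma"])
            sig_draws.append(np.exp(lognormal_logpdf(grid[:, None], mu_d[None, :], sig_d[None, :])).mean(axis=1))
        sd = np.stack(sig_draws)
        out["signal_lo"] = np.percentile(sd, 2.5, axis=0)
        out["signal_hi"] = np.percentile(sd, 97.5, axis=0)
    return out


def _conv_curve(grid, mu, sig, lam):
    # average the convolved density over many records, chunked over the grid
    acc = np.zeros(grid.size)
    for g in range(grid.size):
        acc[g] = np.exp(lognnc_logpdf(np.full(mu.size, grid[g]),
                                      DistParamTriple(mu, sig, lam))).mean()
    return acc


def variance_explained_share(true_values, noise_sd: float) -> float:
    """Share of observed variance a perfect concentration model can explain.

    With true concentrations varying with sample variance s^2 and additive
    instrument noise of standard deviation ``noise_sd``, predictions from a
    perfect model achieve R^2 = s^2 / (s^2 + noise_sd^2).
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be non-negative")
    v = np.asarray(true_values, float)
    if v.size < 2:
        raise ValueError("need at least two true values")
    s2 = float(np.var(v, ddof=1))
    if s2 == 0.0 and noise_sd == 0.0:
        raise ValueError("variance share undefined for identical values and zero noise")
    return s2 / (s2 + noise_sd**2)
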