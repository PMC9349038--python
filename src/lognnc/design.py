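"""Design matrices and penalties for the additive distributional predictors.

Each of the three distribution parameters (mu, sigma, lam) gets its own
additive predictor built from intercepts, linear terms, reference-coded
categorical effects, penalized cubic regression splines, and latent
spatiotemporal fields.  Links: identity for mu, log for sigma and lam.

Splines are cubic B-splines with knots at empirical quantiles and an
integrated-squared-second-derivative penalty; each spline is reparameterized
into the null space of a sum-to-zero constraint over the training
observations so the intercept stays identifiable.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Literal

import numpy as np
import pandas as pd
from scipy.interpolate import BSpline
from scipy.linalg import null_space

__all__ = [
    "DesignBlock",
    "Term",
    "Intercept",
    "Linear",
    "Categorical",
    "Spline",
    "TrafficSpline",
    "LatentSpatial",
    "LatentTemporal",
    "ModelSpec",
    "Design",
    "encode_categorical",
    "cubic_spline_basis",
    "constrained_traffic_spline",
    "assemble_design",
    "leipzig_spec",
    "rome_spec",
]

ParamName = Literal["mu", "sigma", "lam"]
PARAM_NAMES: tuple[str, ...] = ("mu", "sigma", "lam")


@dataclass
class DesignBlock:
    """One additive component of a predictor: matrix, penalty, names.

    ``penalty`` is symmetric PSD with the same dimension as the matrix
    columns; an all-zero penalty means an improper flat prior (parametric
    effects).  ``builder`` maps a new record table to the matching design
    matrix using the transforms frozen at training time.
    """

    label: str
    target: str
    matrix: np.ndarray
    penalty: np.ndarray
    coef_names: list[str]
    builder: Callable[[pd.DataFrame], np.ndarray] | None = None

    def __post_init__(self) -> None:
        if self.matrix.ndim != 2 or self.penalty.shape != (self.matrix.shape[1],) * 2:
            raise ValueError(f"block {self.label}: penalty/matrix dimensions disagree")
        if not np.allclose(self.penalty, self.penalty.T):
            raise ValueError(f"block {self.label}: penalty not symmetric")

    @property
    def n_coef(self) -> int:
        return self.matrix.shape[1]

    @property
    def penalized(self) -> bool:
        return bool(np.any(self.penalty))


# ---------------------------------------------------------------- terms


@dataclass(frozen=True)
class Term:
    pass


@dataclass(frozen=True)
class Intercept(Term):
    pass


@dataclass(frozen=True)
class Linear(Term):
    covariate: str


@dataclass(frozen=True)
class Categorical(Term):
    covariate: str
    reference: str
    levels: tuple[str, ...] | None = None  # declared order; inferred if None


@dataclass(frozen=True)
class Spline(Term):
    covariate: str
    n_knots: int = 8


@dataclass(frozen=True)
class TrafficSpline(Term):
    """Traffic-count spline: zero-mean on primary-road rows, zero elsewhere."""

    covariate: str = "count"
    primary_flag: str = "on_primary"
    n_knots: int = 8


@dataclass(frozen=True)
class LatentSpatial(Term):
    """Intrinsic first-order GMRF over route segments (sum-to-zero)."""

    variance: float = 0.1


@dataclass(frozen=True)
class LatentTemporal(Term):
    """Zero-mean GP over campaign time with exponential correlation."""

    range_s: float = 600.0
    variance: float = 0.1
    n_knots: int = 50


@dataclass
class ModelSpec:
    """Declarative additive predictors for the three parameters."""

    mu: list[Term] = field(default_factory=lambda: [Intercept()])
    sigma: list[Term] = field(default_factory=lambda: [Intercept()])
    lam: list[Term] | None = None  # None: family has no lam predictor

    def __post_init__(self) -> None:
        if self.lam is not None:
            for t in self.lam:
                if not isinstance(t, (Intercept, LatentTemporal)):
                    raise ValueError(
                        "the lam predictor admits only an intercept and an "
                        "optional temporal latent field; instrument noise "
                        "must not depend on covariates"
                    )
        for pname in ("mu", "sigma", "lam"):
            terms = getattr(self, pname) or []
            seen: set[str] = set()
            for t in terms:
                if isinstance(t, (Spline, TrafficSpline)):
                    if t.covariate in seen:
                        raise ValueError(f"duplicate spline on {t.covariate!r} in {pname}")
                    seen.add(t.covariate)

    def terms_for(self, param: str) -> list[Term]:
        terms = getattr(self, param)
        return list(terms) if terms is not None else []

    def to_dict(self) -> dict:
        def enc(t: Term) -> dict:
            d = {"kind": type(t).__name__}
            for f_ in getattr(t, "__dataclass_fields__", {}):
                v = getattr(t, f_)
                d[f_] = list(v) if isinstance(v, tuple) else v
            return d

        return {p: ([enc(t) for t in getattr(self, p)] if getattr(self, p) is not None else None)
                for p in PARAM_NAMES}

    @classmethod
    def from_dict(cls, d: dict) -> "ModelSpec":
        kinds = {c.__name__: c for c in
                 (Intercept, Linear, Categorical, Spline, TrafficSpline,
                  LatentSpatial, LatentTemporal)}

        def dec(item: dict) -> Term:
            item = dict(item)
            k = kinds[item.pop("kind")]
            for key, v in item.items():
                if isinstance(v, list):
                    item[key] = tuple(v)
            return k(**item)

        kw = {}
        for p in PARAM_NAMES:
            v = d.get(p)
            kw[p] = None if v is None else [dec(t) for t in v]
        if kw["mu"] is None:
            kw["mu"] = [Intercept()]
        if kw["sigma"] is None:
            kw["sigma"] = [Intercept()]
        return cls(**kw)

    def replace_sigma_intercept_only(self) -> "ModelSpec":
        return ModelSpec(mu=list(self.mu), sigma=[Intercept()], lam=None if self.lam is None else list(self.lam))


# ---------------------------------------------------------------- encoders


def encode_categorical(levels, reference: str, declared: tuple[str, ...] | None = None,
                       covariate: str = "x", target: str = "mu") -> DesignBlock:
    """Reference-coded indicator block: one column per non-reference level.

    Rows at the reference level are all-zero; unseen levels at prediction
    time raise an error naming the offending level.
    """
    s = pd.Series(levels).astype(str)
    order = list(declared) if declared is not None else sorted(s.unique())
    if reference not in order:
        raise ValueError(f"reference level {reference!r} not among levels {order}")
    non_ref = [l for l in order if l != reference]
    if not non_ref:
        import warnings

        warnings.warn(f"categorical {covariate!r} has a single level; no columns generated")

    def build(values) -> np.ndarray:
        v = pd.Series(values).astype(str)
        unknown = set(v.unique()) - set(order)
        if unknown:
            raise ValueError(f"unknown level(s) {sorted(unknown)} for covariate {covariate!r}")
        return np.column_stack([(v == l).to_numpy(float) for l in non_ref]) if non_ref else np.empty((len(v), 0))

    X = build(s)
    k = len(non_ref)
    return DesignBlock(
        label=f"{target}:{covariate}",
        target=target,
        matrix=X,
        penalty=np.zeros((k, k)),
        coef_names=[f"{covariate}[{l}]" for l in non_ref],
        builder=lambda df: build(df[covariate]),
    )


def _bspline_design(x: np.ndarray, t: np.ndarray) -> np.ndarray:
    x = np.clip(x, t[3], t[-4])  # evaluate within the knot range
    return BSpline.design_matrix(x, t, 3).toarray()


def _second_derivative_penalty(t: np.ndarray) -> np.ndarray:
    """Exact integral of B_i'' B_j'' over the knot span (2-pt Gauss-Legendre
    per interval; the product of second derivatives of cubics is quadratic)."""
    k = len(t) - 4
    interior = np.unique(t[3:-3])
    gl_x = np.array([-1.0, 1.0]) / np.sqrt(3.0)
    pts, wts = [], []
    for a, b in zip(interior[:-1], interior[1:]):
        pts.extend(0.5 * (a + b) + 0.5 * (b - a) * gl_x)
        wts.extend([0.5 * (b - a)] * 2)
    pts, wts = np.asarray(pts), np.asarray(wts)
    D2 = np.column_stack([
        BSpline(t, np.eye(k)[i], 3).derivative(2)(pts) for i in range(k)
    ])
    return (D2 * wts[:, None]).T @ D2


def _quantile_knots(x: np.ndarray, n_knots: int) -> np.ndarray:
    ux = np.unique(x)
    if ux.size < n_knots:
        raise ValueError(f"need at least {n_knots} unique values, got {ux.size}")
    inner = np.quantile(ux, np.linspace(0.0, 1.0, n_knots))
    inner = np.unique(inner)
    if inner.size < 4:
        raise ValueError("degenerate knot sequence; increase data spread or lower n_knots")
    return np.concatenate([[inner[0]] * 3, inner, [inner[-1]] * 3])


def cubic_spline_basis(x, n_knots: int = 8, covariate: str = "x", target: str = "mu") -> DesignBlock:
    """Centered cubic regression spline with a second-derivative penalty.

    Knots sit at empirical quantiles.  The basis is reparameterized into the
    null space of the sum-to-zero constraint over the training x, removing
    the constant direction so the block is identifiable next to an
    intercept; linear functions remain in the penalty null space.
    """
    if n_knots < 3:
        raise ValueError("n_knots must be >= 3")
    x = np.asarray(x, float)
    if not np.all(np.isfinite(x)):
        raise ValueError("x must be finite")
    t = _quantile_knots(x, n_knots)
    B = _bspline_design(x, t)
    P = _second_derivative_penalty(t)
    constraint = B.mean(axis=0, keepdims=True)
    Z = null_space(constraint)
    Xc = B @ Z
    Pc = Z.T @ P @ Z

    def build(df: pd.DataFrame) -> np.ndarray:
        return _bspline_design(np.asarray(df[covariate], float), t) @ Z

    return DesignBlock(
        label=f"{target}:s({covariate})",
        target=target,
        matrix=Xc,
        penalty=0.5 * (Pc + Pc.T),
        coef_names=[f"s({covariate}).{i + 1}" for i in range(Xc.shape[1])],
        builder=build,
    )


def constrained_traffic_spline(count, on_primary, n_knots: int = 8,
                               covariate: str = "count", target: str = "mu") -> DesignBlock:
    """Traffic-count spline, zero mean over primary-road rows, exactly zero
    elsewhere (keeps street-class effects interpretable)."""
    on_primary = np.asarray(on_primary, bool)
    if not on_primary.any():
        raise ValueError("no primary-road observations: traffic spline undefined")
    count = np.asarray(count, float)
    cp = count[on_primary]
    if not np.all(np.isfinite(cp)):
        raise ValueError("count must be finite wherever on_primary is true")
    t = _quantile_knots(cp, n_knots)
    Bp = _bspline_design(cp, t)
    P = _second_derivative_penalty(t)
    constraint = Bp.mean(axis=0, keepdims=True)  # zero mean on primary rows
    Z = null_space(constraint)

    def build_from(cnt: np.ndarray, prim: np.ndarray) -> np.ndarray:
        X = np.zeros((len(prim), Z.shape[1]))
        if prim.any():
            X[prim] = _bspline_design(cnt[prim], t) @ Z
        return X

    Pc = Z.T @ P @ Z
    return DesignBlock(
        label=f"{target}:s({covariate})",
        target=target,
        matrix=build_from(count, on_primary),
        penalty=0.5 * (Pc + Pc.T),
        coef_names=[f"s({covariate}).{i + 1}" for i in range(Z.shape[1])],
        builder=lambda df: build_from(
            np.asarray(df[covariate], float),
            np.asarray(df[TrafficSpline.primary_flag] if TrafficSpline.primary_flag in df else df["strclass"] == "primary", bool),
        ),
    )


# ---------------------------------------------------------------- assembly


@dataclass
class Design:
    """Per-parameter ordered design blocks plus a linear evaluator."""

    blocks: dict[str, list[DesignBlock]]
    n_obs: int

    def params(self) -> list[str]:
        return [p for p in PARAM_NAMES if self.blocks.get(p)]

    def all_blocks(self) -> list[tuple[str, DesignBlock]]:
        return [(p, b) for p in self.params() for b in self.blocks[p]]

    def eta(self, coefs: dict[str, np.ndarray]) -> dict[str, np.ndarray]:
        """Map a coefficient set {block label: vector} to the linear
        predictors.  Linear in the coefficients by construction."""
        out: dict[str, np.ndarray] = {}
        for p in self.params():
            acc = np.zeros(self.n_obs)
            for b in self.blocks[p]:
                acc = acc + b.matrix @ coefs[b.label]
            out[p] = acc
        return out

    def coef_table(self) -> pd.DataFrame:
        rows = [
            {"param": p, "block": b.label, "coef": name, "penalized": b.penalized}
            for p, b in self.all_blocks()
            for name in b.coef_names
        ]
        return pd.DataFrame(rows)


def _parametric_block(records: pd.DataFrame, terms: list[Term], param: str) -> DesignBlock | None:
    cols: list[np.ndarray] = []
    names: list[str] = []
    builders: list[Callable[[pd.DataFrame], np.ndarray]] = []
    for t in terms:
        if isinstance(t, Intercept):
            cols.append(np.ones((len(records), 1)))
            names.append("(Intercept)")
            builders.append(lambda df: np.ones((len(df), 1)))
        elif isinstance(t, Linear):
            name = t.covariate
            if name not in records:
                raise KeyError(f"missing covariate {name!r}")
            cols.append(np.asarray(records[name], float)[:, None])
            names.append(name)
            builders.append(lambda df, name=name: np.asarray(df[name], float)[:, None])
        elif isinstance(t, Categorical):
            if t.covariate not in records:
                raise KeyError(f"missing covariate {t.covariate!r}")
            blk = encode_categorical(records[t.covariate], t.reference, t.levels,
                                     covariate=t.covariate, target=param)
            cols.append(blk.matrix)
            names.extend(blk.coef_names)
            builders.append(blk.builder)
    if not cols:
        return None
    X = np.column_stack(cols)
    k = X.shape[1]

    def build(df: pd.DataFrame) -> np.ndarray:
        return np.column_stack([b(df) for b in builders])

    return DesignBlock(label=f"{param}:parametric", target=param, matrix=X,
                       penalty=np.zeros((k, k)), coef_names=names, builder=build)


def assemble_design(records: pd.DataFrame, spec: ModelSpec, route=None) -> Design:
    """Build all design blocks for a record table.

    Latent terms need extra context: the spatial GMRF needs the route graph,
    the temporal GP uses the ``time`` column.  Raises KeyError naming any
    missing covariate.
    """
    from .latent import gmrf_block, gp_time_block  # deferred: latent imports design

    blocks: dict[str, list[DesignBlock]] = {}
    for param in PARAM_NAMES:
        terms = spec.terms_for(param)
        if not terms:
            continue
        plist: list[DesignBlock] = []
        pblock = _parametric_block(records, terms, param)
        if pblock is not None:
            plist.append(pblock)
        for t in terms:
            if isinstance(t, Spline):
                if t.covariate not in records:
                    raise KeyError(f"missing covariate {t.covariate!r}")
                plist.append(cubic_spline_basis(np.asarray(records[t.covariate], float),
                                                t.n_knots, covariate=t.covariate, target=param))
            elif isinstance(t, TrafficSpline):
                if t.covariate not in records:
                    raise KeyError(f"missing covariate {t.covariate!r}")
                on_primary = (records["strclass"].astype(str) == "primary").to_numpy()
                plist.append(constrained_traffic_spline(
                    np.asarray(records[t.covariate], float), on_primary,
                    t.n_knots, covariate=t.covariate, target=param))
            elif isinstance(t, LatentSpatial):
                if route is None:
                    raise ValueError("LatentSpatial term requires a RouteGraph")
                plist.append(gmrf_block(records["segment_id"], route, target=param,
                                        variance=t.variance))
            elif isinstance(t, LatentTemporal):
                plist.append(gp_time_block(np.asarray(records["time"], float), target=param,
                                           range_s=t.range_s, variance=t.variance,
                                           n_knots=t.n_knots))
        blocks[param] = plist
    return Design(blocks=blocks, n_obs=len(records))


# ------------------------------------------------------- campaign presets

WD_SECTORS = ("N", "NE", "E", "SE", "S", "SW", "W", "NW")
LEIPZIG_STRCLASS = ("park", "residential", "tertiary", "secondary", "primary")
ROME_STRCLASS = ("pedestrian", "residential", "tertiary", "secondary", "primary")
STRCONF = ("open", "half-open", "canyon")
ROME_STRACT = ("residential", "commercial", "touristic")
TRAFF_LEVELS = ("green", "orange", "red", "darkred")


def _common_terms(strclass_levels: tuple[str, ...], strclass_ref: str,
                  wd_ref: str = "SW") -> list[Term]:
    return [
        Intercept(),
        Linear("ws"),
        Categorical("wd", reference=wd_ref, levels=WD_SECTORS),
        Categorical("strclass", reference=strclass_ref, levels=strclass_levels),
        Categorical("strconf", reference="open", levels=STRCONF),
        Categorical("weekday", reference="weekend", levels=("weekend", "weekday")),
        Spline("h", n_knots=8),
    ]


def leipzig_spec(latent: bool = True, noise_model: bool = True) -> ModelSpec:
    """Leipzig-style predictor: wind, direction, street class/configuration,
    weekday, season, hour spline, constrained traffic-count spline."""
    def terms() -> list[Term]:
        out = _common_terms(LEIPZIG_STRCLASS, "park")
        out.append(Categorical("season", reference="summer", levels=("summer", "winter")))
        out.append(TrafficSpline("count", n_knots=8))
        if latent:
            out.append(LatentSpatial())
            out.append(LatentTemporal())
        return out

    lam_terms: list[Term] | None = None
    if noise_model:
        lam_terms = [Intercept()] + ([LatentTemporal(range_s=3600.0, n_knots=30)] if latent else [])
    return ModelSpec(mu=terms(), sigma=terms(), lam=lam_terms)


def rome_spec(latent: bool = True, noise_model: bool = True) -> ModelSpec:
    """Rome-style predictor: adds log ambient concentration, street activity
    and qualitative traffic; no season (single-month campaign)."""
    def terms() -> list[Term]:
        out = _common_terms(ROME_STRCLASS, "pedestrian")
        out.insert(2, Linear("log_amb"))
        out.append(Categorical("stract", reference="residential", levels=ROME_STRACT))
        out.append(Categorical("traff", reference="green", levels=TRAFF_LEVELS))
        if latent:
            out.append(LatentSpatial())
            out.append(LatentTemporal())
        return out

    lam_terms: list[Term] | None = None
    if noise_model:
        lam_terms = [Intercept()] + ([LatentTemporal(range_s=3600.0, n_knots=30)] if latent else [])
    return ModelSpec(mu=terms(), sigma=terms(), lam=lam_terms)
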