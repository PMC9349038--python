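"""Latent zero-mean error processes: a route-segment GMRF and a temporal GP.

The spatial field is a first-order intrinsic Gauss-Markov random field over
adjacent route segments (precision = graph Laplacian, rank deficiency one,
sum-to-zero constraint).  The temporal field is a zero-mean Gaussian process
with exponential correlation exp(-|dt|/range) over campaign time,
represented low-rank through a knot-based predictive process.  Both fields
act like random intercepts: they absorb spatial and serial correlation that
the observed covariates cannot explain.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd
from scipy.linalg import cho_factor, cho_solve, null_space

from .design import DesignBlock

__all__ = [
    "RouteGraph",
    "LatentFieldSpec",
    "gmrf_precision",
    "gp_time_basis",
    "field_log_prior",
    "gmrf_block",
    "gp_time_block",
]


@dataclass
class RouteGraph:
    """Ordered route segments, adjacency, and per-segment street attributes."""

    segments: list[str]
    edges: list[tuple[str, str]]
    attributes: pd.DataFrame  # indexed by segment id: strclass, strconf, (stract)

    def __post_init__(self) -> None:
        missing = set(self.segments) - set(self.attributes.index.astype(str))
        if missing:
            raise ValueError(f"segments without attributes: {sorted(missing)}")

    def graph(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(self.segments)
        g.add_edges_from(self.edges)
        return g

    def to_tables(self) -> tuple[pd.DataFrame, pd.DataFrame]:
        """Serializable edge-list and attribute tables."""
        edges = pd.DataFrame(self.edges, columns=["segment_a", "segment_b"])
        attrs = self.attributes.copy()
        attrs.index.name = "segment_id"
        return edges, attrs.reset_index()

    @classmethod
    def from_tables(cls, edges: pd.DataFrame, attrs: pd.DataFrame) -> "RouteGraph":
        attrs = attrs.set_index(attrs["segment_id"].astype(str)).drop(columns="segment_id")
        attrs.index.name = None
        segs = list(attrs.index)
        e = [(str(a), str(b)) for a, b in zip(edges["segment_a"], edges["segment_b"])]
        return cls(segments=segs, edges=e, attributes=attrs)


@dataclass(frozen=True)
class LatentFieldSpec:
    kind: str  # "gmrf_space" | "gp_time"
    target: str
    variance: float
    range_s: float | None = None

    def __post_init__(self) -> None:
        if self.variance <= 0:
            raise ValueError("variance must be positive")
        if self.kind == "gp_time" and (self.range_s is None or self.range_s <= 0):
            raise ValueError("gp_time needs a positive range")


def gmrf_precision(route: RouteGraph) -> tuple[np.ndarray, np.ndarray]:
    """First-order intrinsic GMRF precision over route segments.

    Returns (K, constraint): K has segment degree on the diagonal and -1 for
    neighbors (the graph Laplacian; rank deficiency one on a connected
    graph), and the all-ones sum-to-zero constraint vector.
    """
    g = route.graph()
    if not nx.is_connected(g):
        comps = [sorted(c) for c in nx.connected_components(g)]
        raise ValueError(f"route graph is disconnected; components: {comps}")
    K = nx.laplacian_matrix(g, nodelist=route.segments).toarray().astype(float)
    return K, np.ones(len(route.segments))


def gp_time_basis(times: np.ndarray, spec: LatentFieldSpec, n_knots: int = 50) -> DesignBlock:
    """Low-rank (predictive-process) basis for an exponential-correlation GP.

    Coefficients are the field values at knot times; the design row for time
    t is r(t, u) R_uu^{-1} with r the exponential correlation, so the implied
    field covariance tau^2 R_tu R_uu^{-1} R_ut approximates the exact kernel.
    The penalty is R_uu^{-1}: a zero-mean Gaussian prior on the knot values.
    """
    if n_knots < 2:
        raise ValueError("n_knots must be >= 2")
    times = np.asarray(times, float)
    rho = float(spec.range_s)
    uniq = np.unique(times)
    knots = np.unique(np.quantile(uniq, np.linspace(0.0, 1.0, min(n_knots, uniq.size))))
    R_uu = np.exp(-np.abs(knots[:, None] - knots[None, :]) / rho)
    R_uu[np.diag_indices_from(R_uu)] += 1e-8
    cf = cho_factor(R_uu)
    K = cho_solve(cf, np.eye(len(knots)))

    def build_at(t: np.ndarray) -> np.ndarray:
        R_tu = np.exp(-np.abs(np.asarray(t, float)[:, None] - knots[None, :]) / rho)
        return cho_solve(cf, R_tu.T).T

    return DesignBlock(
        label=f"{spec.target}:gp(time)",
        target=spec.target,
        matrix=build_at(times),
        penalty=0.5 * (K + K.T),
        coef_names=[f"gp(time).{i + 1}" for i in range(len(knots))],
        builder=lambda df: build_at(np.asarray(df["time"], float)),
    )


def field_log_prior(gamma: np.ndarray, precision: np.ndarray, variance: float) -> float:
    """Rank-corrected log-density of the zero-mean Gaussian field prior.

    For an improper (intrinsic) precision the normalizing constant uses the
    pseudo-determinant over the positive eigenvalues; proper precisions
    reduce to the ordinary multivariate normal log-density.
    """
    if variance <= 0:
        raise ValueError("variance must be positive")
    gamma = np.asarray(gamma, float)
    K = np.asarray(precision, float)
    if K.shape != (gamma.size, gamma.size):
        raise ValueError("dimension mismatch between gamma and precision")
    evals = np.linalg.eigvalsh(K)
    tol = evals.max() * 1e-10 if evals.size else 0.0
    pos = evals[evals > tol]
    rank = pos.size
    logpdet = float(np.sum(np.log(pos)))
    quad = float(gamma @ K @ gamma) / variance
    return 0.5 * (logpdet - rank * np.log(2.0 * np.pi * variance) - quad)


def segment_attribute_matrix(route: RouteGraph) -> np.ndarray:
    """Segment-level indicator matrix of the route's street attributes."""
    cols = []
    for attr in route.attributes.columns:
        vals = route.attributes[attr].astype(str)
        for lvl in sorted(vals.unique()):
            cols.append((vals == lvl).to_numpy(float))
    return np.column_stack(cols) if cols else np.empty((len(route.segments), 0))


def gmrf_block(segment_ids, route: RouteGraph, target: str = "mu",
               variance: float = 0.1, restricted: bool = True) -> DesignBlock:
    """Design block for the spatial GMRF: segment indicators reparameterized
    into the null space of the identifiability constraints, with the
    transformed Laplacian penalty.

    With ``restricted=True`` (restricted spatial regression) the field is
    additionally constrained orthogonal to the segment-level street
    attributes, so it cannot absorb street-class/configuration contrasts
    that belong to the fixed effects.
    """
    K, constraint = gmrf_precision(route)
    C = constraint[None, :]
    if restricted:
        C = np.vstack([C, segment_attribute_matrix(route).T])
    Z = null_space(C)
    Kc = Z.T @ K @ Z
    index = {s: i for i, s in enumerate(route.segments)}

    def build(seg) -> np.ndarray:
        seg = pd.Series(seg).astype(str)
        unknown = set(seg.unique()) - set(index)
        if unknown:
            raise ValueError(f"unknown segment id(s): {sorted(unknown)}")
        rows = seg.map(index).to_numpy()
        return Z[rows]

    return DesignBlock(
        label=f"{target}:gmrf(segment)",
        target=target,
        matrix=build(segment_ids),
        penalty=0.5 * (Kc + Kc.T),
        coef_names=[f"gmrf.{i + 1}" for i in range(Z.shape[1])],
        builder=lambda df: build(df["segment_id"]),
    )


def gp_time_block(times: np.ndarray, target: str = "mu", range_s: float = 600.0,
                  variance: float = 0.1, n_knots: int = 50) -> DesignBlock:
    spec = LatentFieldSpec(kind="gp_time", target=target, variance=variance, range_s=range_s)
    return gp_time_basis(times, spec, n_knots=n_knots)
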