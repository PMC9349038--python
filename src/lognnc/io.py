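"""Readers, writers and run configuration.

All tabular artifacts are plain CSV (comma, UTF-8).  Record timestamps are
seconds from campaign start (a float column); ISO-8601 timestamps are also
accepted on input and converted.  Negative eBC values are preserved on
read: they carry information about the instrument noise level, and
dropping them biases concentration estimates upward.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .latent import RouteGraph

__all__ = [
    "REQUIRED_COLUMNS",
    "read_mm_csv",
    "write_mm_csv",
    "read_route",
    "write_route",
    "RunConfig",
    "config_hash",
    "write_with_provenance",
]

REQUIRED_COLUMNS = ("time", "round_id", "segment_id", "value")


def read_mm_csv(path: str | Path, route: RouteGraph | None = None) -> pd.DataFrame:
    """Read a mobile-measurement record table.

    Validates the required schema, converts ISO timestamps to seconds from
    the first record if needed, and (when a route is given) checks segment
    ids and category levels against the route attribute table.
    """
    path = Path(path)
    df = pd.read_csv(path)
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path.name}: missing required column(s): {missing}")
    if df["time"].dtype == object:
        try:
            t = pd.to_datetime(df["time"], format="ISO8601")
        except (ValueError, TypeError) as exc:
            bad = df["time"].iloc[0]
            raise ValueError(f"{path.name}: unparseable time value {bad!r} at line 2") from exc
        df["time"] = (t - t.iloc[0]).dt.total_seconds()
    bad_rows = ~np.isfinite(pd.to_numeric(df["value"], errors="coerce"))
    if bad_rows.any():
        line = int(np.flatnonzero(bad_rows)[0]) + 2  # header + 1-based
        raise ValueError(f"{path.name}: unparseable value at line {line}")
    df["value"] = df["value"].astype(float)
    if route is not None:
        unknown = set(df["segment_id"].astype(str)) - set(route.segments)
        if unknown:
            raise ValueError(f"{path.name}: unknown segment id(s): {sorted(unknown)[:5]}")
    return df


def write_mm_csv(df: pd.DataFrame, path: str | Path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False)


def write_route(route: RouteGraph, edges_path: str | Path, attrs_path: str | Path) -> None:
    edges, attrs = route.to_tables()
    edges.to_csv(edges_path, index=False)
    attrs.to_csv(attrs_path, index=False)


def read_route(edges_path: str | Path, attrs_path: str | Path) -> RouteGraph:
    return RouteGraph.from_tables(pd.read_csv(edges_path), pd.read_csv(attrs_path))


@dataclass
class RunConfig:
    """One fitting/diagnosis run: paths, model choices, sampler settings."""

    records: str
    output_dir: str
    family: str = "lognnc"
    variant: str = "final"
    template: str = "leipzig_like"
    route_edges: str | None = None
    route_attrs: str | None = None
    n_iter: int = 3000
    burn_in: int = 1000
    thinning: int = 2
    seed: int = 0
    map_only: bool = False
    latent: bool = True
    extra: dict = field(default_factory=dict)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__ if f != "extra"}
        kwargs = {k: v for k, v in raw.items() if k in known}
        extra = {k: v for k, v in raw.items() if k not in known}
        missing = [k for k in ("records", "output_dir") if k not in kwargs]
        if missing:
            raise ValueError(f"config {path}: missing required key(s) {missing}")
        return cls(**kwargs, extra=extra)

    def to_dict(self) -> dict:
        d = {k: getattr(self, k) for k in self.__dataclass_fields__ if k != "extra"}
        d.update(self.extra)
        return d


def config_hash(cfg: RunConfig | dict) -> str:
    d = cfg.to_dict() if isinstance(cfg, RunConfig) else dict(cfg)
    blob = json.dumps(d, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:12]


def write_with_provenance(df: pd.DataFrame, path: str | Path, seed: int,
                          cfg_hash: str) -> None:
    """Write a CSV with a provenance comment header (seed + config hash)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        fh.write(f"# seed={seed} config={cfg_hash}\n")
        df.to_csv(fh, index=False)


def read_provenance_csv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, comment="#")
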