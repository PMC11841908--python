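"""Discretization of continuous section scores into ordinal states.

Three unsupervised binning methods (equal width, equal frequency, 1-D
k-means) and three schemes: every variable binary (two_state), every
variable ternary (three_state), or a per-variable state count chosen by
the silhouette criterion on 1-D k-means clusterings (mixed).  States are
labelled C0..C(k-1) in ascending score order.

Bin intervals are half-open [lo, hi) with the last bin closed, and values
outside the fitted range clamp to the nearest bin, so a fitted BinningSpec
can be replayed on new data (e.g. the test fold of a cross-validation).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml
from sklearn.cluster import KMeans
from sklearn.metrics import silhouette_score

from .synth import SurveyDataset

METHODS = ("equal_width", "equal_frequency", "kmeans")
SCHEMES = ("two_state", "three_state", "mixed")
STATE_CANDIDATES = (2, 3)


@dataclass
class BinningSpec:
    """Fitted binning: method, per-variable state count and interior edges."""

    method: str
    scheme: str
    k: dict[str, int]
    edges: dict[str, list[float]]

    def __post_init__(self) -> None:
        if self.method not in METHODS:
            raise ValueError(f"unknown method {self.method!r}")
        if self.scheme not in SCHEMES:
            raise ValueError(f"unknown scheme {self.scheme!r}")
        for col, k in self.k.items():
            if len(self.edges[col]) != k - 1:
                raise ValueError(f"{col}: expected {k - 1} edges")
            if list(self.edges[col]) != sorted(self.edges[col]):
                raise ValueError(f"{col}: edges must be increasing")

    def states(self, column: str) -> list[str]:
        return [f"C{i}" for i in range(self.k[column])]

    def assign(self, column: str, values: np.ndarray) -> np.ndarray:
        """Map values to integer state codes (edge values go to the upper bin)."""
        return np.searchsorted(self.edges[column], np.asarray(values, dtype=float),
                               side="right")

    def to_text(self, path) -> None:
        doc = {
            "method": self.method,
            "scheme": self.scheme,
            "variables": {
                c: {"k": int(self.k[c]), "edges": [float(e) for e in self.edges[c]]}
                for c in self.k
            },
        }
        with open(path, "w") as fh:
            yaml.safe_dump(doc, fh, sort_keys=True)

    @classmethod
    def from_text(cls, path) -> "BinningSpec":
        with open(path) as fh:
            doc = yaml.safe_load(fh)
        return cls(
            method=doc["method"],
            scheme=doc["scheme"],
            k={c: v["k"] for c, v in doc["variables"].items()},
            edges={c: v["edges"] for c, v in doc["variables"].items()},
        )


@dataclass
class DiscreteDataset:
    """Ordinal state matrix (integer codes, ascending with the raw values)."""

    codes: pd.DataFrame
    spec: BinningSpec

    @property
    def columns(self) -> list[str]:
        return list(self.codes.columns)

    @property
    def n_rows(self) -> int:
        return len(self.codes)

    def n_states(self, column: str) -> int:
        return self.spec.k[column]

    def labels(self) -> pd.DataFrame:
        """State-label view: C0..C(k-1) strings."""
        return self.codes.apply(lambda s: s.map(lambda v: f"C{v}"))

    @classmethod
    def from_codes(cls, codes: pd.DataFrame,
                   k: dict[str, int] | None = None) -> "DiscreteDataset":
        """Wrap already-discrete integer codes (placeholder bin edges)."""
        if k is None:
            k = {c: int(codes[c].max()) + 1 for c in codes.columns}
        edges = {c: [i + 0.5 for i in range(k[c] - 1)] for c in codes.columns}
        spec = BinningSpec(method="equal_width", scheme="mixed", k=k, edges=edges)
        return cls(codes=codes.astype(int), spec=spec)


def _kmeans_1d(values: np.ndarray, k: int) -> tuple[np.ndarray, np.ndarray, float]:
    """Deterministic 1-D k-means: quantile-initialized Lloyd iterations.

    Returns (sorted centers, labels re-indexed by center order, inertia).
    """
    x = np.asarray(values, dtype=float).reshape(-1, 1)
    init = np.quantile(x, [(j + 0.5) / k for j in range(k)]).reshape(-1, 1)
    # jitter-free deterministic init can collide on tied quantiles
    if len(np.unique(init)) < k:
        init = np.unique(x)[np.linspace(0, len(np.unique(x)) - 1, k).astype(int)]
        init = init.reshape(-1, 1)
    km = KMeans(n_clusters=k, init=init, n_init=1, max_iter=300).fit(x)
    order = np.argsort(km.cluster_centers_.ravel())
    relabel = np.empty(k, dtype=int)
    relabel[order] = np.arange(k)
    return km.cluster_centers_.ravel()[order], relabel[km.labels_], float(km.inertia_)


def select_state_count(values: np.ndarray,
                       candidates: tuple[int, ...] = STATE_CANDIDATES,
                       diagnostics: dict | None = None) -> int:
    """Pick the state count maximizing the mean silhouette of 1-D k-means.

    The within-cluster sum of squares per candidate (the elbow curve) is
    written into ``diagnostics`` when a dict is supplied; it is advisory
    only and never drives the choice.  Ties go to the smaller count.
    """
    x = np.asarray(values, dtype=float)
    distinct = np.unique(x)
    if len(distinct) < 2:
        raise ValueError("constant column cannot be discretized")
    best_k, best_sil = None, -np.inf
    for k in sorted(candidates):
        if k > len(distinct):
            continue  # candidate infeasible on this column
        centers, labels, inertia = _kmeans_1d(x, k)
        sil = float(silhouette_score(x.reshape(-1, 1), labels))
        if diagnostics is not None:
            diagnostics.setdefault("wss", {})[k] = inertia
            diagnostics.setdefault("silhouette", {})[k] = sil
        if sil > best_sil + 1e-12:
            best_k, best_sil = k, sil
    return best_k


def equal_width_edges(values: np.ndarray, k: int) -> list[float]:
    """Interior edges of k equal-length intervals over [min, max]."""
    _check_k(k)
    x = np.asarray(values, dtype=float)
    lo, hi = float(x.min()), float(x.max())
    if hi <= lo:
        raise ValueError("constant column: max must exceed min")
    return [lo + j * (hi - lo) / k for j in range(1, k)]


def equal_frequency_edges(values: np.ndarray, k: int) -> list[float]:
    """Interior edges at the j/k sample quantiles (linear interpolation)."""
    _check_k(k)
    x = np.asarray(values, dtype=float)
    if len(np.unique(x)) < k:
        raise ValueError("fewer distinct values than states")
    edges = [float(np.quantile(x, j / k)) for j in range(1, k)]
    if len(set(edges)) < len(edges):
        raise ValueError("tied quantiles: too few distinct values for equal frequency")
    return edges


def kmeans_edges(values: np.ndarray, k: int, seed: int = 0) -> list[float]:
    """Interior edges at midpoints between sorted 1-D k-means centers.

    The clustering is quantile-initialized and fully deterministic; ``seed``
    is accepted for interface symmetry with the other builders.
    """
    _check_k(k)
    x = np.asarray(values, dtype=float)
    if len(np.unique(x)) < k:
        raise ValueError("fewer distinct values than states")
    centers, _, _ = _kmeans_1d(x, k)
    return [float((centers[j] + centers[j + 1]) / 2) for j in range(k - 1)]


def _check_k(k: int) -> None:
    if k not in STATE_CANDIDATES:
        raise ValueError(f"state count must be one of {STATE_CANDIDATES}")


_EDGE_BUILDERS = {
    "equal_width": lambda x, k, seed: equal_width_edges(x, k),
    "equal_frequency": lambda x, k, seed: equal_frequency_edges(x, k),
    "kmeans": kmeans_edges,
}


def fit_binning(dataset: SurveyDataset, scheme: str, method: str,
                seed: int = 0) -> BinningSpec:
    """Choose per-variable state counts per the scheme and fit edges."""
    if scheme not in SCHEMES:
        raise ValueError(f"unknown scheme {scheme!r}")
    if method not in METHODS:
        raise ValueError(f"unknown method {method!r}")
    k_of: dict[str, int] = {}
    edges: dict[str, list[float]] = {}
    for col in dataset.columns:
        x = dataset.values[col].to_numpy(dtype=float)
        if np.isnan(x).any():
            raise ValueError("impute missing cells before discretizing")
        if scheme == "two_state":
            k = 2
        elif scheme == "three_state":
            k = 3
        else:
            k = select_state_count(x)
        k_of[col] = k
        edges[col] = _EDGE_BUILDERS[method](x, k, seed)
    return BinningSpec(method=method, scheme=scheme, k=k_of, edges=edges)


def apply_scheme(dataset: SurveyDataset, scheme: str, method: str,
                 seed: int = 0) -> DiscreteDataset:
    """Fit a BinningSpec on the dataset and apply it columnwise."""
    spec = fit_binning(dataset, scheme, method, seed)
    return apply_spec(dataset, spec)


def apply_spec(dataset: SurveyDataset, spec: BinningSpec) -> DiscreteDataset:
    codes = {}
    for col in dataset.columns:
        codes[col] = spec.assign(col, dataset.values[col].to_numpy(dtype=float))
    return DiscreteDataset(codes=pd.DataFrame(codes, index=dataset.values.index),
                           spec=spec)
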