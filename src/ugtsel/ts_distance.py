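"""Elastic distances on 1-D index series and their protein-level aggregation.

Three time-series distances are provided, all with L1 local cost:

* DTW — classic dynamic-programming warping cost, unconstrained window,
  symmetric step pattern (up, right, diagonal);
* LCSS — 1 - L/max(|x|,|y|), where L is the longest common subsequence under
  value tolerance ``epsilon`` and warping window ``delta``;
* MVM — minimum over monotone injective embeddings of the shorter series
  into the longer of the summed L1 mismatch.

A protein-level distance between two encoded records is the sum of series
distances over a chosen subset of loops and index columns; restricting those
subsets isolates any loop/index combination.  MVM's argument-order asymmetry
is resolved by always embedding the shorter series (equal lengths reduce to a
plain L1 sum, which is symmetric), so distance matrices are symmetric.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from numba import njit

from .encoding import LOOP_LABELS, IndexSeriesSet

__all__ = [
    "METRICS",
    "DistanceSpec",
    "DistanceMatrix",
    "dtw",
    "lcss_distance",
    "mvm",
    "series_distance",
    "default_lcss_epsilons",
    "protein_distance",
    "distance_matrix",
    "series_distance_cache",
]

METRICS = ("dtw", "lcss", "mvm")


@njit(cache=True)
def _dtw_kernel(x, y):
    n, m = len(x), len(y)
    d = np.full((n + 1, m + 1), np.inf)
    d[0, 0] = 0.0
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            c = abs(x[i - 1] - y[j - 1])
            best = d[i - 1, j - 1]
            if d[i - 1, j] < best:
                best = d[i - 1, j]
            if d[i, j - 1] < best:
                best = d[i, j - 1]
            d[i, j] = c + best
    return d[n, m]


@njit(cache=True)
def _lcss_len_kernel(x, y, eps, delta):
    n, m = len(x), len(y)
    length = np.zeros((n + 1, m + 1), dtype=np.int64)
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            if abs(x[i - 1] - y[j - 1]) <= eps and abs(i - j) <= delta:
                length[i, j] = length[i - 1, j - 1] + 1
            else:
                length[i, j] = max(length[i - 1, j], length[i, j - 1])
    return length[n, m]


@njit(cache=True)
def _mvm_kernel(x, y):
    # x is the shorter series; monotone injective embedding into y
    n, m = len(x), len(y)
    prev_min = np.zeros(m + 1)  # prefix minima of previous row, prev_min[j] = min over j' <= j
    cur = np.empty(m + 1)
    for i in range(1, n + 1):
        cur[:] = np.inf
        for j in range(i, m - (n - i) + 1):
            base = 0.0 if i == 1 else prev_min[j - 1]
            cur[j] = abs(x[i - 1] - y[j - 1]) + base
        prev_min[0] = np.inf
        for j in range(1, m + 1):
            prev_min[j] = cur[j] if cur[j] < prev_min[j - 1] else prev_min[j - 1]
    return prev_min[m]


def _as_series(x) -> np.ndarray:
    arr = np.asarray(x, dtype=float).ravel()
    if arr.size == 0:
        raise ValueError("empty series")
    return arr


def dtw(x, y) -> float:
    """Dynamic time warping cost (L1 local cost, unconstrained window)."""
    return float(_dtw_kernel(_as_series(x), _as_series(y)))


def lcss_distance(x, y, epsilon: float, delta: int | None = None) -> float:
    """LCSS distance in [0, 1]: 1 - LCSS length / max(|x|, |y|).

    Values match when within ``epsilon`` and their positions within ``delta``
    (``None`` = unconstrained).
    """
    if epsilon <= 0:
        raise ValueError("lcss epsilon must be > 0")
    xa, ya = _as_series(x), _as_series(y)
    if delta is None:
        delta = max(len(xa), len(ya))
    L = _lcss_len_kernel(xa, ya, float(epsilon), int(delta))
    return float(1.0 - L / max(len(xa), len(ya)))


def mvm(x, y) -> float:
    """Minimal variance matching cost; requires |x| <= |y| (x embeds into y)."""
    xa, ya = _as_series(x), _as_series(y)
    if len(xa) > len(ya):
        raise ValueError(f"mvm requires |x| <= |y|, got {len(xa)} > {len(ya)}")
    return float(_mvm_kernel(xa, ya))


def series_distance(
    x, y, metric: str, epsilon: float | None = None, delta: int | None = None
) -> float:
    """Symmetrized single-series distance under the named metric."""
    if metric == "dtw":
        return dtw(x, y)
    if metric == "lcss":
        return lcss_distance(x, y, epsilon, delta)
    if metric == "mvm":
        xa, ya = _as_series(x), _as_series(y)
        return mvm(xa, ya) if len(xa) <= len(ya) else mvm(ya, xa)
    raise ValueError(f"unknown metric {metric!r}; expected one of {METRICS}")


@dataclass(frozen=True)
class DistanceSpec:
    """Which metric to use and which loops / index columns to sum over.

    ``indices`` are 1-based column numbers into the encoded score table
    (PC1..PC7 for the PCA encoding).  ``lcss_epsilon`` may be a single float
    or None, in which case per-index defaults must be supplied at call time.
    """

    metric: str = "dtw"
    loops: tuple[str, ...] = LOOP_LABELS
    indices: tuple[int, ...] = (1, 2, 3, 4, 5, 6, 7)
    lcss_epsilon: float | None = None
    lcss_delta: int | None = None

    def __post_init__(self) -> None:
        if self.metric not in METRICS:
            raise ValueError(f"unknown metric {self.metric!r}")
        if not self.loops or not self.indices:
            raise ValueError("loops and indices must be non-empty")
        if not set(self.loops) <= set(LOOP_LABELS):
            raise ValueError(f"loops must be within {LOOP_LABELS}")
        if self.lcss_epsilon is not None and self.lcss_epsilon <= 0:
            raise ValueError("lcss_epsilon must be > 0")


@dataclass
class DistanceMatrix:
    """Pairwise protein distances with ordered record IDs."""

    ids: tuple[str, ...]
    values: np.ndarray

    def __post_init__(self) -> None:
        n = len(self.ids)
        if self.values.shape != (n, n):
            raise ValueError("matrix shape does not match ids")
        if np.any(np.diag(self.values) != 0):
            raise ValueError("diagonal must be zero")
        if np.any(self.values < 0):
            raise ValueError("distances must be non-negative")

    def loc(self, a: str, b: str) -> float:
        return float(self.values[self.ids.index(a), self.ids.index(b)])

    def to_tsv(self, path) -> None:
        pd.DataFrame(self.values, index=list(self.ids), columns=list(self.ids)).to_csv(
            path, sep="\t", index_label="id", float_format="%.10g"
        )

    @classmethod
    def from_tsv(cls, path) -> "DistanceMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0)
        return cls(ids=tuple(str(c) for c in df.columns), values=df.to_numpy(dtype=float))


def default_lcss_epsilons(table: pd.DataFrame) -> dict[int, float]:
    """Per-index LCSS tolerance: half the pooled standard deviation of each
    score column over the residue table."""
    return {
        i + 1: 0.5 * float(table.iloc[:, i].std(ddof=1)) for i in range(table.shape[1])
    }


def _epsilon_for(spec: DistanceSpec, idx: int, epsilons: dict[int, float] | None) -> float | None:
    if spec.metric != "lcss":
        return None
    if spec.lcss_epsilon is not None:
        return spec.lcss_epsilon
    if epsilons is None or idx not in epsilons:
        raise ValueError("lcss requires an epsilon (set spec.lcss_epsilon or pass epsilons)")
    return epsilons[idx]


def protein_distance(
    u: IndexSeriesSet,
    v: IndexSeriesSet,
    spec: DistanceSpec,
    epsilons: dict[int, float] | None = None,
) -> float:
    """Sum of per-series distances over the spec's loops and indices."""
    total = 0.0
    for lab in spec.loops:
        if lab not in u.series or lab not in v.series:
            raise KeyError(f"loop {lab!r} absent from a record")
        for idx in spec.indices:
            total += series_distance(
                u[lab][:, idx - 1],
                v[lab][:, idx - 1],
                spec.metric,
                _epsilon_for(spec, idx, epsilons),
                spec.lcss_delta,
            )
    return total


def distance_matrix(
    series_sets: list[IndexSeriesSet],
    spec: DistanceSpec,
    epsilons: dict[int, float] | None = None,
) -> DistanceMatrix:
    """Symmetric pairwise protein distance matrix over encoded records."""
    if len(series_sets) < 2:
        raise ValueError("need at least 2 records")
    ids = tuple(s.record_id for s in series_sets)
    n = len(ids)
    values = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d = protein_distance(series_sets[i], series_sets[j], spec, epsilons)
            values[i, j] = values[j, i] = d
    return DistanceMatrix(ids=ids, values=values)


def series_distance_cache(
    series_sets: list[IndexSeriesSet],
    metric: str = "dtw",
    epsilons: dict[int, float] | None = None,
    lcss_epsilon: float | None = None,
    lcss_delta: int | None = None,
) -> np.ndarray:
    """Per-(loop, index) pairwise series distances, shape (7, p, n, n).

    Each of the per-series terms is computed once per record pair; any
    loop/index-restricted protein distance is then an exact sum of cached
    terms, which the combinatorial search exploits.
    """
    n = len(series_sets)
    p = len(series_sets[0].columns)
    cache = np.zeros((len(LOOP_LABELS), p, n, n))
    for li, lab in enumerate(LOOP_LABELS):
        for k in range(p):
            eps = lcss_epsilon
            if metric == "lcss" and eps is None:
                if epsilons is None:
                    raise ValueError("lcss requires epsilons")
                eps = epsilons[k + 1]
            for i in range(n):
                xi = series_sets[i][lab][:, k]
                for j in range(i + 1, n):
                    d = series_distance(xi, series_sets[j][lab][:, k], metric, eps, lcss_delta)
                    cache[li, k, i, j] = cache[li, k, j, i] = d
    return cache
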