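"""Exhaustive 3NN evaluation over all loop x index subset combinations.

Every non-empty subset of the seven loops crossed with every non-empty subset
of the first five index columns is evaluated with a leave-one-out kNN
classifier; because a restricted protein distance is an exact sum of cached
per-(loop, index) series distances, each of the 7 x p series pairs is
computed only once per record pair and the ~4000 combinations are cheap
matrix reductions.

Aggregation views mirror how the combinatorial results are read: per-record
miss frequencies, the frequency spectrum of distinct loss patterns, and a
per-loop-combination mode analysis that flags loop subsets whose index
choices agree on one small loss pattern — the signature of a loop subset
genuinely carrying class signal rather than a crossvalidation accident.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Mapping, Sequence

import numpy as np

from .classifiers import LossPattern
from .encoding import LOOP_LABELS, IndexSeriesSet
from .ts_distance import series_distance_cache

__all__ = [
    "ComboResult",
    "ModeSummary",
    "enumerate_combos",
    "run_search",
    "miss_frequency_by_record",
    "loss_pattern_spectrum",
    "mode_analysis",
]


@dataclass(frozen=True)
class ComboResult:
    """Crossvalidated loss for one (loop subset, index subset) combination."""

    loops: tuple[str, ...]
    indices: tuple[int, ...]
    loss: LossPattern

    def __post_init__(self) -> None:
        if not self.loops or not self.indices:
            raise ValueError("loop and index subsets must be non-empty")


@dataclass(frozen=True)
class ModeSummary:
    """Modal loss pattern of one loop subset across its index subsets."""

    loops: tuple[str, ...]
    modal_loss_pattern: LossPattern
    mode_frequency: int
    n_index_subsets: int
    qualifies: bool


def _subsets(items: Sequence) -> list[tuple]:
    out = []
    for r in range(1, len(items) + 1):
        out.extend(combinations(items, r))
    return out


def enumerate_combos(
    loop_labels: Sequence[str] = LOOP_LABELS,
    index_labels: Sequence[int] = (1, 2, 3, 4, 5),
) -> list[tuple[tuple[str, ...], tuple[int, ...]]]:
    """All non-empty (loop subset, index subset) pairs in deterministic order
    (subsets by increasing size, then lexicographically; loops vary slowest)."""
    return [(lp, ix) for lp in _subsets(loop_labels) for ix in _subsets(index_labels)]


def _knn_l1o_losses(
    dist: np.ndarray, ids: Sequence[str], y: np.ndarray, k: int
) -> LossPattern:
    """Vectorized leave-one-out kNN on a dense distance matrix.

    Ties in distance break to the smallest record ID, matching knn_classify.
    """
    n = len(ids)
    d = dist.copy()
    np.fill_diagonal(d, np.inf)
    id_rank = np.argsort(np.argsort(np.array(ids, dtype=object)))
    order = np.lexsort((np.broadcast_to(id_rank, (n, n)), d), axis=-1)
    votes = y[order[:, :k]].sum(axis=1)
    preds = (2 * votes > k).astype(int)
    wrong = preds != y
    missed = frozenset(np.array(ids, dtype=object)[wrong])
    fps = frozenset(np.array(ids, dtype=object)[wrong & (y == 0)])
    return LossPattern(missed=missed, false_positives=fps)


def run_search(
    series_sets: list[IndexSeriesSet],
    labels: Mapping[str, int],
    metric: str = "dtw",
    k: int = 3,
    index_labels: Sequence[int] = (1, 2, 3, 4, 5),
    epsilons: dict[int, float] | None = None,
    cache: np.ndarray | None = None,
) -> list[ComboResult]:
    """L1O kNN crossvalidation for every loop x index combination."""
    ids = [s.record_id for s in series_sets]
    y = np.array([labels[i] for i in ids], dtype=int)
    if cache is None:
        cache = series_distance_cache(series_sets, metric, epsilons)
    loop_pos = {lab: i for i, lab in enumerate(LOOP_LABELS)}
    results = []
    for loops, indices in enumerate_combos(index_labels=index_labels):
        li = [loop_pos[lab] for lab in loops]
        ki = [i - 1 for i in indices]
        d = cache[np.ix_(li, ki)].sum(axis=(0, 1))
        results.append(
            ComboResult(loops=loops, indices=indices, loss=_knn_l1o_losses(d, ids, y, k))
        )
    return results


def miss_frequency_by_record(results: Sequence[ComboResult]) -> dict[str, int]:
    """How many combinations misclassified each record."""
    counts: dict[str, int] = {}
    for r in results:
        for i in r.loss.missed:
            counts[i] = counts.get(i, 0) + 1
    return counts


def loss_pattern_spectrum(results: Sequence[ComboResult]) -> list[tuple[LossPattern, int]]:
    """Distinct loss patterns with frequencies, sorted by frequency descending,
    then pattern size ascending, then lexicographically."""
    counts: dict[tuple[str, ...], tuple[LossPattern, int]] = {}
    for r in results:
        key = r.loss.key()
        prev = counts.get(key)
        counts[key] = (r.loss, (prev[1] if prev else 0) + 1)
    return sorted(
        counts.values(), key=lambda pc: (-pc[1], pc[0].n_errors, pc[0].key())
    )


def mode_analysis(
    results: Sequence[ComboResult],
    max_loss: int = 4,
    min_frequency: int = 10,
) -> list[ModeSummary]:
    """Group results by loop subset and find each subset's modal loss pattern.

    A loop subset qualifies when its modal pattern has fewer than ``max_loss``
    errors and occurs in at least ``min_frequency`` of its index subsets
    (defaults mirror "loss under 4, frequency higher than 9" out of the 31
    index choices).  Modal ties break to the smaller, lexicographically first
    pattern.
    """
    by_loops: dict[tuple[str, ...], list[LossPattern]] = {}
    for r in results:
        by_loops.setdefault(r.loops, []).append(r.loss)
    summaries = []
    for loops, losses in by_loops.items():
        counts: dict[tuple[str, ...], tuple[LossPattern, int]] = {}
        for loss in losses:
            prev = counts.get(loss.key())
            counts[loss.key()] = (loss, (prev[1] if prev else 0) + 1)
        modal, freq = min(
            counts.values(), key=lambda pc: (-pc[1], pc[0].n_errors, pc[0].key())
        )
        summaries.append(
            ModeSummary(
                loops=loops,
                modal_loss_pattern=modal,
                mode_frequency=freq,
                n_index_subsets=len(losses),
                qualifies=(modal.n_errors < max_loss and freq >= min_frequency),
            )
        )
    return summaries
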