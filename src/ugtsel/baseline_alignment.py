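"""Alignment-score distance baseline.

The comparison point for the elastic-distance classifiers: a distance derived
from standard global pairwise alignment scores (BLOSUM62, affine gaps 10/0.5)
as the reciprocal of the score.  Three scopes are supported — full sequences,
the concatenation of a record's loops, or a per-loop sum of reciprocal scores
(the latter makes the baseline loop-combination-specific, so it is directly
comparable with loop-restricted elastic classifiers).

A full progressive multiple-alignment pipeline is deliberately not used: the
baseline's role is comparative, and a documented single-pass pairwise global
aligner keeps it reproducible.  Non-positive scores map to a large sentinel
distance.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from Bio import Align
from Bio.Align import substitution_matrices

from .encoding import LOOP_LABELS, UGTRecord
from .ts_distance import DistanceMatrix

__all__ = [
    "AlignmentDistanceSpec",
    "make_aligner",
    "pairwise_alignment_score",
    "alignment_distance",
    "alignment_distance_matrix",
    "SENTINEL_DISTANCE",
]

SENTINEL_DISTANCE = 1e6

SCOPES = ("full", "concatenated-loops", "per-loop-sum")


@dataclass(frozen=True)
class AlignmentDistanceSpec:
    """Scope and scoring for the alignment-distance baseline."""

    scope: str = "full"
    matrix: str = "BLOSUM62"
    gap_open: float = 10.0
    gap_extend: float = 0.5
    loops: tuple[str, ...] = LOOP_LABELS

    def __post_init__(self) -> None:
        if self.scope not in SCOPES:
            raise ValueError(f"scope must be one of {SCOPES}, got {self.scope!r}")
        if self.gap_open < 0 or self.gap_extend < 0:
            raise ValueError("gap penalties must be >= 0")


def make_aligner(spec: AlignmentDistanceSpec | None = None) -> Align.PairwiseAligner:
    spec = spec or AlignmentDistanceSpec()
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = substitution_matrices.load(spec.matrix)
    aligner.open_gap_score = -spec.gap_open
    aligner.extend_gap_score = -spec.gap_extend
    return aligner


def pairwise_alignment_score(
    seq_a: str, seq_b: str, spec: AlignmentDistanceSpec | None = None
) -> float:
    """Optimal global affine-gap alignment score of two sequences."""
    if not seq_a or not seq_b:
        raise ValueError("cannot align an empty sequence")
    return float(make_aligner(spec).score(seq_a, seq_b))


def _score_to_distance(score: float) -> float:
    if score <= 0:
        warnings.warn("non-positive alignment score; using sentinel distance")
        return SENTINEL_DISTANCE
    return 1.0 / score


def alignment_distance(
    a: UGTRecord, b: UGTRecord, spec: AlignmentDistanceSpec | None = None
) -> float:
    """Reciprocal-of-score alignment distance between two records."""
    spec = spec or AlignmentDistanceSpec()
    if spec.scope == "full":
        return _score_to_distance(pairwise_alignment_score(a.sequence, b.sequence, spec))
    if spec.scope == "concatenated-loops":
        ca = "".join(a.loop_seq(lab) for lab in spec.loops)
        cb = "".join(b.loop_seq(lab) for lab in spec.loops)
        return _score_to_distance(pairwise_alignment_score(ca, cb, spec))
    # per-loop-sum: additive over the chosen loop subset
    return float(
        sum(
            _score_to_distance(
                pairwise_alignment_score(a.loop_seq(lab), b.loop_seq(lab), spec)
            )
            for lab in spec.loops
        )
    )


def alignment_distance_matrix(
    records: list[UGTRecord], spec: AlignmentDistanceSpec | None = None
) -> DistanceMatrix:
    """Pairwise alignment-distance matrix, format-compatible with the elastic
    distance matrices so classifiers are interchangeable."""
    if len(records) < 2:
        raise ValueError("need at least 2 records")
    ids = tuple(r.id for r in records)
    n = len(ids)
    values = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d = alignment_distance(records[i], records[j], spec)
            values[i, j] = values[j, i] = d
    return DistanceMatrix(ids=ids, values=values)
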