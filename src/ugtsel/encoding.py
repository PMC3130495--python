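"""Mapping sequences + loop annotations to index time series and flat vectors.

A protein record carries seven annotated acceptor-pocket loop intervals
(labeled a-g, 1-based inclusive).  Two encodings are produced:

* per-loop, per-index numeric series (``encode_record``) of the loop's own
  length, after dropping any annotated excluded positions (e.g. the conserved
  first-loop histidine, identical in every sequence and hence uninformative);
* uniform-length flattened vectors (``flatten_to_vector``) built from
  *covering windows* — per-loop windows of one shared length that contain each
  record's loop, positioned by a gapless sum-of-pairs alignment across all
  records and concatenated loop a->g, position left->right, index PC1->PC7.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from Bio.Align import substitution_matrices

__all__ = [
    "LOOP_LABELS",
    "UGTRecord",
    "IndexSeriesSet",
    "CoveringWindows",
    "encode_record",
    "build_covering_windows",
    "flatten_to_vector",
]

#: the seven acceptor-pocket loop labels, N-terminal to C-terminal
LOOP_LABELS = ("a", "b", "c", "d", "e", "f", "g")

#: residue codes encoded as all-zero score vectors (unknown/ambiguous)
NEUTRAL_CODES = frozenset("XBZJUO")

_STANDARD = frozenset("ACDEFGHIKLMNPQRSTVWY")


@dataclass(frozen=True)
class UGTRecord:
    """One protein: sequence, seven loop intervals, binary label, metadata.

    Loop intervals are 1-based inclusive, ordered a->g, non-overlapping, and
    within sequence bounds.  ``exclusions`` lists 1-based positions dropped
    before series encoding.
    """

    id: str
    sequence: str
    loops: dict[str, tuple[int, int]]
    label: int | None = None
    metadata: dict = field(default_factory=dict)
    exclusions: frozenset[int] = frozenset()

    def __post_init__(self) -> None:
        if set(self.loops) != set(LOOP_LABELS):
            raise ValueError(f"{self.id}: loops must be labeled {LOOP_LABELS}, got {sorted(self.loops)}")
        prev_end = 0
        for lab in LOOP_LABELS:
            start, end = self.loops[lab]
            if not (1 <= start <= end <= len(self.sequence)):
                raise ValueError(f"{self.id}: loop {lab} interval {start}-{end} out of bounds")
            if start <= prev_end:
                raise ValueError(f"{self.id}: loop {lab} overlaps or is out of order")
            prev_end = end

    def loop_seq(self, label: str) -> str:
        start, end = self.loops[label]
        return self.sequence[start - 1 : end]


@dataclass
class IndexSeriesSet:
    """Per-loop, per-index 1-D series for one record (loop -> len x p array)."""

    record_id: str
    series: dict[str, np.ndarray]
    columns: tuple[str, ...]

    def __getitem__(self, loop: str) -> np.ndarray:
        return self.series[loop]


def encode_record(
    rec: UGTRecord, table: pd.DataFrame, exclusions: frozenset[int] | None = None
) -> IndexSeriesSet:
    """Encode a record's loops as per-index numeric series.

    ``table`` is a residue score table (rows = one-letter codes); excluded
    positions are dropped before encoding; neutral codes (X/B/Z/...) encode as
    all-zero rows with a warning.
    """
    if exclusions is None:
        exclusions = rec.exclusions
    lookup = {res: table.loc[res].to_numpy(dtype=float) for res in table.index}
    zero = np.zeros(table.shape[1])
    series = {}
    for lab in LOOP_LABELS:
        start, end = rec.loops[lab]
        rows = []
        for pos in range(start, end + 1):
            if pos in exclusions:
                continue
            res = rec.sequence[pos - 1]
            if res in lookup:
                rows.append(lookup[res])
            elif res in NEUTRAL_CODES:
                warnings.warn(f"{rec.id}: neutral residue code {res!r} at {pos} encoded as zeros")
                rows.append(zero)
            else:
                raise ValueError(f"{rec.id}: unresolvable residue {res!r} at position {pos}")
        series[lab] = np.array(rows).reshape(len(rows), table.shape[1])
    return IndexSeriesSet(record_id=rec.id, series=series, columns=tuple(table.columns))


# ---------------------------------------------------------------------------
# covering windows
# ---------------------------------------------------------------------------

@dataclass
class CoveringWindows:
    """Uniform-length per-loop windows containing each record's loop.

    ``starts[(record_id, loop)]`` is the 1-based window start; windows may
    overrun sequence ends, in which case out-of-bounds positions read as the
    neutral code 'X'.
    """

    lengths: dict[str, int]
    starts: dict[tuple[str, str], int]

    @property
    def total_length(self) -> int:
        return sum(self.lengths.values())

    def window_seq(self, rec: UGTRecord, loop: str) -> str:
        s = self.starts[(rec.id, loop)]
        w = self.lengths[loop]
        return "".join(
            rec.sequence[p - 1] if 1 <= p <= len(rec.sequence) else "X"
            for p in range(s, s + w)
        )


def _submatrix_lookup(name: str):
    mat = substitution_matrices.load(name)
    alpha = mat.alphabet

    def score(a: str, b: str) -> float:
        if a not in alpha:
            a = "X"
        if b not in alpha:
            b = "X"
        return float(mat[a, b])

    return score


def _admissible_starts(rec: UGTRecord, loop: str, w: int) -> list[int]:
    start, end = rec.loops[loop]
    cands = [s for s in range(end - w + 1, start + 1)]
    in_bounds = [s for s in cands if s >= 1 and s + w - 1 <= len(rec.sequence)]
    return in_bounds or cands


def _window_chars(rec: UGTRecord, s: int, w: int) -> list[str]:
    return [
        rec.sequence[p - 1] if 1 <= p <= len(rec.sequence) else "X" for p in range(s, s + w)
    ]


def build_covering_windows(
    records: list[UGTRecord],
    margins: int | dict[str, int] = 2,
    scoring: str = "BLOSUM62",
    max_sweeps: int = 50,
) -> CoveringWindows:
    """Position uniform-length covering windows by gapless sum-of-pairs alignment.

    Per loop the window length is the maximum loop length over records plus a
    symmetric margin on each side.  Offsets are refined one record at a time
    (coordinate ascent on the gapless sum-of-pairs substitution score, subject
    to window >= loop), until no offset changes; ties break to the smallest
    start.  Windows overrunning a sequence end are shifted inward when
    possible, otherwise padded with the neutral code.
    """
    if len(records) < 2:
        raise ValueError("need at least 2 records to build covering windows")
    if isinstance(margins, int):
        margins = {lab: margins for lab in LOOP_LABELS}
    score = _submatrix_lookup(scoring)
    order = sorted(records, key=lambda r: r.id)
    lengths, starts = {}, {}
    for lab in LOOP_LABELS:
        w = max(r.loops[lab][1] - r.loops[lab][0] + 1 for r in records) + 2 * margins[lab]
        lengths[lab] = w
        cands = {r.id: _admissible_starts(r, lab, w) for r in order}
        cur = {}
        for r in order:
            loop_start, loop_end = r.loops[lab]
            ideal = loop_start - (w - (loop_end - loop_start + 1)) // 2
            cur[r.id] = min(cands[r.id], key=lambda s: (abs(s - ideal), s))
        chars = {r.id: _window_chars(r, cur[r.id], w) for r in order}
        for _ in range(max_sweeps):
            changed = False
            for r in order:
                others = [chars[o.id] for o in order if o.id != r.id]
                best_s, best_score = None, -np.inf
                for s in cands[r.id]:
                    cw = _window_chars(r, s, w)
                    total = sum(
                        score(a, b) for oc in others for a, b in zip(cw, oc)
                    )
                    if total > best_score:
                        best_s, best_score = s, total
                if best_s != cur[r.id]:
                    cur[r.id] = best_s
                    chars[r.id] = _window_chars(r, best_s, w)
                    changed = True
            if not changed:
                break
        for r in order:
            starts[(r.id, lab)] = cur[r.id]
    return CoveringWindows(lengths=lengths, starts=starts)


def flatten_to_vector(
    rec: UGTRecord, windows: CoveringWindows, table: pd.DataFrame
) -> np.ndarray:
    """Concatenate windowed residue scores into one fixed-length vector.

    Length = total window length x number of index columns; ordering is loop
    a->g, window position left->right, index column order.  Out-of-bounds and
    neutral codes contribute zero rows.
    """
    lookup = {res: table.loc[res].to_numpy(dtype=float) for res in table.index}
    zero = np.zeros(table.shape[1])
    parts = []
    for lab in LOOP_LABELS:
        if (rec.id, lab) not in windows.starts:
            raise KeyError(f"{rec.id}: no covering window for loop {lab}")
        for res in windows.window_seq(rec, lab):
            parts.append(lookup.get(res, zero))
    return np.concatenate(parts)
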