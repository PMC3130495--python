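"""Synthetic UGT-like datasets with known planted ground truth.

Real regioselectivity data requires downloading accession sequences and
structure-derived loop annotations, so every stage of the pipeline is
exercised instead on simulated records that mimic the study's shape: 23
sequences of 446-511 residues, seven ordered non-overlapping loops with the
observed per-loop length variation (3-6, 2-18, 7-24, 2-3, 1-4, 2-9, 2-9),
and a 10/13 class split.

Class-correlated signal is confined to chosen loops and planted in
index-score space by residue rejection sampling against the shipped score
table — positives draw loop residues until the mean z-score over the signal
indices clears the effect size — so the full residue-graph -> PCA -> encoding
path is exercised rather than bypassed with fictional residues.  A second
generator plants template-based class signal and then corrupts loop series
with time-warping indels, the regime elastic distances exist for.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict, field
from pathlib import Path

import numpy as np
import pandas as pd

from .encoding import LOOP_LABELS, UGTRecord
from .index_pca import fit_pca, project
from .residue_model import RESIDUES, compute_raw_index_table

__all__ = [
    "DEFAULT_LOOP_RANGES",
    "SimConfig",
    "default_score_table",
    "simulate",
    "simulate_warped",
    "write_fixture",
]

#: per-loop (min, max) length ranges, loops a-g
DEFAULT_LOOP_RANGES = {
    "a": (3, 6),
    "b": (2, 18),
    "c": (7, 24),
    "d": (2, 3),
    "e": (1, 4),
    "f": (2, 9),
    "g": (2, 9),
}

POSITIVE_CLASS = "3"
NEGATIVE_CLASS = "NA"


@dataclass(frozen=True)
class SimConfig:
    """Study-shaped simulation parameters.

    ``effect_size`` is the mean z-score shift (in pooled score-table SD units
    over the signal indices) required of positive-class residues drawn in
    signal loops; ``noise_rate`` is an i.i.d. per-residue substitution
    probability applied after signal planting.
    """

    n_records: int = 23
    length_range: tuple[int, int] = (446, 511)
    loop_length_ranges: dict[str, tuple[int, int]] = field(
        default_factory=lambda: dict(DEFAULT_LOOP_RANGES)
    )
    signal_loops: tuple[str, ...] = ("b", "e")
    signal_indices: tuple[int, ...] = (1, 2)
    effect_size: float = 1.0
    noise_rate: float = 0.05
    n_positive: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 <= self.noise_rate <= 1):
            raise ValueError("noise_rate must lie in [0, 1]")
        if self.effect_size > 0 and (not self.signal_loops or not self.signal_indices):
            raise ValueError("signal loops/indices must be non-empty when effect_size > 0")
        if not 0 <= self.n_positive <= self.n_records:
            raise ValueError("n_positive must lie in [0, n_records]")
        for lab, (lo, hi) in self.loop_length_ranges.items():
            if not (1 <= lo <= hi):
                raise ValueError(f"invalid length range for loop {lab}: {(lo, hi)}")


_SCORE_TABLE_CACHE: dict[str, pd.DataFrame] = {}


def default_score_table() -> pd.DataFrame:
    """PCA score table from the packaged chemistry (computed once, cached)."""
    if "table" not in _SCORE_TABLE_CACHE:
        raw = compute_raw_index_table()
        _SCORE_TABLE_CACHE["table"] = project(raw, fit_pca(raw))
    return _SCORE_TABLE_CACHE["table"]


def _signal_z(table: pd.DataFrame, indices: tuple[int, ...]) -> np.ndarray:
    cols = table.iloc[:, [i - 1 for i in indices]]
    return ((cols - cols.mean()) / cols.std(ddof=1)).mean(axis=1).to_numpy()


def _place_loops(
    rng: np.random.Generator, length: int, loop_lens: dict[str, int]
) -> dict[str, tuple[int, int]]:
    """Place the seven loops in order with random positive inter-loop gaps."""
    total = sum(loop_lens.values())
    n_gaps = len(LOOP_LABELS) + 1
    free = length - total - n_gaps  # every gap gets at least 1
    if free < 0:
        raise ValueError(f"loops (total {total}) do not fit in sequence of length {length}")
    extra = rng.multinomial(free, np.full(n_gaps, 1.0 / n_gaps))
    loops = {}
    pos = 0
    for i, lab in enumerate(LOOP_LABELS):
        pos += 1 + int(extra[i])  # gap before this loop
        loops[lab] = (pos + 1, pos + loop_lens[lab])
        pos += loop_lens[lab]
    return loops


def _draw_signal_residue(
    rng: np.random.Generator, z: np.ndarray, effect_size: float, max_tries: int = 1000
) -> str:
    best, best_z = None, -np.inf
    for _ in range(max_tries):
        res = RESIDUES[rng.integers(len(RESIDUES))]
        rz = z[RESIDUES.index(res)]
        if rz >= effect_size:
            return res
        if rz > best_z:
            best, best_z = res, rz
    return best


def _apply_noise(rng: np.random.Generator, seq: list[str], rate: float) -> None:
    if rate <= 0:
        return
    for i in np.flatnonzero(rng.random(len(seq)) < rate):
        seq[i] = RESIDUES[rng.integers(len(RESIDUES))]


def simulate(
    config: SimConfig | None = None, score_table: pd.DataFrame | None = None
) -> tuple[list[UGTRecord], dict]:
    """Generate records with class signal planted by residue composition.

    Positive-class residues in the signal loops are rejection-sampled until
    their mean signal-index z-score reaches the effect size; everything else
    is uniform background.  Returns the records and a ground-truth manifest.
    """
    config = config or SimConfig()
    if score_table is None:
        score_table = default_score_table()
    rng = np.random.default_rng(config.seed)
    z = _signal_z(score_table, config.signal_indices)

    labels = np.zeros(config.n_records, dtype=int)
    labels[rng.permutation(config.n_records)[: config.n_positive]] = 1

    records = []
    for n in range(config.n_records):
        length = int(rng.integers(config.length_range[0], config.length_range[1] + 1))
        loop_lens = {
            lab: int(rng.integers(lo, hi + 1))
            for lab, (lo, hi) in config.loop_length_ranges.items()
        }
        loops = _place_loops(rng, length, loop_lens)
        seq = [RESIDUES[i] for i in rng.integers(len(RESIDUES), size=length)]
        if labels[n] and config.effect_size > 0:
            for lab in config.signal_loops:
                start, end = loops[lab]
                for pos in range(start, end + 1):
                    seq[pos - 1] = _draw_signal_residue(rng, z, config.effect_size)
        _apply_noise(rng, seq, config.noise_rate)
        rid = f"S{n + 1:02d}"
        records.append(
            UGTRecord(
                id=rid,
                sequence="".join(seq),
                loops=loops,
                label=int(labels[n]),
                metadata={"origin": "synthetic"},
            )
        )
    manifest = {
        "generator": "simulate",
        "config": _config_dict(config),
        "labels": {r.id: r.label for r in records},
    }
    return records, manifest


def simulate_warped(
    config: SimConfig | None = None, warp_rate: float = 0.4
) -> tuple[list[UGTRecord], dict]:
    """Generate records whose class signal survives under time warping.

    Each class gets a fixed random residue template per signal loop; a
    record's loop is its class template stretched/compressed by random
    duplication/deletion indels to a random admissible length (warp), then
    hit by substitution noise.  Variation within a class is therefore mostly
    temporal, the regime in which warping-tolerant distances are expected to
    outperform rigid matching.
    """
    config = config or SimConfig()
    rng = np.random.default_rng(config.seed)

    templates = {}
    for lab in config.signal_loops:
        lo, hi = config.loop_length_ranges[lab]
        tlen = max(hi, 2)
        for cls in (0, 1):
            templates[(lab, cls)] = [
                RESIDUES[i] for i in rng.integers(len(RESIDUES), size=tlen)
            ]

    labels = np.zeros(config.n_records, dtype=int)
    labels[rng.permutation(config.n_records)[: config.n_positive]] = 1

    records = []
    for n in range(config.n_records):
        length = int(rng.integers(config.length_range[0], config.length_range[1] + 1))
        loop_lens = {
            lab: int(rng.integers(lo, hi + 1))
            for lab, (lo, hi) in config.loop_length_ranges.items()
        }
        loops = _place_loops(rng, length, loop_lens)
        seq = [RESIDUES[i] for i in rng.integers(len(RESIDUES), size=length)]
        for lab in config.signal_loops:
            start, end = loops[lab]
            target = end - start + 1
            loop_seq = list(templates[(lab, labels[n])])
            while len(loop_seq) > target:  # random deletions (time compression)
                del loop_seq[rng.integers(len(loop_seq))]
            while len(loop_seq) < target:  # random duplications (time dilation)
                i = int(rng.integers(len(loop_seq)))
                loop_seq.insert(i, loop_seq[i])
            if warp_rate > 0:  # extra local duplications balanced by deletions
                for _ in range(rng.binomial(target, warp_rate)):
                    i = int(rng.integers(len(loop_seq)))
                    j = int(rng.integers(len(loop_seq)))
                    loop_seq.insert(i, loop_seq[i])
                    del loop_seq[j if j < i else j + 1]
            seq[start - 1 : end] = loop_seq
        _apply_noise(rng, seq, config.noise_rate)
        records.append(
            UGTRecord(
                id=f"S{n + 1:02d}",
                sequence="".join(seq),
                loops=loops,
                label=int(labels[n]),
                metadata={"origin": "synthetic-warped"},
            )
        )
    manifest = {
        "generator": "simulate_warped",
        "config": _config_dict(config),
        "warp_rate": warp_rate,
        "labels": {r.id: r.label for r in records},
    }
    return records, manifest


def _config_dict(config: SimConfig) -> dict:
    d = asdict(config)
    d["length_range"] = list(d["length_range"])
    d["loop_length_ranges"] = {k: list(v) for k, v in d["loop_length_ranges"].items()}
    d["signal_loops"] = list(d["signal_loops"])
    d["signal_indices"] = list(d["signal_indices"])
    return d


def write_fixture(records: list[UGTRecord], manifest: dict, directory) -> dict[str, Path]:
    """Write a dataset fixture: FASTA, loop TSV, labels TSV and JSON manifest.

    Positive records get class "3" and negatives "NA", so reading the fixture
    back for the 3-O problem reproduces the planted binary labels.
    """
    import json

    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = {
        "fasta": directory / "sequences.fasta",
        "loops": directory / "loops.tsv",
        "labels": directory / "labels.tsv",
        "manifest": directory / "manifest.json",
    }
    with open(paths["fasta"], "w") as fh:
        for r in records:
            fh.write(f">{r.id}\n")
            for i in range(0, len(r.sequence), 60):
                fh.write(r.sequence[i : i + 60] + "\n")
    with open(paths["loops"], "w") as fh:
        fh.write("id\tloop_label\tstart\tend\texclude\n")
        for r in records:
            for lab in LOOP_LABELS:
                start, end = r.loops[lab]
                excl = ",".join(
                    str(p) for p in sorted(r.exclusions) if start <= p <= end
                )
                fh.write(f"{r.id}\t{lab}\t{start}\t{end}\t{excl}\n")
    with open(paths["labels"], "w") as fh:
        fh.write("id\tclass\n")
        for r in records:
            cls = POSITIVE_CLASS if r.label else NEGATIVE_CLASS
            fh.write(f"{r.id}\t{cls}\n")
    with open(paths["manifest"], "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return paths
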