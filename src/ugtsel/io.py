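"""Dataset readers/writers and the packaged study metadata.

A dataset is a FASTA of sequences plus two TSVs: loop annotations
(id, loop_label a-g, start, end, optional comma-separated excluded
positions; 1-based inclusive coordinates) and class labels (id, class).
Class strings are comma-separated position tokens ("5, 3"); a primed token
like "3′" is distinct from the unprimed "3", and "NA" means no class.
A record is positive for a binary problem ("3-O", "7-O", ...) when its class
set contains the problem's position token.

The 23-enzyme study metadata (IDs, labels, acceptors, organisms, accessions,
regioselectivity classes) ships as packaged TSV; the sequences themselves
are deliberately not bundled and must be fetched by accession or simulated.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import pandas as pd
from Bio import SeqIO

from .encoding import LOOP_LABELS, UGTRecord

__all__ = [
    "Dataset",
    "parse_class",
    "problem_token",
    "is_positive",
    "read_dataset",
    "load_table1",
    "table1_binary_labels",
]


@dataclass
class Dataset:
    """Validated records labeled for one binary regioselectivity problem."""

    records: list[UGTRecord]
    problem: str
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        ids = [r.id for r in self.records]
        if len(ids) != len(set(ids)):
            dup = sorted({i for i in ids if ids.count(i) > 1})
            raise ValueError(f"duplicate record IDs: {dup}")
        unlabeled = [r.id for r in self.records if r.label is None]
        if unlabeled:
            raise ValueError(f"records without a label: {unlabeled}")

    @property
    def labels(self) -> dict[str, int]:
        return {r.id: r.label for r in self.records}


def parse_class(s: str) -> frozenset[str]:
    """Split a class string into its position tokens; NA/empty -> none."""
    s = str(s).strip()
    if not s or s.upper() == "NA":
        return frozenset()
    return frozenset(tok.strip() for tok in s.split(",") if tok.strip())


def problem_token(problem: str) -> str:
    """Map a problem name like "3-O" to its class token "3"."""
    if not problem.endswith("-O"):
        raise ValueError(f"problem must look like '3-O', got {problem!r}")
    return problem[:-2]


def is_positive(class_string: str, problem: str) -> bool:
    return problem_token(problem) in parse_class(class_string)


def _checksum(path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()[:16]


def read_dataset(fasta, loops_tsv, labels_tsv, problem: str = "3-O") -> Dataset:
    """Load and validate a dataset, resolving class strings to binary labels."""
    seqs = {rec.id: str(rec.seq) for rec in SeqIO.parse(str(fasta), "fasta")}
    loops_df = pd.read_csv(loops_tsv, sep="\t", dtype={"id": str}, comment="#")
    labels_df = pd.read_csv(
        labels_tsv, sep="\t", dtype=str, comment="#", keep_default_na=False
    )

    class_by_id = dict(zip(labels_df["id"], labels_df["class"].astype(str)))
    missing = sorted(set(seqs) - set(class_by_id)) + sorted(set(class_by_id) - set(seqs))
    if missing:
        raise ValueError(f"ID mismatch between FASTA and labels: {missing}")

    records = []
    for rid in sorted(seqs):
        grp = loops_df[loops_df["id"] == rid]
        if set(grp["loop_label"]) != set(LOOP_LABELS):
            raise ValueError(
                f"{rid}: expected loop annotations {LOOP_LABELS}, got {sorted(grp['loop_label'])}"
            )
        loops, exclusions = {}, set()
        for row in grp.itertuples():
            loops[row.loop_label] = (int(row.start), int(row.end))
            if "exclude" in grp.columns and isinstance(row.exclude, str) and row.exclude:
                exclusions.update(int(p) for p in row.exclude.split(","))
        records.append(
            UGTRecord(
                id=rid,
                sequence=seqs[rid],
                loops=loops,
                label=int(is_positive(class_by_id[rid], problem)),
                metadata={"class": class_by_id[rid]},
                exclusions=frozenset(exclusions),
            )
        )
    provenance = {
        str(p): _checksum(p) for p in (fasta, loops_tsv, labels_tsv)
    }
    return Dataset(records=records, problem=problem, provenance=provenance)


def load_table1() -> pd.DataFrame:
    """The packaged 23-enzyme study metadata table (no sequences)."""
    path = resources.files("ugtsel") / "data" / "table1.tsv"
    return pd.read_csv(path, sep="\t", dtype={"id": str})


def table1_binary_labels(problem: str) -> dict[str, int]:
    """Binary labels for a problem, keyed by numeric study ID."""
    t = load_table1()
    return {str(i): int(is_positive(c, problem)) for i, c in zip(t["id"], t["class"])}
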