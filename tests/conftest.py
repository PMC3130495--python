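import numpy as np
import pytest

from ugtsel.encoding import LOOP_LABELS, UGTRecord, encode_record
from ugtsel.index_pca import fit_pca, project
from ugtsel.residue_model import compute_raw_index_table, load_chemistry
from ugtsel.synthetic_data import SimConfig, simulate


@pytest.fixture(scope="session")
def chemistry():
    return load_chemistry()


@pytest.fixture(scope="session")
def raw_table(chemistry):
    return compute_raw_index_table(chemistry)


@pytest.fixture(scope="session")
def pca_model(raw_table):
    return fit_pca(raw_table)


@pytest.fixture(scope="session")
def score_table(raw_table, pca_model):
    return project(raw_table, pca_model)


def make_record(loop_seqs: dict[str, str], rec_id: str = "R1", label: int = 0,
                spacer: str = "G", exclusions=frozenset()) -> UGTRecord:
    """Assemble a record whose seven loops are the given strings, separated by
    single spacer residues."""
    seq, loops, pos = spacer, {}, 1
    for lab in LOOP_LABELS:
        s = loop_seqs.get(lab, "A")
        loops[lab] = (pos + 1, pos + len(s))
        seq += s + spacer
        pos += len(s) + 1
    return UGTRecord(id=rec_id, sequence=seq, loops=loops, label=label,
                     exclusions=exclusions)


@pytest.fixture(scope="session")
def toy_records():
    return [
        make_record({"b": "ACD", "e": "KR"}, "T1", 1),
        make_record({"b": "ACE", "e": "KK"}, "T2", 1),
        make_record({"b": "GGG", "e": "DE"}, "T3", 0),
        make_record({"b": "GGA", "e": "DD"}, "T4", 0),
    ]


@pytest.fixture(scope="session")
def toy_series(toy_records, score_table):
    return [encode_record(r, score_table) for r in toy_records]


@pytest.fixture(scope="session")
def sim_dataset(score_table):
    records, manifest = simulate(SimConfig(seed=0))
    series = [encode_record(r, score_table) for r in records]
    labels = {r.id: r.label for r in records}
    return records, series, labels, manifest
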