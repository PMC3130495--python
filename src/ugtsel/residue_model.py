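"""Graph models of amino-acid side chains and the seven derived residue indices.

Each residue is modeled as a rooted, labeled graph: atoms (alpha-carbon plus
all side-chain atoms, hydrogens included) are nodes, covalent bonds are edges
weighted by idealized bond length.  Proline additionally carries its
backbone ring closure, so its graph is cyclic through the root.  From these
graphs seven numeric indices are computed per residue:

====================  =========================================================
reach                 bond-length-weighted eccentricity of the alpha-carbon
branching_density     mean degree over internal (degree >= 2) nodes
forking_index         internal nodes tallied by reciprocal unit-hop distance
net_partial_charge    sum of atomic partial charges
average_polarity      mean unsigned bond dipole (|dq| x bond length)
hb_acceptor_index     electronegativity- and distance-weighted lone-pair tally
hb_donor_index        electronegativity- and distance-weighted donor-H tally
====================  =========================================================

The chemistry (partial charges, bond lengths, electronegativities, lone-pair
and donor-hydrogen assignments) ships as editable TSV package data covering
standard pH-7 protonation states (Lys+, Arg+, Asp-, Glu-, neutral His
epsilon-tautomer).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from typing import Callable, Mapping

import networkx as nx
import numpy as np
import pandas as pd

__all__ = [
    "RESIDUES",
    "INDEX_COLUMNS",
    "Atom",
    "Bond",
    "SideChainGraph",
    "load_chemistry",
    "build_residue_graph",
    "reach",
    "branching_density",
    "forking_index",
    "net_partial_charge",
    "average_polarity",
    "hb_acceptor_index",
    "hb_donor_index",
    "compute_raw_index_table",
    "reciprocal_hop_weight",
]

#: canonical residue order used for all 20-row tables
RESIDUES = tuple("ACDEFGHIKLMNPQRSTVWY")

#: column order of the raw index table
INDEX_COLUMNS = (
    "reach",
    "branching_density",
    "forking_index",
    "net_partial_charge",
    "average_polarity",
    "hb_acceptor_index",
    "hb_donor_index",
)


@dataclass(frozen=True)
class Atom:
    """One atom of a side-chain graph.

    ``hb_acceptor_lone_pairs`` counts only lone pairs deemed to participate in
    hydrogen bonding (0 for atoms judged non-bonding); ``is_hb_donor_h`` marks
    hydrogens bound to N/O/S that donate hydrogen bonds.
    """

    name: str
    element: str
    partial_charge: float
    electronegativity: float
    hb_acceptor_lone_pairs: int = 0
    is_hb_donor_h: bool = False

    def __post_init__(self) -> None:
        if self.electronegativity <= 0:
            raise ValueError(f"electronegativity must be > 0, got {self.electronegativity}")
        if self.hb_acceptor_lone_pairs < 0:
            raise ValueError("hb_acceptor_lone_pairs must be >= 0")
        if self.hb_acceptor_lone_pairs > 0 and self.element not in ("N", "O", "S"):
            raise ValueError(f"lone pairs counted on non-N/O/S atom {self.name} ({self.element})")


@dataclass(frozen=True)
class Bond:
    """A covalent bond between two named atoms, with idealized length in Angstrom."""

    a: str
    b: str
    length: float

    def __post_init__(self) -> None:
        if self.a == self.b:
            raise ValueError(f"bond endpoints must differ, got {self.a}")
        if self.length <= 0:
            raise ValueError(f"bond length must be > 0, got {self.length}")


@dataclass
class SideChainGraph:
    """Rooted labeled graph of one residue's alpha-carbon + side chain."""

    residue: str
    root: str
    atoms: tuple[Atom, ...]
    bonds: tuple[Bond, ...]
    graph: nx.Graph = field(repr=False, default=None)

    def __post_init__(self) -> None:
        g = nx.Graph()
        for atom in self.atoms:
            g.add_node(atom.name, atom=atom)
        for bond in self.bonds:
            if bond.a not in g or bond.b not in g:
                raise ValueError(f"{self.residue}: bond {bond.a}-{bond.b} references unknown atom")
            g.add_edge(bond.a, bond.b, length=bond.length)
        if self.root not in g:
            raise ValueError(f"{self.residue}: root {self.root} not among atoms")
        if g.number_of_nodes() > 1 and not nx.is_connected(g):
            raise ValueError(f"{self.residue}: graph is not connected")
        self.graph = g

    def atom(self, name: str) -> Atom:
        return self.graph.nodes[name]["atom"]


# ---------------------------------------------------------------------------
# chemistry parameter set
# ---------------------------------------------------------------------------

def load_chemistry(
    atoms_path=None, bonds_path=None
) -> Mapping[str, tuple[pd.DataFrame, pd.DataFrame]]:
    """Load the chemistry parameter set (per-residue atom and bond tables).

    Defaults to the packaged TSVs; pass explicit paths to swap in an
    alternative parameter set with the same columns.
    """
    if atoms_path is None or bonds_path is None:
        data = resources.files("ugtsel") / "data"
        atoms_path = atoms_path or data / "chemistry_atoms.tsv"
        bonds_path = bonds_path or data / "chemistry_bonds.tsv"
    atoms = pd.read_csv(atoms_path, sep="\t")
    bonds = pd.read_csv(bonds_path, sep="\t")
    chemistry = {}
    for res, grp in atoms.groupby("residue", sort=True):
        chemistry[res] = (grp.reset_index(drop=True), bonds[bonds.residue == res].reset_index(drop=True))
    return chemistry


def build_residue_graph(
    residue: str, chemistry: Mapping[str, tuple[pd.DataFrame, pd.DataFrame]] | None = None
) -> SideChainGraph:
    """Build the rooted side-chain graph for a one-letter residue code."""
    if chemistry is None:
        chemistry = load_chemistry()
    if residue not in RESIDUES or residue not in chemistry:
        raise ValueError(f"unknown residue code {residue!r}; expected one of {''.join(RESIDUES)}")
    atoms_df, bonds_df = chemistry[residue]
    atoms = tuple(
        Atom(
            name=r.atom,
            element=r.element,
            partial_charge=float(r.partial_charge),
            electronegativity=float(r.electronegativity),
            hb_acceptor_lone_pairs=int(r.hb_acceptor_lone_pairs),
            is_hb_donor_h=bool(r.is_hb_donor_h),
        )
        for r in atoms_df.itertuples()
    )
    bonds = tuple(Bond(r.atom1, r.atom2, float(r.length)) for r in bonds_df.itertuples())
    return SideChainGraph(residue=residue, root="CA", atoms=atoms, bonds=bonds)


# ---------------------------------------------------------------------------
# the seven indices
# ---------------------------------------------------------------------------

def reach(g: SideChainGraph) -> float:
    """Bond-length-weighted eccentricity of the root (side-chain size, Angstrom)."""
    dist = nx.single_source_dijkstra_path_length(g.graph, g.root, weight="length")
    return max(dist.values())


def branching_density(g: SideChainGraph) -> float:
    """Mean degree over internal nodes (degree >= 2); 0 when none exist."""
    degs = [d for _, d in g.graph.degree() if d >= 2]
    return float(np.mean(degs)) if degs else 0.0


def forking_index(g: SideChainGraph) -> float:
    """Internal nodes tallied by reciprocal unit-hop distance from the root.

    The root itself is excluded (its hop distance of 0 has no reciprocal).
    """
    hops = nx.single_source_shortest_path_length(g.graph, g.root)
    degree = dict(g.graph.degree())
    return sum(1.0 / d for node, d in hops.items() if d >= 1 and degree[node] >= 2)


def net_partial_charge(g: SideChainGraph) -> float:
    """Sum of atomic partial charges (elementary charge units)."""
    return float(sum(a.partial_charge for a in g.atoms))


def average_polarity(g: SideChainGraph) -> float:
    """Mean unsigned bond dipole, |delta charge| x bond length; 0 without bonds."""
    dipoles = [
        abs(g.atom(b.a).partial_charge - g.atom(b.b).partial_charge) * b.length for b in g.bonds
    ]
    return float(np.mean(dipoles)) if dipoles else 0.0


def reciprocal_hop_weight(hops: int) -> float:
    """Default bounded decreasing distance weight for the H-bond indices."""
    return 1.0 / (1.0 + hops)


def hb_acceptor_index(
    g: SideChainGraph, distance_weight: Callable[[int], float] = reciprocal_hop_weight
) -> float:
    """Electronegativity- and distance-weighted tally of H-bond accepting lone pairs."""
    hops = nx.single_source_shortest_path_length(g.graph, g.root)
    return float(
        sum(
            a.hb_acceptor_lone_pairs * a.electronegativity * distance_weight(hops[a.name])
            for a in g.atoms
            if a.hb_acceptor_lone_pairs > 0
        )
    )


def hb_donor_index(
    g: SideChainGraph, distance_weight: Callable[[int], float] = reciprocal_hop_weight
) -> float:
    """Tally of donor hydrogens, each weighted by its heavy atom's
    electronegativity and unit-hop distance from the root."""
    hops = nx.single_source_shortest_path_length(g.graph, g.root)
    total = 0.0
    for a in g.atoms:
        if not a.is_hb_donor_h:
            continue
        heavy = next(
            n for n in g.graph.neighbors(a.name) if g.atom(n).element in ("N", "O", "S")
        )
        heavy_atom = g.atom(heavy)
        total += heavy_atom.electronegativity * distance_weight(hops[heavy])
    return float(total)


def compute_raw_index_table(
    chemistry: Mapping[str, tuple[pd.DataFrame, pd.DataFrame]] | None = None,
    distance_weight: Callable[[int], float] = reciprocal_hop_weight,
) -> pd.DataFrame:
    """Compute the 20 x 7 raw residue index table (rows in canonical order)."""
    if chemistry is None:
        chemistry = load_chemistry()
    rows = {}
    for res in RESIDUES:
        g = build_residue_graph(res, chemistry)
        rows[res] = [
            reach(g),
            branching_density(g),
            forking_index(g),
            net_partial_charge(g),
            average_polarity(g),
            hb_acceptor_index(g, distance_weight),
            hb_donor_index(g, distance_weight),
        ]
    table = pd.DataFrame.from_dict(rows, orient="index", columns=list(INDEX_COLUMNS))
    table = table.loc[list(RESIDUES)]
    if table.isna().any().any() or not np.isfinite(table.to_numpy()).all():
        raise ValueError("index table contains missing or non-finite values")
    return table


def write_index_table(table: pd.DataFrame, path) -> None:
    """Write an index table as TSV (residue row labels, named columns)."""
    table.to_csv(path, sep="\t", index_label="residue", float_format="%.6f")


_AAINDEX_ORDER = tuple("ARNDCQEGHILKMFPSTWYV")


def write_index_table_aaindex(table: pd.DataFrame, path, prefix: str = "UGTS") -> None:
    """Write each index column as an AAindex-style flat record.

    One record per column: H accession, D description, I header with the
    canonical A/R/N/D... residue order followed by two rows of ten values.
    """
    with open(path, "w") as fh:
        for k, col in enumerate(table.columns, start=1):
            vals = [table.loc[res, col] for res in _AAINDEX_ORDER]
            fh.write(f"H {prefix}{k:03d}\n")
            fh.write(f"D {col} (graph-derived side-chain index)\n")
            fh.write("I    A/L     R/K     N/M     D/F     C/P     Q/S     E/T     G/W     H/Y     I/V\n")
            for row in (vals[:10], vals[10:]):
                fh.write("  " + " ".join(f"{v:7.3f}" for v in row) + "\n")
            fh.write("//\n")
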