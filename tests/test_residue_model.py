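"""Side-chain graph construction and the seven residue indices, checked
against independent oracles built directly from the chemistry TSV tables."""

import networkx as nx
import numpy as np
import pandas as pd
import pytest

from ugtsel.residue_model import (
    RESIDUES,
    Atom,
    Bond,
    SideChainGraph,
    average_polarity,
    branching_density,
    build_residue_graph,
    compute_raw_index_table,
    forking_index,
    hb_acceptor_index,
    hb_donor_index,
    net_partial_charge,
    reach,
    reciprocal_hop_weight,
)


def path_graph(lengths, charges=None):
    """Cα-rooted path with given bond lengths: CA - X1 - X2 ..."""
    n = len(lengths) + 1
    charges = charges or [0.0] * n
    names = ["CA"] + [f"X{i}" for i in range(1, n)]
    atoms = tuple(Atom(nm, "C", q, 2.55) for nm, q in zip(names, charges))
    bonds = tuple(Bond(names[i], names[i + 1], lengths[i]) for i in range(n - 1))
    return SideChainGraph("A", "CA", atoms, bonds)


class TestGraphConstruction:
    def test_unknown_residue_rejected(self, chemistry):
        with pytest.raises(ValueError, match="unknown residue"):
            build_residue_graph("X", chemistry)

    def test_glycine_is_root_plus_hydrogen(self, chemistry):
        g = build_residue_graph("G", chemistry)
        elements = sorted(a.element for a in g.atoms)
        assert elements == ["C", "H"]
        assert g.root == "CA"

    def test_proline_has_cycle_through_root(self, chemistry):
        g = build_residue_graph("P", chemistry)
        cycles = nx.cycle_basis(g.graph)
        assert any("CA" in c for c in cycles)

    def test_alanine_node_count(self, chemistry):
        # CA + CB + 3 methyl hydrogens; the alpha-hydrogen belongs to the backbone
        g = build_residue_graph("A", chemistry)
        assert g.graph.number_of_nodes() == 5
        assert sorted(a.element for a in g.atoms) == ["C", "C", "H", "H", "H"]

    def test_all_graphs_connected_and_rooted(self, chemistry):
        for res in RESIDUES:
            g = build_residue_graph(res, chemistry)
            assert nx.is_connected(g.graph)
            assert g.root in g.graph

    def test_atom_invariants_enforced(self):
        with pytest.raises(ValueError, match="non-N/O/S"):
            Atom("C1", "C", 0.0, 2.55, hb_acceptor_lone_pairs=1)
        with pytest.raises(ValueError, match="endpoints"):
            Bond("A1", "A1", 1.0)


class TestReach:
    def test_single_node_graph(self):
        g = SideChainGraph("G", "CA", (Atom("CA", "C", 0.0, 2.55),), ())
        assert reach(g) == 0.0

    def test_two_bond_path(self):
        assert reach(path_graph([1.5, 1.0])) == pytest.approx(2.5)

    @pytest.mark.parametrize("res", RESIDUES)
    def test_matches_all_simple_paths_oracle(self, res, chemistry):
        """Brute force: min over all simple root-to-node paths, max over nodes."""
        g = build_residue_graph(res, chemistry)
        best = 0.0
        for node in g.graph.nodes:
            if node == g.root:
                continue
            dists = []
            for path in nx.all_simple_paths(g.graph, g.root, node):
                dists.append(
                    sum(g.graph.edges[a, b]["length"] for a, b in zip(path, path[1:]))
                )
            best = max(best, min(dists))
        assert reach(g) == pytest.approx(best)
        assert reach(g) >= max(b.length for b in g.bonds)


class TestBranchingDensity:
    def test_three_node_path(self):
        assert branching_density(path_graph([1.0, 1.0])) == pytest.approx(2.0)

    def test_star(self):
        atoms = tuple([Atom("CA", "C", 0, 2.55)] + [Atom(f"X{i}", "H", 0, 2.2) for i in range(4)])
        bonds = tuple(Bond("CA", f"X{i}", 1.09) for i in range(4))
        g = SideChainGraph("A", "CA", atoms, bonds)
        assert branching_density(g) == pytest.approx(4.0)

    def test_leucine_degree_census_oracle(self, chemistry):
        """Independent census from the bonds table, not the graph object."""
        _, bonds = chemistry["L"]
        counts = pd.concat([bonds.atom1, bonds.atom2]).value_counts()
        expected = counts[counts >= 2].mean()
        g = build_residue_graph("L", chemistry)
        assert branching_density(g) == pytest.approx(expected)

    def test_no_internal_nodes_gives_zero(self):
        g = path_graph([1.0])  # two nodes, both leaves
        assert branching_density(g) == 0.0


class TestForkingIndex:
    def test_short_path(self):
        # CA - a - b: 'a' is internal at hop 1, b is a leaf
        assert forking_index(path_graph([1.0, 1.0])) == pytest.approx(1.0)

    def test_leafless_contribution_zero(self):
        assert forking_index(path_graph([1.0])) == 0.0

    def test_valine_bfs_layer_oracle(self, chemistry):
        """BFS layers rebuilt from the bonds table alone."""
        _, bonds = chemistry["V"]
        adj = {}
        for r in bonds.itertuples():
            adj.setdefault(r.atom1, set()).add(r.atom2)
            adj.setdefault(r.atom2, set()).add(r.atom1)
        hops, frontier, d = {"CA": 0}, {"CA"}, 0
        while frontier:
            d += 1
            frontier = {n for f in frontier for n in adj[f] if n not in hops}
            hops.update({n: d for n in frontier})
        expected = sum(
            1.0 / h for n, h in hops.items() if h >= 1 and len(adj[n]) >= 2
        )
        assert forking_index(build_residue_graph("V", chemistry)) == pytest.approx(expected)


class TestChargeAndPolarity:
    def test_cancellation(self):
        g = path_graph([1.0], charges=[0.3, -0.3])
        assert net_partial_charge(g) == pytest.approx(0.0)

    def test_aspartate_matches_table_column_sum(self, chemistry):
        atoms, _ = chemistry["D"]
        g = build_residue_graph("D", chemistry)
        assert net_partial_charge(g) == pytest.approx(atoms.partial_charge.sum())

    def test_uniform_charges_zero_polarity(self):
        g = path_graph([1.0, 2.0], charges=[0.1, 0.1, 0.1])
        assert average_polarity(g) == pytest.approx(0.0)

    def test_single_bond_dipole(self):
        g = path_graph([1.5], charges=[0.2, -0.2])
        assert average_polarity(g) == pytest.approx(0.4 * 1.5)

    def test_serine_per_bond_oracle(self, chemistry):
        atoms, bonds = chemistry["S"]
        q = dict(zip(atoms.atom, atoms.partial_charge))
        expected = np.mean(
            [abs(q[r.atom1] - q[r.atom2]) * r.length for r in bonds.itertuples()]
        )
        assert average_polarity(build_residue_graph("S", chemistry)) == pytest.approx(expected)


class TestHydrogenBondIndices:
    def test_alanine_has_no_hb_terms(self, chemistry):
        g = build_residue_graph("A", chemistry)
        assert hb_acceptor_index(g) == 0.0
        assert hb_donor_index(g) == 0.0

    def test_asparagine_acceptor_term_oracle(self, chemistry):
        """Enumerate qualifying lone pairs from the TSV with BFS hop distances."""
        atoms, bonds = chemistry["N"]
        g = build_residue_graph("N", chemistry)
        import networkx as nx

        hops = nx.single_source_shortest_path_length(g.graph, "CA")
        expected = sum(
            r.hb_acceptor_lone_pairs * r.electronegativity * reciprocal_hop_weight(hops[r.atom])
            for r in atoms.itertuples()
            if r.hb_acceptor_lone_pairs > 0
        )
        assert hb_acceptor_index(g) == pytest.approx(expected)

    def test_lysine_three_donor_hydrogens_share_nitrogen_weight(self, chemistry):
        atoms, _ = chemistry["K"]
        g = build_residue_graph("K", chemistry)
        import networkx as nx

        hops = nx.single_source_shortest_path_length(g.graph, "CA")
        n_name = atoms[atoms.element == "N"].atom.iloc[0]
        en_n = atoms[atoms.element == "N"].electronegativity.iloc[0]
        expected = 3 * en_n * reciprocal_hop_weight(hops[n_name])
        assert hb_donor_index(g) == pytest.approx(expected)

    def test_custom_distance_weight_hook(self, chemistry):
        g = build_residue_graph("S", chemistry)
        unweighted = hb_acceptor_index(g, distance_weight=lambda d: 1.0)
        assert unweighted > hb_acceptor_index(g)


class TestIndexTable:
    def test_shape_and_finite(self, raw_table):
        assert raw_table.shape == (20, 7)
        assert np.isfinite(raw_table.to_numpy()).all()
        assert list(raw_table.index) == list(RESIDUES)

    def test_deterministic(self, chemistry, raw_table):
        again = compute_raw_index_table(chemistry)
        assert (again.to_numpy() == raw_table.to_numpy()).all()

    def test_aaindex_export_has_seven_records(self, raw_table, tmp_path):
        from ugtsel.residue_model import write_index_table_aaindex

        path = tmp_path / "indices.aaindex"
        write_index_table_aaindex(raw_table, path)
        text = path.read_text()
        assert text.count("//") == 7
        assert text.count("H UGTS") == 7

    def test_relabeling_invariance(self, chemistry):
        """Renaming node identifiers leaves all seven indices unchanged."""
        g = build_residue_graph("T", chemistry)
        renamed = SideChainGraph(
            residue="T",
            root="r0",
            atoms=tuple(
                Atom(f"r{i}", a.element, a.partial_charge, a.electronegativity,
                     a.hb_acceptor_lone_pairs, a.is_hb_donor_h)
                for i, a in enumerate(g.atoms)
            ),
            bonds=tuple(
                Bond(
                    f"r{[x.name for x in g.atoms].index(b.a)}",
                    f"r{[x.name for x in g.atoms].index(b.b)}",
                    b.length,
                )
                for b in g.bonds
            ),
        )
        for fn in (reach, branching_density, forking_index, net_partial_charge,
                   average_polarity, hb_acceptor_index, hb_donor_index):
            assert fn(renamed) == pytest.approx(fn(g))
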