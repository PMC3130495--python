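"""Regenerate the packaged side-chain chemistry tables.

Builds each of the 20 standard amino acids (pH-7 protonation states: Lys+,
Arg+, Asp-, Glu-, neutral His epsilon-tautomer) with rdkit, computes
Gasteiger-Marsili partial charges on the free amino acid, and extracts the
alpha-carbon + side-chain subgraph (plus proline's backbone ring closure).
Bond lengths are idealized covalent values; electronegativities are Pauling.

Output: src/ugtsel/data/chemistry_atoms.tsv, chemistry_bonds.tsv.
Run from the repository root:  python scripts/make_chemistry.py
"""

from __future__ import annotations

import collections
from pathlib import Path

from rdkit import Chem
from rdkit.Chem import AllChem

SMILES = {
    "A": "NC(C)C(=O)O",
    "R": "NC(CCCNC(N)=[NH2+])C(=O)O",
    "N": "NC(CC(N)=O)C(=O)O",
    "D": "NC(CC(=O)[O-])C(=O)O",
    "C": "NC(CS)C(=O)O",
    "E": "NC(CCC(=O)[O-])C(=O)O",
    "Q": "NC(CCC(N)=O)C(=O)O",
    "G": "NCC(=O)O",
    "H": "NC(Cc1c[nH]cn1)C(=O)O",  # neutral, H on NE2 (epsilon tautomer)
    "I": "NC(C(C)CC)C(=O)O",
    "L": "NC(CC(C)C)C(=O)O",
    "K": "NC(CCCC[NH3+])C(=O)O",
    "M": "NC(CCSC)C(=O)O",
    "F": "NC(Cc1ccccc1)C(=O)O",
    "P": "OC(=O)C1CCCN1",
    "S": "NC(CO)C(=O)O",
    "T": "NC(C(C)O)C(=O)O",
    "W": "NC(Cc1c[nH]c2ccccc12)C(=O)O",
    "Y": "NC(Cc1ccc(O)cc1)C(=O)O",
    "V": "NC(C(C)C)C(=O)O",
}

PAULING = {"H": 2.20, "C": 2.55, "N": 3.04, "O": 3.44, "S": 2.58}

# idealized covalent bond lengths, Angstrom
BOND_LENGTHS = {
    ("C", "C", "1"): 1.54,
    ("C", "C", "ar"): 1.40,
    ("C", "N", "1"): 1.47,
    ("C", "N", "ar"): 1.34,
    ("C", "N", "2"): 1.32,
    ("C", "O", "1"): 1.43,
    ("C", "O", "2"): 1.22,
    ("C", "S", "1"): 1.81,
    ("C", "H", "1"): 1.09,
    ("H", "N", "1"): 1.01,
    ("H", "O", "1"): 0.96,
    ("H", "S", "1"): 1.34,
}
CARBOXYLATE_CO = 1.25  # delocalized C-O(-) bond


def bond_length(bond: Chem.Bond) -> float:
    a, b = bond.GetBeginAtom(), bond.GetEndAtom()
    ea, eb = sorted((a.GetSymbol(), b.GetSymbol()))
    if {ea, eb} == {"C", "O"} and (a.GetFormalCharge() == -1 or b.GetFormalCharge() == -1):
        return CARBOXYLATE_CO
    if bond.GetIsAromatic():
        order = "ar"
    else:
        order = str(int(bond.GetBondTypeAsDouble()))
    return BOND_LENGTHS[(ea, eb, order)]


def extract_side_chain(code: str):
    mol = Chem.MolFromSmiles(SMILES[code])
    mol = Chem.AddHs(mol)
    AllChem.ComputeGasteigerCharges(mol)

    patt = Chem.MolFromSmarts("[CX3](=O)[OX2H1,OX1-]")
    ca = backbone_n = match = None
    for m in mol.GetSubstructMatches(patt):
        carboxyl_c = mol.GetAtomWithIdx(m[0])
        for cand in carboxyl_c.GetNeighbors():
            if cand.GetSymbol() != "C":
                continue
            n_nbr = [n for n in cand.GetNeighbors() if n.GetSymbol() == "N"]
            if n_nbr:
                ca, backbone_n, match = cand, n_nbr[0], m
                break
        if ca is not None:
            break
    if ca is None:
        raise RuntimeError(f"backbone not found for {code}")

    excluded = set(match)
    for idx in match[1:]:
        for n in mol.GetAtomWithIdx(idx).GetNeighbors():
            if n.GetSymbol() == "H":
                excluded.add(n.GetIdx())
    excluded.add(backbone_n.GetIdx())
    for n in backbone_n.GetNeighbors():
        if n.GetSymbol() == "H":
            excluded.add(n.GetIdx())
    alpha_hs = [n.GetIdx() for n in ca.GetNeighbors() if n.GetSymbol() == "H"]
    if code == "G":
        excluded.update(alpha_hs[1:])  # keep exactly one H as glycine's side chain
    else:
        excluded.update(alpha_hs)

    # BFS from CA; proline's backbone N is kept as a terminal ring-closure node
    keep = [ca.GetIdx()]
    seen = {ca.GetIdx()}
    queue = collections.deque([ca.GetIdx()])
    while queue:
        cur = queue.popleft()
        for n in mol.GetAtomWithIdx(cur).GetNeighbors():
            i = n.GetIdx()
            if i in seen:
                continue
            if i == backbone_n.GetIdx():
                if code == "P" and cur != ca.GetIdx():
                    seen.add(i)
                    keep.append(i)  # terminal: do not traverse through
                continue
            if i in excluded:
                continue
            seen.add(i)
            keep.append(i)
            queue.append(i)
    if code == "P":
        if backbone_n.GetIdx() not in seen:
            raise RuntimeError("proline ring closure not found")

    counters: dict[str, int] = collections.defaultdict(int)
    names = {}
    for i in keep:
        atom = mol.GetAtomWithIdx(i)
        if i == ca.GetIdx():
            names[i] = "CA"
        elif i == backbone_n.GetIdx():
            names[i] = "N"
        else:
            el = atom.GetSymbol()
            counters[el] += 1
            names[i] = f"{el}{counters[el]}"

    atoms = []
    for i in keep:
        atom = mol.GetAtomWithIdx(i)
        el = atom.GetSymbol()
        charge = float(atom.GetProp("_GasteigerCharge"))
        h_nbrs = [n for n in atom.GetNeighbors() if n.GetSymbol() == "H" and n.GetIdx() in seen]
        lone_pairs = 0
        if i != backbone_n.GetIdx():
            if el == "O":
                lone_pairs = 2
            elif el == "N" and atom.GetIsAromatic() and atom.GetTotalNumHs(includeNeighbors=True) == 0:
                lone_pairs = 1  # His ND1 pyridine-type nitrogen
            elif el == "S" and not h_nbrs:
                lone_pairs = 2  # Met thioether; Cys S-H deemed a negligible acceptor
        donor_h = 0
        if el == "H":
            heavy = atom.GetNeighbors()[0]
            if heavy.GetSymbol() in ("N", "O", "S") and heavy.GetIdx() in seen:
                donor_h = 1
        atoms.append((names[i], el, charge, PAULING[el], lone_pairs, donor_h))

    bonds = []
    for bond in mol.GetBonds():
        i, j = bond.GetBeginAtomIdx(), bond.GetEndAtomIdx()
        if i in seen and j in seen:
            bonds.append((names[i], names[j], bond_length(bond)))
    return atoms, bonds


def main() -> None:
    out = Path(__file__).resolve().parent.parent / "src" / "ugtsel" / "data"
    out.mkdir(parents=True, exist_ok=True)
    with open(out / "chemistry_atoms.tsv", "w") as fa, open(out / "chemistry_bonds.tsv", "w") as fb:
        fa.write("residue\tatom\telement\tpartial_charge\telectronegativity\thb_acceptor_lone_pairs\tis_hb_donor_h\n")
        fb.write("residue\tatom1\tatom2\tlength\n")
        for code in sorted(SMILES):
            atoms, bonds = extract_side_chain(code)
            for name, el, q, en, lp, dh in atoms:
                fa.write(f"{code}\t{name}\t{el}\t{q:.6f}\t{en:.2f}\t{lp}\t{dh}\n")
            for a, b, length in bonds:
                fb.write(f"{code}\t{a}\t{b}\t{length:.3f}\n")
    print("wrote", out)


if __name__ == "__main__":
    main()
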