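"""Test-only brute-force single-cut MMP oracle.

Independent of the package's fragmentation machinery: bonds are deleted one at
a time on editable copies, hydrogen sites come from making every hydrogen
explicit (no symmetry reduction), and the shared-core search is a raw
set-intersection with plain loops. Only the fragment *rendering* convention
(canonical SMILES rooted at the [*:1] attachment) is shared with the package,
as part of its output contract.
"""

from __future__ import annotations

from functools import lru_cache

from rdkit import Chem


def rooted(mol: Chem.Mol) -> str:
    dummy = next(a.GetIdx() for a in mol.GetAtoms() if a.GetAtomicNum() == 0)
    return Chem.MolToSmiles(mol, rootedAtAtom=dummy, canonical=True)


@lru_cache(maxsize=100_000)
def heavy_count(fragment_smiles: str) -> int:
    mol = Chem.MolFromSmiles(fragment_smiles)
    return sum(1 for a in mol.GetAtoms() if a.GetAtomicNum() > 1)


def brute_force_fragmentations(smiles: str) -> set[tuple[str, str]]:
    """All (core, r_group) single-cut splits, both orientations per bond plus
    one hydrogen site per explicit hydrogen."""
    mol = Chem.MolFromSmiles(smiles)
    out: set[tuple[str, str]] = set()
    for bond in mol.GetBonds():
        if bond.IsInRing() or bond.GetBondTypeAsDouble() != 1.0:
            continue
        if (
            bond.GetBeginAtom().GetAtomicNum() < 2
            or bond.GetEndAtom().GetAtomicNum() < 2
        ):
            continue
        em = Chem.RWMol(mol)
        i, j = bond.GetBeginAtomIdx(), bond.GetEndAtomIdx()
        em.RemoveBond(i, j)
        for idx in (i, j):
            d = em.AddAtom(Chem.Atom(0))
            em.GetAtomWithIdx(d).SetAtomMapNum(1)
            em.AddBond(idx, d, Chem.BondType.SINGLE)
        frag = em.GetMol()
        Chem.SanitizeMol(frag)
        parts = Chem.GetMolFrags(frag, asMols=True)
        assert len(parts) == 2
        a, b = (rooted(p) for p in parts)
        out.add((a, b))
        out.add((b, a))
    molh = Chem.AddHs(mol)
    for atom in molh.GetAtoms():
        if atom.GetAtomicNum() != 1:
            continue
        em = Chem.RWMol(molh)
        em.GetAtomWithIdx(atom.GetIdx()).SetAtomicNum(0)
        em.GetAtomWithIdx(atom.GetIdx()).SetAtomMapNum(1)
        core = Chem.RemoveHs(em.GetMol())
        Chem.SanitizeMol(core)
        out.add((rooted(core), "[*:1][H]"))
    return out


def brute_force_index(smiles: str) -> dict[str, list[str]]:
    index: dict[str, list[str]] = {}
    for core, r in brute_force_fragmentations(smiles):
        index.setdefault(core, []).append(r)
    for rs in index.values():
        rs.sort()
    return index


def brute_force_mmp_from_indices(
    sa: str, sb: str, index_a: dict[str, list[str]], index_b: dict[str, list[str]]
):
    """Best shared core (max heavy atoms, ties by lexicographic core SMILES);
    returns (core, r_a, r_b) or None."""
    if sa == sb:
        return None
    best = None
    for core in set(index_a) & set(index_b):
        r_a = index_a[core][0]
        r_b = index_b[core][0]
        if r_a == r_b:
            continue
        key = (-heavy_count(core), core)
        if best is None or key < best[0]:
            best = (key, core, r_a, r_b)
    if best is None:
        return None
    return best[1], best[2], best[3]


def brute_force_mmp(sa: str, sb: str):
    sa = Chem.MolToSmiles(Chem.MolFromSmiles(sa))
    sb = Chem.MolToSmiles(Chem.MolFromSmiles(sb))
    return brute_force_mmp_from_indices(
        sa, sb, brute_force_index(sa), brute_force_index(sb)
    )
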