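"""Single-cut matched-molecular-pair (MMP) detection and filtering.

An MMP is a pair of molecules that differ by a single localized transformation:
both can be fragmented, by cutting one acyclic single bond (or abstracting one
hydrogen), into a shared *core* and two different *R-groups*, each fragment
carrying one attachment point ``[*:1]``. The transformation is rendered as a
SMIRKS-like string ``r_source>>r_target``, e.g. ``[*:1][H]>>[*:1]C`` for a
hydrogen-to-methyl replacement.

Hydrogen replacement is modeled with an explicit ``[*:1][H]`` R-group so that
H-to-substituent transformations arise from the same shared-core machinery as
heavy-bond cuts.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from functools import lru_cache

from rdkit import Chem

from molopt.chemio import (
    EmptyCorpusError,
    Molecule,
    heavy_atoms,
    mol_from_smiles,
    molecule_from_mol,
)

HYDROGEN_R = "[*:1][H]"


@dataclass(frozen=True)
class Fragmentation:
    """One way of splitting a molecule into core + R-group.

    ``cut_bond`` is the (begin, end) atom-index pair of the broken bond, or
    ``("H", atom_index)`` for a hydrogen-abstraction site.
    """

    core: str
    r_group: str
    cut_bond: tuple


@dataclass(frozen=True)
class MatchedPair:
    source: Molecule
    target: Molecule
    core: str
    transformation: str  # "r_source>>r_target" with [*:1] maps
    r_source_heavy: int
    r_target_heavy: int

    @property
    def r_source(self) -> str:
        return self.transformation.split(">>")[0]

    @property
    def r_target(self) -> str:
        return self.transformation.split(">>")[1]

    def reverse(self) -> "MatchedPair":
        return MatchedPair(
            source=self.target,
            target=self.source,
            core=self.core,
            transformation=f"{self.r_target}>>{self.r_source}",
            r_source_heavy=self.r_target_heavy,
            r_target_heavy=self.r_source_heavy,
        )


@dataclass(frozen=True)
class MMPFilterConfig:
    """Extraction constraints on core size, R-group size/ratio and H-bonding."""

    max_core_heavy: int = 50
    max_r_heavy: int = 13
    max_r_ratio: float = 0.33
    max_r_hbd: int = 3
    max_r_hba: int = 3


def _as_mol(mol: Molecule | Chem.Mol | str) -> Chem.Mol:
    if isinstance(mol, Chem.Mol):
        return mol
    if isinstance(mol, Molecule):
        return mol_from_smiles(mol.smiles_canonical)
    return mol_from_smiles(mol)


def _fragment_smiles(mol: Chem.Mol) -> str:
    """Canonical SMILES of a one-attachment fragment, rooted at [*:1] so the
    attachment point is written first ("[*:1]C", not "C[*:1]")."""
    dummy = next(a.GetIdx() for a in mol.GetAtoms() if a.GetAtomicNum() == 0)
    return Chem.MolToSmiles(mol, rootedAtAtom=dummy, canonical=True)


def _cut_bond(mol: Chem.Mol, begin: int, end: int) -> tuple[str, str]:
    """Break one acyclic single bond; return the two fragments' canonical
    SMILES, the one containing ``begin`` first, each with one [*:1]."""
    em = Chem.RWMol(mol)
    em.RemoveBond(begin, end)
    for atom_idx in (begin, end):
        dummy = em.AddAtom(Chem.Atom(0))
        em.GetAtomWithIdx(dummy).SetAtomMapNum(1)
        em.AddBond(atom_idx, dummy, Chem.BondType.SINGLE)
    frag = em.GetMol()
    Chem.SanitizeMol(frag)
    pieces = Chem.GetMolFrags(frag)
    mols = Chem.GetMolFrags(frag, asMols=True)
    first = 0 if begin in pieces[0] else 1
    return _fragment_smiles(mols[first]), _fragment_smiles(mols[1 - first])


def _h_site_core(mol: Chem.Mol, atom_idx: int) -> str:
    """Replace one hydrogen on ``atom_idx`` by a [*:1] attachment point."""
    em = Chem.RWMol(mol)
    atom = em.GetAtomWithIdx(atom_idx)
    if atom.GetNumExplicitHs() > 0:
        atom.SetNumExplicitHs(atom.GetNumExplicitHs() - 1)
    dummy = em.AddAtom(Chem.Atom(0))
    em.GetAtomWithIdx(dummy).SetAtomMapNum(1)
    em.AddBond(atom_idx, dummy, Chem.BondType.SINGLE)
    out = em.GetMol()
    Chem.SanitizeMol(out)
    return _fragment_smiles(out)


def enumerate_single_cuts(mol: Molecule | Chem.Mol | str) -> list[Fragmentation]:
    """Enumerate all single-cut fragmentations of a molecule.

    Every acyclic single bond between two heavy atoms contributes a
    fragmentation in both orientations (core/R-group swapped; one entry when
    symmetric), and every symmetry-distinct heavy atom bearing at least one
    hydrogen contributes a hydrogen-site fragmentation with R-group
    ``[*:1][H]``. Duplicate (core, r_group) combinations are collapsed.
    """
    rdmol = _as_mol(mol)
    frags: list[Fragmentation] = []
    seen: set[tuple[str, str]] = set()

    for bond in rdmol.GetBonds():
        if bond.IsInRing() or bond.GetBondType() != Chem.BondType.SINGLE:
            continue
        a, b = bond.GetBeginAtom(), bond.GetEndAtom()
        if a.GetAtomicNum() <= 1 or b.GetAtomicNum() <= 1:
            continue
        ai, bi = a.GetIdx(), b.GetIdx()
        frag_a, frag_b = _cut_bond(rdmol, ai, bi)
        for core, r_group, cut in (
            (frag_a, frag_b, (ai, bi)),
            (frag_b, frag_a, (bi, ai)),
        ):
            if (core, r_group) not in seen:
                seen.add((core, r_group))
                frags.append(Fragmentation(core=core, r_group=r_group, cut_bond=cut))

    ranks = list(Chem.CanonicalRankAtoms(rdmol, breakTies=False))
    done_ranks: set[int] = set()
    for atom in rdmol.GetAtoms():
        if atom.GetAtomicNum() <= 1 or atom.GetTotalNumHs() < 1:
            continue
        rank = ranks[atom.GetIdx()]
        if rank in done_ranks:
            continue
        done_ranks.add(rank)
        core = _h_site_core(rdmol, atom.GetIdx())
        if (core, HYDROGEN_R) not in seen:
            seen.add((core, HYDROGEN_R))
            frags.append(
                Fragmentation(core=core, r_group=HYDROGEN_R, cut_bond=("H", atom.GetIdx()))
            )
    return frags


def weld(core: str, r_group: str) -> Molecule:
    """Join a core and an R-group at their [*:1] attachment points.

    An ``[*:1][H]`` R-group restores a hydrogen, i.e. returns the bare core
    molecule.
    """
    combined = Chem.CombineMols(mol_from_smiles(core), mol_from_smiles(r_group))
    zipped = Chem.molzip(combined)
    Chem.SanitizeMol(zipped)
    zipped = Chem.RemoveHs(zipped)
    return molecule_from_mol(zipped)


@lru_cache(maxsize=200_000)
def fragment_heavy_atoms(fragment_smiles: str) -> int:
    """Heavy atoms of a [*:1]-bearing fragment, excluding the dummy.

    Cached: shared-core searches over molecule libraries re-evaluate the same
    fragment strings many times.
    """
    return heavy_atoms(mol_from_smiles(fragment_smiles))


def fragment_index(mol: Molecule | Chem.Mol | str) -> dict[str, list[str]]:
    """Map core SMILES -> sorted R-groups over all single-cut fragmentations.

    Precompute this per molecule when matching one molecule against many
    (corpus construction, evaluating generated sets against a start molecule).
    """
    index: dict[str, list[str]] = {}
    for f in enumerate_single_cuts(mol):
        index.setdefault(f.core, []).append(f.r_group)
    for rs in index.values():
        rs.sort()
    return index


def pair_from_indices(
    a: Molecule,
    b: Molecule,
    index_a: dict[str, list[str]],
    index_b: dict[str, list[str]],
) -> MatchedPair | None:
    """Build the MatchedPair for two pre-fragmented molecules (see find_mmp)."""
    if a.smiles_canonical == b.smiles_canonical:
        return None
    candidates = []
    for core in index_a.keys() & index_b.keys():
        r_a, r_b = index_a[core][0], index_b[core][0]
        if r_a == r_b:
            continue
        candidates.append((fragment_heavy_atoms(core), core, r_a, r_b))
    if not candidates:
        return None
    # max core heavy atoms, then lexicographic core SMILES
    candidates.sort(key=lambda c: (-c[0], c[1]))
    _, core, r_a, r_b = candidates[0]
    return MatchedPair(
        source=a,
        target=b,
        core=core,
        transformation=f"{r_a}>>{r_b}",
        r_source_heavy=fragment_heavy_atoms(r_a),
        r_target_heavy=fragment_heavy_atoms(r_b),
    )


def find_mmp(a: Molecule, b: Molecule) -> MatchedPair | None:
    """Detect whether two molecules form a single-cut MMP.

    Among all shared canonical cores the one with the most heavy atoms is
    chosen (smallest R-groups, i.e. the most localized transformation), ties
    broken by lexicographically smallest core SMILES. Returns ``None`` for
    identical molecules or when no single-cut core is shared.
    """
    if a.smiles_canonical == b.smiles_canonical:
        return None
    return pair_from_indices(a, b, fragment_index(a), fragment_index(b))


def r_group_ratio(pair: MatchedPair, side: str) -> float:
    """Heavy-atom ratio of the exchanged R-group to the whole molecule."""
    if side == "source":
        return pair.r_source_heavy / pair.source.heavy_atom_count
    if side == "target":
        return pair.r_target_heavy / pair.target.heavy_atom_count
    raise ValueError(f"side must be source/target, got {side!r}")


def passes_filters(
    pair: MatchedPair, cfg: MMPFilterConfig = MMPFilterConfig()
) -> tuple[bool, list[str]]:
    """Check a pair against the extraction constraints.

    Returns ``(ok, violated_rule_names)``. Corpus-level constraints (property
    outlier trimming, external quality filters) are handled by corpus hooks,
    not here.
    """
    violations: list[str] = []
    if fragment_heavy_atoms(pair.core) > cfg.max_core_heavy:
        violations.append("max_core_heavy")
    if max(pair.r_source_heavy, pair.r_target_heavy) > cfg.max_r_heavy:
        violations.append("max_r_heavy")
    if (
        r_group_ratio(pair, "source") > cfg.max_r_ratio
        or r_group_ratio(pair, "target") > cfg.max_r_ratio
    ):
        violations.append("max_r_ratio")
    for r_smiles in (pair.r_source, pair.r_target):
        frag = molecule_from_mol(mol_from_smiles(r_smiles))
        if frag.hbd > cfg.max_r_hbd and "max_r_hbd" not in violations:
            violations.append("max_r_hbd")
        if frag.hba > cfg.max_r_hba and "max_r_hba" not in violations:
            violations.append("max_r_hba")
    return (not violations, violations)


@dataclass
class TransformationStats:
    pct_unique: float
    pct_singletons: float
    pct_top1: float
    pct_top20: float
    top20: list[tuple[str, int]] = field(default_factory=list)


def transformation_stats(pairs: list[MatchedPair]) -> TransformationStats:
    """Frequency statistics of transformations over a pair corpus.

    Percentages are relative to the number of pairs; the top-20 list is
    ordered by count (descending) then lexicographic SMIRKS.
    """
    if not pairs:
        raise EmptyCorpusError("transformation_stats requires at least one pair")
    counts = Counter(p.transformation for p in pairs)
    n = len(pairs)
    singletons = sum(1 for c in counts.values() if c == 1)
    ranked = sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
    top20 = ranked[:20]
    return TransformationStats(
        pct_unique=100.0 * len(counts) / n,
        pct_singletons=100.0 * singletons / n,
        pct_top1=100.0 * ranked[0][1] / n,
        pct_top20=100.0 * sum(c for _, c in top20) / n,
        top20=top20,
    )
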