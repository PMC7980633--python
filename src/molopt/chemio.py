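"""SMILES canonicalization, tokenization and vocabulary handling.

Molecules are carried around as canonical SMILES plus a few cached descriptors.
Tokenization is a lossless longest-match split: bracket expressions (``[nH]``),
two-character organic-subset halogens (``Cl``, ``Br``), two-digit ring closures
(``%12``) and every remaining single character each become one token, so that
joining the tokens reproduces the input string exactly.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from rdkit import Chem, RDLogger
from rdkit.Chem import Lipinski

RDLogger.DisableLog("rdApp.*")


class ParseError(ValueError):
    """Raised when a SMILES string cannot be parsed."""

    def __init__(self, smiles: str):
        self.smiles = smiles
        super().__init__(f"unparseable SMILES: {smiles!r}")


class EmptyCorpusError(ValueError):
    """Raised when an operation requires a non-empty corpus."""


@dataclass(frozen=True)
class Molecule:
    """A molecule identified by its canonical SMILES.

    ``heavy_atom_count`` excludes hydrogens and attachment-point dummy atoms;
    ``hbd``/``hba`` are Lipinski hydrogen-bond donor/acceptor counts.
    """

    smiles_canonical: str
    heavy_atom_count: int
    hbd: int
    hba: int

    def __str__(self) -> str:  # pragma: no cover - convenience
        return self.smiles_canonical


@dataclass(frozen=True)
class TokenSequence:
    """An ordered token list tagged as model source or target."""

    tokens: tuple[str, ...]
    kind: str = "source"  # "source" | "target"

    def __post_init__(self):
        if self.kind not in ("source", "target"):
            raise ValueError(f"kind must be source/target, got {self.kind!r}")
        object.__setattr__(self, "tokens", tuple(self.tokens))

    def __len__(self) -> int:
        return len(self.tokens)

    def __iter__(self):
        return iter(self.tokens)


def mol_from_smiles(smiles: str) -> Chem.Mol:
    """Parse SMILES into an RDKit mol, raising :class:`ParseError` on failure."""
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise ParseError(smiles)
    return mol


def heavy_atoms(mol: Chem.Mol) -> int:
    """Heavy-atom count excluding attachment dummies (atomic number 0)."""
    return sum(1 for a in mol.GetAtoms() if a.GetAtomicNum() > 1)


def molecule_from_mol(mol: Chem.Mol) -> Molecule:
    return Molecule(
        smiles_canonical=Chem.MolToSmiles(mol),
        heavy_atom_count=heavy_atoms(mol),
        hbd=Lipinski.NumHDonors(mol),
        hba=Lipinski.NumHAcceptors(mol),
    )


def canonicalize(smiles: str) -> Molecule:
    """Standardize a SMILES string to RDKit's canonical form.

    Idempotent: canonicalizing the returned SMILES is a fixed point.
    """
    return molecule_from_mol(mol_from_smiles(smiles))


# Longest-match token classes: bracket atoms, %NN ring closures, Cl/Br,
# then any single character. Matches any text, so tokenization never fails
# and re-joining tokens is exactly the input (lossless).
_TOKEN_RE = re.compile(r"\[[^\]]*\]|%\d{2}|Cl|Br|.")


def tokenize_smiles(smiles: str, kind: str = "target") -> TokenSequence:
    """Split a SMILES string into tokens; ``"".join(tokens) == smiles``."""
    return TokenSequence(tuple(_TOKEN_RE.findall(smiles)), kind=kind)


def detokenize(tokens: Iterable[str]) -> str:
    return "".join(tokens)


START, END, PAD, UNK = "^", "$", " ", "?"
SPECIALS = (PAD, START, END, UNK)


@dataclass
class Vocabulary:
    """Token <-> contiguous-id map with pad/start/end/unknown specials.

    Ordering is deterministic: the four specials first (pad gets id 0 so that
    padded batches are zero-filled), then all remaining tokens sorted
    lexicographically.
    """

    token_to_id: dict[str, int] = field(default_factory=dict)

    @classmethod
    def build(
        cls,
        corpus: Sequence[TokenSequence],
        property_tokens: Sequence[str] = (),
    ) -> "Vocabulary":
        """Collect every observed token plus property-change tokens and specials."""
        if len(corpus) == 0:
            raise EmptyCorpusError("cannot build a vocabulary from an empty corpus")
        seen: set[str] = set()
        for seq in corpus:
            seen.update(seq.tokens)
        seen.update(property_tokens)
        seen.difference_update(SPECIALS)
        tokens = list(SPECIALS) + sorted(seen)
        return cls({tok: i for i, tok in enumerate(tokens)})

    def __len__(self) -> int:
        return len(self.token_to_id)

    def __contains__(self, token: str) -> bool:
        return token in self.token_to_id

    @property
    def id_to_token(self) -> dict[int, str]:
        return {i: t for t, i in self.token_to_id.items()}

    @property
    def pad_id(self) -> int:
        return self.token_to_id[PAD]

    @property
    def start_id(self) -> int:
        return self.token_to_id[START]

    @property
    def end_id(self) -> int:
        return self.token_to_id[END]

    @property
    def unk_id(self) -> int:
        return self.token_to_id[UNK]

    def encode(self, tokens: Iterable[str]) -> list[int]:
        """Map tokens to ids; out-of-vocabulary tokens map to the unknown id."""
        unk = self.unk_id
        return [self.token_to_id.get(t, unk) for t in tokens]

    def decode(self, ids: Iterable[int]) -> list[str]:
        rev = self.id_to_token
        return [rev[i] for i in ids]

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.token_to_id, indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "Vocabulary":
        return cls(json.loads(Path(path).read_text()))


def read_smiles_file(path: str | Path) -> list[str]:
    """Read a plain-text SMILES file, one molecule per line."""
    return [ln.strip() for ln in Path(path).read_text().splitlines() if ln.strip()]


def write_smiles_file(path: str | Path, smiles: Iterable[str]) -> None:
    Path(path).write_text("\n".join(smiles) + "\n")
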