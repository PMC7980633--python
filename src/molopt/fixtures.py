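"""Deterministic synthetic MMP corpus: congeneric series on shared scaffolds.

The generator emulates the structure of an MMP training corpus extracted from
a large screening library: families of molecules sharing an aromatic scaffold
and differing in a single R-group, so that every same-scaffold ordered pair is
a matched molecular pair (reverse transformations included). The R-group
library includes hydrogen, so hydrogen-to-substituent transformations such as
``[*:1][H]>>[*:1]C`` — the most frequent transformation in real MMP corpora —
occur naturally.

Scaffolds carry at least nine heavy atoms and R-groups at most four, so every
pair clears the extraction filters (R-group heavy-atom ratio <= 0.33, HBD/HBA
<= 3). Scaffold polarity spans methylsulfonyl/morpholino (logD ~ 1) to
biphenyl/trifluoromethyl (logD ~ 4), which together with the descriptor-based
surrogate oracle yields a corpus where solubility is negatively and CLint
positively correlated with logD, property changes populate tens of logD bins,
and both solubility and CLint categories appear in both directions.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import numpy as np

from molopt.chemio import Molecule
from molopt.mmp import (
    MatchedPair,
    MMPFilterConfig,
    fragment_index,
    pair_from_indices,
    weld,
)
from molopt.props import BinningConfig, PropertyOracle, encode_logd_change, property_change

logger = logging.getLogger(__name__)


class FixtureError(AssertionError):
    """A generated corpus violates one of its contractual properties."""


DEFAULT_SCAFFOLDS: tuple[str, ...] = (
    "[*:1]c1ccc2ccccc2c1",          # naphthalene
    "[*:1]c1ccc(-c2ccccc2)cc1",     # biphenyl
    "[*:1]c1ccc(S(C)(=O)=O)cc1",    # methylsulfonylphenyl (polar)
    "[*:1]c1ccc(N2CCOCC2)cc1",      # morpholinophenyl (polar)
    "[*:1]c1ccc(C(F)(F)F)cc1",      # trifluoromethylphenyl (lipophilic)
    "[*:1]c1ccc2ncccc2c1",          # quinoline
    "[*:1]c1ccc(OC)c(OC)c1",        # dimethoxyphenyl
    "[*:1]c1ccc(-c2ncccn2)cc1",     # phenylpyrimidine
)

DEFAULT_R_LIBRARY: tuple[str, ...] = (
    "[*:1][H]",
    "[*:1]C",
    "[*:1]CC",
    "[*:1]CCC",
    "[*:1]C(C)C",
    "[*:1]CCCC",
    "[*:1]C(C)(C)C",
    "[*:1]F",
    "[*:1]Cl",
    "[*:1]Br",
    "[*:1]O",
    "[*:1]OC",
    "[*:1]OCC",
    "[*:1]N",
    "[*:1]NC",
    "[*:1]N(C)C",
    "[*:1]C#N",
    "[*:1]C(F)(F)F",
    "[*:1]C=C",
    "[*:1]CO",
    "[*:1]CCO",
    "[*:1]S",
    "[*:1]SC",
    "[*:1]C(C)=O",
    "[*:1]C(N)=O",
)


@dataclass(frozen=True)
class FixtureSpec:
    """Configuration of the synthetic corpus.

    ``n_scaffolds``/``r_library_size`` select prefixes of the built-in scaffold
    and R-group tables (or of user-supplied ones); the seed feeds any
    subsampling, the combinatorial enumeration itself being deterministic.
    """

    n_scaffolds: int = 8
    r_library_size: int = 25
    seed: int = 0
    scaffolds: tuple[str, ...] = DEFAULT_SCAFFOLDS
    r_library: tuple[str, ...] = DEFAULT_R_LIBRARY

    def __post_init__(self):
        if self.n_scaffolds > len(self.scaffolds):
            raise ValueError("n_scaffolds exceeds scaffold table size")
        if self.r_library_size > len(self.r_library):
            raise ValueError("r_library_size exceeds R-group table size")


@dataclass
class FixtureCorpus:
    molecules: list[Molecule]
    pairs: list[MatchedPair]
    spec: FixtureSpec
    # scaffold index of every molecule, aligned with `molecules`
    scaffold_of: list[int] = field(default_factory=list)


def generate_corpus(spec: FixtureSpec = FixtureSpec()) -> FixtureCorpus:
    """Weld every scaffold x R-group combination and pair all same-scaffold
    molecules (both directions).

    Pairs are constructed through the same shared-core machinery as
    ``find_mmp`` (fragmentations cached per molecule), so recorded cores and
    transformations match what MMP detection would report. Weld failures are
    excluded and logged; the full default tables produce none.
    """
    scaffolds = spec.scaffolds[: spec.n_scaffolds]
    r_library = spec.r_library[: spec.r_library_size]

    molecules: list[Molecule] = []
    scaffold_of: list[int] = []
    families: list[list[Molecule]] = []
    seen: set[str] = set()
    for s_idx, scaffold in enumerate(scaffolds):
        family: list[Molecule] = []
        for r in r_library:
            try:
                mol = weld(scaffold, r)
            except Exception:  # noqa: BLE001 - excluded, logged
                logger.warning("weld failed: %s + %s", scaffold, r)
                continue
            if mol.smiles_canonical in seen:
                logger.warning("duplicate weld skipped: %s", mol.smiles_canonical)
                continue
            seen.add(mol.smiles_canonical)
            molecules.append(mol)
            scaffold_of.append(s_idx)
            family.append(mol)
        families.append(family)

    indices = {m.smiles_canonical: fragment_index(m) for m in molecules}
    pairs: list[MatchedPair] = []
    for family in families:
        for a, b in itertools.permutations(family, 2):
            pair = pair_from_indices(
                a, b, indices[a.smiles_canonical], indices[b.smiles_canonical]
            )
            if pair is None:  # same-scaffold welds always share the scaffold core
                logger.warning("no MMP for %s / %s", a, b)
                continue
            pairs.append(pair)
    return FixtureCorpus(
        molecules=molecules, pairs=pairs, spec=spec, scaffold_of=scaffold_of
    )


@dataclass
class HealthReport:
    corr_logd_sol: float
    corr_logd_clint: float
    n_logd_bins: int
    sol_categories: set[str]
    clint_categories: set[str]
    n_filter_failures: int


def corpus_healthcheck(
    corpus: FixtureCorpus,
    oracle: PropertyOracle,
    cfg: BinningConfig = BinningConfig(),
    filter_cfg: MMPFilterConfig = MMPFilterConfig(),
) -> HealthReport:
    """Assert the corpus exhibits the correlation and diversity structure the
    training conditions require; raises :class:`FixtureError` naming the first
    violated property.
    """
    from molopt.mmp import passes_filters

    profiles = {m.smiles_canonical: oracle.predict(m) for m in corpus.molecules}
    logd = np.array([profiles[m.smiles_canonical].logd for m in corpus.molecules])
    sol = np.array([profiles[m.smiles_canonical].sol for m in corpus.molecules])
    clint = np.array([profiles[m.smiles_canonical].clint for m in corpus.molecules])
    corr_sol = float(np.corrcoef(logd, sol)[0, 1])
    corr_clint = float(np.corrcoef(logd, clint)[0, 1])

    bins: set[str] = set()
    sol_cats: set[str] = set()
    clint_cats: set[str] = set()
    n_bad = 0
    for pair in corpus.pairs:
        z = property_change(
            profiles[pair.source.smiles_canonical],
            profiles[pair.target.smiles_canonical],
            cfg,
        )
        bins.add(encode_logd_change(z.d_logd, cfg))
        sol_cats.add(z.sol_change)
        clint_cats.add(z.clint_change)
        if not passes_filters(pair, filter_cfg)[0]:
            n_bad += 1

    report = HealthReport(
        corr_logd_sol=corr_sol,
        corr_logd_clint=corr_clint,
        n_logd_bins=len(bins),
        sol_categories=sol_cats,
        clint_categories=clint_cats,
        n_filter_failures=n_bad,
    )
    if not corr_sol < -0.5:
        raise FixtureError(f"corr(logd, sol) = {corr_sol:.3f}, expected < -0.5")
    if not corr_clint > 0.5:
        raise FixtureError(f"corr(logd, clint) = {corr_clint:.3f}, expected > 0.5")
    if len(bins) < 10:
        raise FixtureError(f"only {len(bins)} logD-change bins populated, expected >= 10")
    if len(sol_cats) < 2:
        raise FixtureError(f"solubility categories {sol_cats}, expected >= 2")
    if len(clint_cats) < 2:
        raise FixtureError(f"CLint categories {clint_cats}, expected >= 2")
    if n_bad:
        raise FixtureError(f"{n_bad} pairs violate the extraction filters")
    return report
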