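"""Training-record assembly, data splits and the three evaluation test sets.

A training record pairs a source token sequence x — the three property-change
tokens followed by the source molecule's SMILES tokens (conditional mode), or
the SMILES tokens alone (unconditional) — with a target sequence y of the
target molecule's SMILES tokens. The corpus is split by first sampling a
fraction of all pairs, holding out 10% as test, and splitting the rest 90/10
into train/validation; every stage rounds half-up.

Three test sets mirror increasingly hard generalization:

* Test-Original — the held-out split itself, with each record's realized
  property change as the request.
* Test-Molecule — the subset of Test-Original whose starting molecules never
  appear as a source in training.
* Test-Property — starting molecules with low solubility, high CLint and logD
  in [2.0, 4.4], all given the same fixed request: logD change (-1.1, -0.9],
  solubility low->high, CLint high->low.
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np

from molopt.chemio import Molecule, TokenSequence, tokenize_smiles
from molopt.mmp import MatchedPair
from molopt.props import (
    HIGH_TO_LOW,
    LOW_TO_HIGH,
    BinningConfig,
    PropertyChange,
    PropertyOracle,
    change_tokens,
    property_change,
)


@dataclass(frozen=True)
class PairRecord:
    """One (x, y) training example plus its provenance."""

    x: TokenSequence
    y: TokenSequence
    pair: MatchedPair | None  # None when loaded without provenance
    z: PropertyChange | None  # None for unconditional records

    @property
    def source_molecule(self) -> Molecule | None:
        return self.pair.source if self.pair is not None else None


@dataclass(frozen=True)
class SplitSpec:
    """Sampling and split fractions; all sizes use round-half-up."""

    sample_frac: float = 0.02
    test_frac: float = 0.10
    valid_frac_of_rest: float = 0.10
    seed: int = 0

    def __post_init__(self):
        for f in (self.sample_frac, self.test_frac, self.valid_frac_of_rest):
            if not (0.0 < f <= 1.0):
                raise ValueError(f"fractions must lie in (0, 1], got {f}")


@dataclass
class Split:
    train: list[PairRecord]
    valid: list[PairRecord]
    test: list[PairRecord]


def round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


def split_sizes(n_pairs: int, spec: SplitSpec = SplitSpec()) -> dict[str, int]:
    """Notional split arithmetic for a corpus of ``n_pairs`` pairs.

    Example: 9,927,876 pairs at the default fractions gives 198,558 sampled,
    19,856 test, 17,870 validation and 160,832 training records.
    """
    sampled = round_half_up(spec.sample_frac * n_pairs)
    test = round_half_up(spec.test_frac * sampled)
    rest = sampled - test
    valid = round_half_up(spec.valid_frac_of_rest * rest)
    return {"sampled": sampled, "test": test, "valid": valid, "train": rest - valid}


def build_records(
    pairs: Sequence[MatchedPair],
    oracle: PropertyOracle,
    cfg: BinningConfig = BinningConfig(),
    conditional: bool = True,
) -> list[PairRecord]:
    """Encode pairs into training records (one per pair; reverse pairs are
    separate pairs, hence separate records). Duplicate (x, y) token pairs are
    dropped. Oracle failures propagate, tagged with the offending molecule.
    """
    profiles: dict[str, object] = {}

    def profile(mol: Molecule):
        key = mol.smiles_canonical
        if key not in profiles:
            try:
                profiles[key] = oracle.predict(mol)
            except Exception as exc:
                raise RuntimeError(f"property oracle failed on {key}") from exc
        return profiles[key]

    records: list[PairRecord] = []
    seen: set[tuple[tuple[str, ...], tuple[str, ...]]] = set()
    for pair in pairs:
        source_tokens = tokenize_smiles(pair.source.smiles_canonical).tokens
        y = tokenize_smiles(pair.target.smiles_canonical, kind="target")
        if conditional:
            z = property_change(profile(pair.source), profile(pair.target), cfg)
            x = TokenSequence(tuple(change_tokens(z, cfg)) + source_tokens, kind="source")
        else:
            z = None
            x = TokenSequence(source_tokens, kind="source")
        key = (x.tokens, y.tokens)
        if key in seen:
            continue
        seen.add(key)
        records.append(PairRecord(x=x, y=y, pair=pair, z=z))
    return records


def split(records: Sequence[PairRecord], spec: SplitSpec = SplitSpec()) -> Split:
    """Sample and split records reproducibly.

    Membership is a seeded permutation; sizes follow :func:`split_sizes`.
    """
    if len(records) < 10:
        raise ValueError(f"corpus too small to split: {len(records)} records")
    sizes = split_sizes(len(records), spec)
    rng = np.random.default_rng(spec.seed)
    order = rng.permutation(len(records))
    sampled = [records[i] for i in order[: sizes["sampled"]]]
    test = sampled[: sizes["test"]]
    rest = sampled[sizes["test"] :]
    valid = rest[: sizes["valid"]]
    train = rest[sizes["valid"] :]
    return Split(train=train, valid=valid, test=test)


def make_test_molecule(test: Sequence[PairRecord], train: Sequence[PairRecord]) -> list[PairRecord]:
    """Restrict to test records whose starting molecule never occurs as a
    training source (canonical-SMILES identity)."""
    train_sources = {r.pair.source.smiles_canonical for r in train}
    return [r for r in test if r.pair.source.smiles_canonical not in train_sources]


TEST_PROPERTY_CHANGE = PropertyChange(
    d_logd=-1.0, sol_change=LOW_TO_HIGH, clint_change=HIGH_TO_LOW
)


def make_test_property(
    test: Sequence[PairRecord],
    oracle: PropertyOracle,
    cfg: BinningConfig = BinningConfig(),
    logd_range: tuple[float, float] = (2.0, 4.4),
) -> list[PairRecord]:
    """Select starting molecules with low solubility, high CLint and logD in
    ``logd_range``, and overwrite every request with the fixed optimization
    goal (logD down one unit, solubility low->high, CLint high->low).
    """
    out: list[PairRecord] = []
    cache: dict[str, object] = {}
    for rec in test:
        mol = rec.pair.source
        key = mol.smiles_canonical
        if key not in cache:
            cache[key] = oracle.predict(mol)
        p = cache[key]
        if not (p.sol < cfg.sol_threshold and p.clint >= cfg.clint_threshold):
            continue
        if not (logd_range[0] <= p.logd <= logd_range[1]):
            continue
        z = TEST_PROPERTY_CHANGE
        source_tokens = tokenize_smiles(key).tokens
        x = TokenSequence(tuple(change_tokens(z, cfg)) + source_tokens, kind="source")
        out.append(PairRecord(x=x, y=rec.y, pair=rec.pair, z=z))
    return out


def write_records_tsv(path: str | Path, records: Sequence[PairRecord]) -> None:
    """Persist records as TSV with space-joined token columns."""
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t")
        writer.writerow(["source_seq", "target_seq"])
        for rec in records:
            writer.writerow([" ".join(rec.x.tokens), " ".join(rec.y.tokens)])


def read_records_tsv(path: str | Path) -> list[tuple[TokenSequence, TokenSequence]]:
    """Load (x, y) token sequences from TSV (provenance is not round-tripped)."""
    out = []
    with open(path, newline="") as fh:
        reader = csv.reader(fh, delimiter="\t")
        header = next(reader)
        if header[:2] != ["source_seq", "target_seq"]:
            raise ValueError(f"unexpected header {header!r} in {path}")
        for row in reader:
            out.append(
                (
                    TokenSequence(tuple(row[0].split(" ")), kind="source"),
                    TokenSequence(tuple(row[1].split(" ")), kind="target"),
                )
            )
    return out


def write_pairs_csv(path: str | Path, pairs: Sequence[MatchedPair]) -> None:
    """Pair table CSV with SMIRKS rendered with [*:1] atom maps."""
    from molopt.mmp import r_group_ratio

    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(
            [
                "source_smiles",
                "target_smiles",
                "core",
                "transformation",
                "r_ratio_source",
                "r_ratio_target",
            ]
        )
        for p in pairs:
            writer.writerow(
                [
                    p.source.smiles_canonical,
                    p.target.smiles_canonical,
                    p.core,
                    p.transformation,
                    f"{r_group_ratio(p, 'source'):.4f}",
                    f"{r_group_ratio(p, 'target'):.4f}",
                ]
            )
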