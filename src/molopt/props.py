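"""Property oracles, property-change binning and condition tokens.

Three ADMET properties drive the optimization: logD (lipophilicity, unitless),
aqueous solubility (log10 uM) and human liver microsome intrinsic clearance,
CLint (log10 uL/min/mg). Solubility and CLint are binarized low/high at 50 uM
and 20 uL/min/mg respectively — 1.7 and 1.3 in log10 scale — and their desired
changes encoded as three categories (low->high, high->low, no_change), while
the desired logD change is encoded into half-open intervals of width 0.2
(plus two open-ended intervals beyond +-outer_bound). Each encoded change is a
single vocabulary token prepended to the source sequence.

The property oracle is an injectable interface (``predict(Molecule) ->
PropertyProfile``); :class:`SurrogateOracle` is a deterministic stand-in built
from RDKit descriptors, constructed so that over a congeneric-series corpus
solubility correlates negatively and CLint positively with logD.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Protocol, Sequence

from rdkit.Chem import Crippen, Descriptors, rdMolDescriptors

from molopt.chemio import Molecule, mol_from_smiles

LOW_TO_HIGH = "low->high"
HIGH_TO_LOW = "high->low"
NO_CHANGE = "no_change"
CATEGORIES = (LOW_TO_HIGH, HIGH_TO_LOW, NO_CHANGE)


@dataclass(frozen=True)
class PropertyProfile:
    """Predicted logD / solubility / CLint for one molecule."""

    logd: float
    sol: float
    clint: float


@dataclass(frozen=True)
class PropertyChange:
    """Desired (or realized) change between a source and target molecule."""

    d_logd: float
    sol_change: str
    clint_change: str

    def __post_init__(self):
        for c in (self.sol_change, self.clint_change):
            if c not in CATEGORIES:
                raise ValueError(f"unknown category {c!r}")


@dataclass(frozen=True)
class BinningConfig:
    """Encoding parameters for property changes.

    Bounded logD-change bins are half-open intervals (c-0.1, c+0.1] centered
    on multiples of ``bin_width``; beyond ``+-outer_bound`` two open-ended
    intervals apply. ``sol_threshold``/``clint_threshold`` are the low/high
    cutoffs in log10 scale.
    """

    bin_width: float = 0.2
    outer_bound: float = 3.1
    sol_threshold: float = 1.7
    clint_threshold: float = 1.3


@dataclass(frozen=True)
class SatisfactionTolerance:
    """Slack applied when judging generated molecules, reflecting property-
    model error: |logD - target| <= logd_tol; the low/high cutoffs are widened
    by sol_margin / clint_margin (a molecule counts as high solubility iff
    sol >= 1.7-0.6 and as low iff sol <= 1.7+0.6, likewise CLint with 0.35).
    """

    logd_tol: float = 0.4
    sol_margin: float = 0.6
    clint_margin: float = 0.35


class PropertyOracle(Protocol):
    def predict(self, mol: Molecule) -> PropertyProfile: ...


class SurrogateOracle:
    """Deterministic descriptor-based property calculator.

    logD is the Crippen logP estimate; solubility decreases with logD with a
    small polar-surface-area correction; CLint increases with logD with an
    aromatic-ring correction. Coefficients are fixed so that on congeneric
    series the solubility/logD correlation is strongly negative and the
    CLint/logD correlation strongly positive, and so that values straddle the
    1.7 / 1.3 thresholds over a logD range of roughly 1-5.
    """

    def predict(self, mol: Molecule) -> PropertyProfile:
        rdmol = mol_from_smiles(mol.smiles_canonical)
        logd = Crippen.MolLogP(rdmol)
        tpsa = Descriptors.TPSA(rdmol)
        n_arom = rdMolDescriptors.CalcNumAromaticRings(rdmol)
        sol = 3.4 - 0.9 * logd + 0.01 * tpsa
        clint = 0.4 + 0.5 * logd + 0.1 * n_arom
        return PropertyProfile(logd=logd, sol=sol, clint=clint)

    def predict_many(self, mols: Sequence[Molecule]) -> list[PropertyProfile]:
        return [self.predict(m) for m in mols]


def _bin_center(d: float, width: float) -> float:
    # unique multiple c of width with d in (c - width/2, c + width/2]
    k = math.ceil(round(d / width - 0.5, 9))
    return k * width


def _fmt(x: float) -> str:
    return f"{x + 0.0:.1f}"


def encode_logd_change(d: float, cfg: BinningConfig = BinningConfig()) -> str:
    """Encode a logD change into its interval token.

    Bounded bins render as ``LogD_change_(lo,hi]``; values beyond the outer
    bound get the open-ended tokens ``LogD_change_(-inf,-b]`` /
    ``LogD_change_(b,inf)``.
    """
    if not math.isfinite(d):
        raise ValueError(f"logD change must be finite, got {d!r}")
    half = cfg.bin_width / 2.0
    if d <= -cfg.outer_bound:
        return f"LogD_change_(-inf,{_fmt(-cfg.outer_bound)}]"
    if d > cfg.outer_bound:
        return f"LogD_change_({_fmt(cfg.outer_bound)},inf)"
    c = _bin_center(d, cfg.bin_width)
    return f"LogD_change_({_fmt(c - half)},{_fmt(c + half)}]"


def decode_logd_token(token: str) -> tuple[float, float]:
    """Interval bounds (lo, hi) of a logD-change token; inf for open ends."""
    inner = token.removeprefix("LogD_change_")
    lo_s, hi_s = inner.strip("(])").split(",")
    return float(lo_s), float(hi_s)


def logd_target_midpoint(token: str, cfg: BinningConfig = BinningConfig()) -> float:
    """Representative desired logD change for a token: the interval midpoint,
    or the bound extended by bin_width/2 for the open-ended intervals."""
    lo, hi = decode_logd_token(token)
    half = cfg.bin_width / 2.0
    if math.isinf(lo):
        return hi - half
    if math.isinf(hi):
        return lo + half
    return (lo + hi) / 2.0


def all_logd_tokens(cfg: BinningConfig = BinningConfig()) -> list[str]:
    """Every logD-change token under a binning config, in increasing order."""
    tokens = [f"LogD_change_(-inf,{_fmt(-cfg.outer_bound)}]"]
    n = round(cfg.outer_bound / cfg.bin_width - 0.5)
    for k in range(-n, n + 1):
        tokens.append(encode_logd_change(k * cfg.bin_width, cfg))
    tokens.append(f"LogD_change_({_fmt(cfg.outer_bound)},inf)")
    return tokens


def _label(value: float, threshold: float) -> str:
    # boundary convention: a value exactly at the threshold counts as high
    return "low" if value < threshold else "high"


def encode_category_change(
    source_value: float, target_value: float, threshold: float
) -> str:
    """Three-category change of a binarized property."""
    src, tgt = _label(source_value, threshold), _label(target_value, threshold)
    if src == tgt:
        return NO_CHANGE
    return LOW_TO_HIGH if src == "low" else HIGH_TO_LOW


def property_change(
    source: PropertyProfile,
    target: PropertyProfile,
    cfg: BinningConfig = BinningConfig(),
) -> PropertyChange:
    """Realized change between two property profiles."""
    return PropertyChange(
        d_logd=target.logd - source.logd,
        sol_change=encode_category_change(source.sol, target.sol, cfg.sol_threshold),
        clint_change=encode_category_change(
            source.clint, target.clint, cfg.clint_threshold
        ),
    )


def change_tokens(z: PropertyChange, cfg: BinningConfig = BinningConfig()) -> list[str]:
    """Render a property change as its three condition tokens, fixed order
    [logD, solubility, CLint]."""
    return [
        encode_logd_change(z.d_logd, cfg),
        f"Solubility_{z.sol_change}",
        f"CLint_{z.clint_change}",
    ]


def all_property_tokens(cfg: BinningConfig = BinningConfig()) -> list[str]:
    """The full condition-token alphabet (every single property change)."""
    tokens = all_logd_tokens(cfg)
    tokens += [f"Solubility_{c}" for c in CATEGORIES]
    tokens += [f"CLint_{c}" for c in CATEGORIES]
    return tokens


def satisfies_desired(
    generated: PropertyProfile,
    desired: PropertyChange,
    start: PropertyProfile,
    cfg: BinningConfig = BinningConfig(),
    tol: SatisfactionTolerance = SatisfactionTolerance(),
) -> bool:
    """Judge whether a generated molecule satisfies all three desired changes.

    The logD target is start.logd plus the desired interval's midpoint and must
    be matched within ``logd_tol``. Solubility/CLint must land in the desired
    category under thresholds widened by the margins; a no_change request
    requires the generated (widened) label to match the start's raw label.
    """
    token = encode_logd_change(desired.d_logd, cfg)
    target_logd = start.logd + logd_target_midpoint(token, cfg)
    if abs(generated.logd - target_logd) > tol.logd_tol:
        return False

    def category_ok(value, start_value, change, threshold, margin) -> bool:
        if change == NO_CHANGE:
            want = _label(start_value, threshold)
        else:
            want = "high" if change == LOW_TO_HIGH else "low"
        if want == "high":
            return value >= threshold - margin
        return value <= threshold + margin

    if not category_ok(
        generated.sol, start.sol, desired.sol_change, cfg.sol_threshold, tol.sol_margin
    ):
        return False
    return category_ok(
        generated.clint,
        start.clint,
        desired.clint_change,
        cfg.clint_threshold,
        tol.clint_margin,
    )
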