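"""Evaluation stack for generated molecules.

For each starting molecule, 10 unique valid generated molecules (distinct from
the start) are judged on three axes:

* satisfaction — do predicted logD / solubility / CLint meet the requested
  change within the evaluation tolerances;
* structural similarity — is the generated molecule an MMP of the start, with
  generated-side R-group heavy-atom ratio <= 0.33 (MMP_0.33) or <= 0.50
  (MMP_0.50), and is the transformation one seen in training ("in Train");
* validity — fraction of raw decodes parseable at all.

Model comparison uses the k-sample Anderson-Darling test (midrank version for
tied, discrete satisfied-counts), and a random-R-group MMP baseline provides a
non-learned reference: given the substitution site, 10 R-groups drawn from the
training pool are welded on and judged by the same satisfaction rule.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from molopt.chemio import Molecule, canonicalize
from molopt.mmp import Fragmentation, fragment_index, pair_from_indices, weld
from molopt.models.training import GenerationResult
from molopt.props import (
    BinningConfig,
    PropertyChange,
    PropertyOracle,
    SatisfactionTolerance,
    satisfies_desired,
)

logger = logging.getLogger(__name__)


# ---- per-start evaluation ---------------------------------------------------


@dataclass
class StartOutput:
    """Generation output for one starting molecule."""

    start: Molecule
    desired: PropertyChange
    result: GenerationResult


@dataclass
class StartEval:
    start: Molecule
    desired: PropertyChange
    generated: list[Molecule]
    satisfied_count: int
    mmp_033: int
    mmp_050: int
    mmp_033_satisfied: int
    mmp_050_satisfied: int
    valid: int
    exhausted: bool
    transformations_033: list[str] = field(default_factory=list)


@dataclass
class Aggregates:
    pct_desirable: float
    pct_mmp033: float
    pct_mmp050: float
    pct_mmp033_in_train: float
    pct_valid: float
    pct_mmp033_D: float
    pct_mmp050_D: float
    coverage: float  # share of starts that reached the full quota


@dataclass
class EvalReport:
    per_start: list[StartEval]
    aggregates: Aggregates

    @property
    def satisfied_counts(self) -> list[int]:
        """Satisfied-count distribution over starts with a full generated set
        (quota shortfalls are excluded; see ``aggregates.coverage``)."""
        return [s.satisfied_count for s in self.per_start if not s.exhausted]


def _pct(num: int, den: int) -> float:
    return 100.0 * num / den if den else 0.0


def evaluate(
    outputs: Sequence[StartOutput],
    oracle: PropertyOracle,
    cfg: BinningConfig = BinningConfig(),
    tol: SatisfactionTolerance = SatisfactionTolerance(),
    train_transformations: set[str] | None = None,
) -> EvalReport:
    """Score generated sets against their requests and the start structures.

    MMP membership compares each generated molecule with its start through the
    shared-core machinery; the R-group ratio is taken on the generated side.
    "in Train" membership compares canonical SMIRKS strings
    (direction-sensitive, since reverse pairs are separate training records).
    """
    per_start: list[StartEval] = []
    profile_cache: dict[str, object] = {}
    frag_cache: dict[str, dict] = {}

    def profile(mol: Molecule):
        key = mol.smiles_canonical
        if key not in profile_cache:
            profile_cache[key] = oracle.predict(mol)
        return profile_cache[key]

    def frags(mol: Molecule) -> dict:
        key = mol.smiles_canonical
        if key not in frag_cache:
            frag_cache[key] = fragment_index(mol)
        return frag_cache[key]

    n_generated = n_satisfied = n_033 = n_050 = 0
    n_033_train = n_033_d = n_050_d = 0
    n_raw = n_raw_valid = 0

    for out in outputs:
        start_profile = profile(out.start)
        start_index = frags(out.start)
        sat = m033 = m050 = m033_d = m050_d = 0
        t033: list[str] = []
        for mol in out.result.molecules:
            ok = satisfies_desired(profile(mol), out.desired, start_profile, cfg, tol)
            sat += ok
            pair = pair_from_indices(out.start, mol, start_index, frags(mol))
            if pair is not None:
                ratio = pair.r_target_heavy / mol.heavy_atom_count
                if ratio <= 0.50:
                    m050 += 1
                    m050_d += ok
                if ratio <= 0.33:
                    m033 += 1
                    m033_d += ok
                    t033.append(pair.transformation)
                    if train_transformations and pair.transformation in train_transformations:
                        n_033_train += 1
        per_start.append(
            StartEval(
                start=out.start,
                desired=out.desired,
                generated=list(out.result.molecules),
                satisfied_count=sat,
                mmp_033=m033,
                mmp_050=m050,
                mmp_033_satisfied=m033_d,
                mmp_050_satisfied=m050_d,
                valid=out.result.n_valid,
                exhausted=out.result.exhausted,
                transformations_033=t033,
            )
        )
        n_generated += len(out.result.molecules)
        n_satisfied += sat
        n_033 += m033
        n_050 += m050
        n_033_d += m033_d
        n_050_d += m050_d
        n_raw += out.result.n_sampled
        n_raw_valid += out.result.n_valid

    aggregates = Aggregates(
        pct_desirable=_pct(n_satisfied, n_generated),
        pct_mmp033=_pct(n_033, n_generated),
        pct_mmp050=_pct(n_050, n_generated),
        pct_mmp033_in_train=_pct(n_033_train, n_033),
        pct_valid=_pct(n_raw_valid, n_raw),
        pct_mmp033_D=_pct(n_033_d, n_satisfied),
        pct_mmp050_D=_pct(n_050_d, n_satisfied),
        coverage=(
            sum(1 for s in per_start if not s.exhausted) / len(per_start)
            if per_start
            else 0.0
        ),
    )
    return EvalReport(per_start=per_start, aggregates=aggregates)


def validity_pct(raw_decodes: Sequence[str]) -> float:
    """Percentage of raw decoded strings parseable as molecules."""
    if not raw_decodes:
        return 0.0
    ok = 0
    for smi in raw_decodes:
        try:
            canonicalize(smi)
            ok += 1
        except Exception:
            pass
    return 100.0 * ok / len(raw_decodes)


# ---- k-sample Anderson-Darling test -----------------------------------------


@dataclass
class ADResult:
    statistic: float  # standardized midrank statistic
    p_value: float
    significant: bool
    alpha: float


# Critical-value coefficients (t_m = b0 + b1/sqrt(m) + b2/m) at the standard
# significance levels; the p-value interpolates log(significance) quadratically
# in the statistic, which is an approximation outside the table range.
_AD_SIG = np.array([0.25, 0.1, 0.05, 0.025, 0.01, 0.005, 0.001])
_AD_B0 = np.array([0.675, 1.281, 1.645, 1.960, 2.326, 2.573, 3.085])
_AD_B1 = np.array([-0.245, 0.250, 0.678, 1.149, 1.822, 2.364, 3.615])
_AD_B2 = np.array([-0.105, -0.305, -0.362, -0.391, -0.396, -0.345, -0.154])


def ad_statistic_midrank(samples: Sequence[np.ndarray]) -> float:
    """Raw midrank k-sample Anderson-Darling statistic (ties allowed)."""
    samples = [np.sort(np.asarray(s, dtype=float)) for s in samples]
    pooled = np.sort(np.concatenate(samples))
    distinct = np.unique(pooled)
    n = np.array([len(s) for s in samples], dtype=float)
    N = float(len(pooled))
    left = pooled.searchsorted(distinct, side="left")
    lj = pooled.searchsorted(distinct, side="right") - left
    Bj = left + lj / 2.0
    denom = Bj * (N - Bj) - N * lj / 4.0
    a2 = 0.0
    for s, ni in zip(samples, n):
        right = s.searchsorted(distinct, side="right")
        fij = right - s.searchsorted(distinct, side="left")
        Mij = right - fij / 2.0
        num = lj / N * (N * Mij - Bj * ni) ** 2
        terms = np.divide(num, denom, out=np.zeros_like(num), where=denom > 0)
        a2 += terms.sum() / ni
    return a2 * (N - 1.0) / N


def ad_compare(counts_by_model: Sequence[Sequence[float]], alpha: float = 0.001) -> ADResult:
    """k-sample Anderson-Darling comparison of per-start satisfied counts.

    Returns the standardized midrank statistic and an interpolated p-value;
    ``significant`` applies the given level (default 0.1%). Degenerate input
    (fewer than two distinct pooled values) yields p = 1.
    """
    if len(counts_by_model) < 2:
        raise ValueError("need at least two samples")
    samples = [np.asarray(s, dtype=float) for s in counts_by_model]
    if any(len(s) == 0 for s in samples):
        raise ValueError("all samples must be non-empty")
    pooled = np.concatenate(samples)
    if np.unique(pooled).size < 2:
        return ADResult(statistic=-np.inf, p_value=1.0, significant=False, alpha=alpha)

    k = len(samples)
    n = np.array([len(s) for s in samples], dtype=float)
    N = float(len(pooled))
    a2 = ad_statistic_midrank(samples)

    H = (1.0 / n).sum()
    hs = (1.0 / np.arange(N - 1, 1, -1)).cumsum()
    h = hs[-1] + 1.0
    g = (hs / np.arange(2, N)).sum()
    a = (4 * g - 6) * (k - 1) + (10 - 6 * g) * H
    b = (2 * g - 4) * k**2 + 8 * h * k + (2 * g - 14 * h - 4) * H - 8 * h + 4 * g - 6
    c = (6 * h + 2 * g - 2) * k**2 + (4 * h - 4 * g + 6) * k + (2 * h - 6) * H + 4 * h
    d = (2 * h + 6) * k**2 - 4 * h * k
    sigma_sq = (a * N**3 + b * N**2 + c * N + d) / ((N - 1.0) * (N - 2.0) * (N - 3.0))
    m = k - 1.0
    stat = (a2 - m) / math.sqrt(sigma_sq)

    # p-value from the published critical-value table: quadratic interpolation
    # of log(significance) within the table, capped/floored outside it.
    critical = _AD_B0 + _AD_B1 / math.sqrt(m) + _AD_B2 / m
    if stat < critical[0]:
        p = float(_AD_SIG[0])
    elif stat > critical[-1]:
        p = float(_AD_SIG[-1])
    else:
        coeffs = np.polyfit(critical, np.log(_AD_SIG), 2)
        p = float(np.exp(np.polyval(coeffs, stat)))
    return ADResult(statistic=stat, p_value=p, significant=p <= alpha, alpha=alpha)


# ---- overlap analysis -------------------------------------------------------


def overlap_analysis(
    desirable_sets: dict[str, Sequence[set[str]]],
) -> dict[frozenset, int]:
    """Venn-region counts of desirable molecules across models.

    ``desirable_sets[model][i]`` is the set of canonical SMILES of desirable
    molecules generated by ``model`` for start ``i``; all models must cover the
    same starts, in order. Counts for every nonempty model subset S are summed
    over starts: a molecule is in region S iff exactly the models in S
    generated it for that start.
    """
    names = sorted(desirable_sets)
    lengths = {len(desirable_sets[m]) for m in names}
    if len(lengths) != 1:
        raise ValueError("all models must provide sets for the same starts")
    (n_starts,) = lengths
    regions: dict[frozenset, int] = {
        frozenset(sub): 0
        for r in range(1, len(names) + 1)
        for sub in itertools.combinations(names, r)
    }
    for i in range(n_starts):
        universe = set().union(*(desirable_sets[m][i] for m in names))
        for mol in universe:
            members = frozenset(m for m in names if mol in desirable_sets[m][i])
            regions[members] += 1
    return regions


# ---- random-R-group MMP baseline --------------------------------------------


def mmp_baseline(
    start: Molecule,
    site: Fragmentation,
    r_pool: Sequence[str],
    oracle: PropertyOracle,
    desired: PropertyChange,
    n: int = 10,
    seed: int = 0,
    cfg: BinningConfig = BinningConfig(),
    tol: SatisfactionTolerance = SatisfactionTolerance(),
) -> int:
    """Satisfied count of the random-substitution baseline.

    The substitution site is assumed known: ``n`` R-groups are drawn from the
    training pool (without replacement when the pool allows) and welded onto
    the start's core; the welded molecules are judged by the same satisfaction
    rule as model output. Weld failures are skipped and redrawn.
    """
    rng = np.random.default_rng(seed)
    pool = list(r_pool)
    start_profile = oracle.predict(start)
    chosen: list[Molecule] = []
    attempts = 0
    replace = len(pool) < n
    order = rng.permutation(len(pool))
    pos = 0
    while len(chosen) < n and attempts < 10 * n:
        attempts += 1
        if replace or pos >= len(order):
            r = pool[int(rng.integers(len(pool)))]
        else:
            r = pool[order[pos]]
            pos += 1
        try:
            chosen.append(weld(site.core, r))
        except Exception:
            logger.warning("baseline weld failed for %s + %s", site.core, r)
    return sum(
        satisfies_desired(oracle.predict(m), desired, start_profile, cfg, tol)
        for m in chosen
    )
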