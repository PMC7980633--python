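"""Desk-scale end-to-end benchmark: conditional vs. unconditional translation.

This module wires the full pipeline together on the synthetic corpus: generate
the congeneric-series fixture, encode conditional and unconditional records,
split, train a desk-preset Transformer in each mode, generate 10 unique valid
molecules per held-out starting molecule, score satisfaction of the requested
property changes, and compare the two satisfied-count distributions with the
k-sample Anderson-Darling test.

Problem sizes (training subset, epoch count, sampling budget) are fixed desk-
scale choices documented in the methods note; models run in float32, which
leaves the comparison unchanged.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from molopt.chemio import Vocabulary
from molopt.corpus import PairRecord, Split, SplitSpec, build_records, split
from molopt.evalsuite import ADResult, EvalReport, StartOutput, ad_compare, evaluate
from molopt.fixtures import FixtureCorpus, FixtureSpec, generate_corpus
from molopt.models import (
    TrainConfig,
    TrainedModel,
    TransformerConfig,
    TransformerModel,
    generate_unique_sets,
    train,
)
from molopt.models.autograd import default_dtype
from molopt.props import SurrogateOracle, all_property_tokens


@dataclass
class BenchmarkData:
    corpus: FixtureCorpus
    cond: Split
    uncond: Split
    vocab: Vocabulary


def build_benchmark_data(
    seed: int = 0,
    fixture_spec: FixtureSpec = FixtureSpec(),
    oracle=None,
) -> BenchmarkData:
    """Fixture corpus encoded in both modes, split identically.

    Conditional and unconditional records are built from the same pair list,
    so one seeded permutation yields aligned splits: record i refers to the
    same underlying pair in both modes.
    """
    oracle = oracle or SurrogateOracle()
    corpus = generate_corpus(fixture_spec)
    cond_records = build_records(corpus.pairs, oracle, conditional=True)
    uncond_records = build_records(corpus.pairs, oracle, conditional=False)
    spec = SplitSpec(sample_frac=1.0, seed=seed)
    cond = split(cond_records, spec)
    # unconditional records can collapse (several pairs share source SMILES as
    # x and target as y only if identical, which cannot happen); same length,
    # same permutation, aligned membership
    assert len(uncond_records) == len(cond_records)
    uncond = split(uncond_records, spec)
    vocab = Vocabulary.build(
        [r.x for r in cond.train] + [r.y for r in cond.train],
        all_property_tokens(),
    )
    return BenchmarkData(corpus=corpus, cond=cond, uncond=uncond, vocab=vocab)


def memorizable_records(
    n: int = 64,
    fixture_spec: FixtureSpec = FixtureSpec(n_scaffolds=2, r_library_size=8),
    oracle=None,
) -> list[PairRecord]:
    """A small training set on which the source->target mapping is a function.

    Conditional records whose source sequence occurs exactly once are kept
    (several pairs can share a source molecule and land in the same
    property-change bins, making their records inherently ambiguous; a model
    can then never reach full greedy accuracy). Used for overfitting checks.
    """
    from collections import Counter

    corpus = generate_corpus(fixture_spec)
    records = build_records(corpus.pairs, oracle or SurrogateOracle())
    counts = Counter(r.x.tokens for r in records)
    unique = [r for r in records if counts[r.x.tokens] == 1]
    if len(unique) < n:
        raise ValueError(f"only {len(unique)} unambiguous records available")
    return unique[:n]


@dataclass
class BenchmarkResult:
    report_cond: EvalReport
    report_uncond: EvalReport
    ad: ADResult
    mean_cond: float
    mean_uncond: float
    trained_cond: TrainedModel
    trained_uncond: TrainedModel


def train_benchmark_model(
    data: BenchmarkData,
    conditional: bool,
    epochs: int = 20,
    lr: float = 1e-3,
    batch: int = 128,
    seed: int = 0,
    train_size: int | None = 1920,
    valid_size: int = 200,
) -> TrainedModel:
    """Train a desk-preset Transformer in float32 on a seeded training subset."""
    sp = data.cond if conditional else data.uncond
    rng = np.random.default_rng(seed)
    if train_size is not None and train_size < len(sp.train):
        idx = rng.choice(len(sp.train), size=train_size, replace=False)
        train_records = [sp.train[i] for i in idx]
    else:
        train_records = list(sp.train)
    valid_records = sp.valid[:valid_size]
    with default_dtype(np.float32):
        model = TransformerModel(
            data.vocab, TransformerConfig.desk(), conditional=conditional, seed=seed
        )
        trained = train(
            model,
            train_records,
            valid_records,
            TrainConfig(lr=lr, batch=batch, epochs=epochs, seed=seed),
        )
    return trained


def evaluation_tasks(
    data: BenchmarkData, n_starts: int = 500
) -> tuple[list[PairRecord], list[PairRecord]]:
    """Held-out records used as evaluation starts, in both encodings.

    Drawn from the test split, topped up from the validation split (also held
    out from training) when the test split alone is smaller than ``n_starts``.
    """
    cond = (data.cond.test + data.cond.valid)[:n_starts]
    uncond = (data.uncond.test + data.uncond.valid)[:n_starts]
    return cond, uncond


def _generate_and_evaluate(
    trained: TrainedModel,
    records: list[PairRecord],
    train_records: list[PairRecord],
    quota: int,
    budget: int,
    seed: int,
    oracle,
    desired_from: list[PairRecord],
) -> EvalReport:
    starts = [r.pair.source for r in records]
    with default_dtype(np.float32):
        results = generate_unique_sets(
            trained.model,
            [r.x for r in records],
            starts,
            quota=quota,
            budget=budget,
            seed=seed,
            max_len=trained.max_len,
        )
    outputs = [
        StartOutput(start=s, desired=d.z, result=res)
        for s, d, res in zip(starts, desired_from, results)
    ]
    train_transformations = {r.pair.transformation for r in train_records}
    return evaluate(outputs, oracle, train_transformations=train_transformations)


def conditional_vs_unconditional(
    seed: int = 0,
    n_starts: int = 500,
    epochs: int = 20,
    quota: int = 10,
    budget: int = 40,
    train_size: int | None = 1920,
    alpha: float = 0.05,
    fixture_spec: FixtureSpec = FixtureSpec(),
) -> BenchmarkResult:
    """Run the conditional-vs-unconditional comparison end to end.

    Each held-out record provides the starting molecule; its realized property
    change is the request for both models (the unconditional model simply does
    not see it). Satisfied counts are compared with the k-sample
    Anderson-Darling test at the given significance level.
    """
    oracle = SurrogateOracle()
    data = build_benchmark_data(seed, fixture_spec, oracle)
    trained_cond = train_benchmark_model(
        data, conditional=True, epochs=epochs, seed=seed, train_size=train_size
    )
    trained_uncond = train_benchmark_model(
        data, conditional=False, epochs=epochs, seed=seed, train_size=train_size
    )
    cond_tasks, uncond_tasks = evaluation_tasks(data, n_starts)
    report_cond = _generate_and_evaluate(
        trained_cond, cond_tasks, data.cond.train, quota, budget, seed + 1,
        oracle, cond_tasks,
    )
    report_uncond = _generate_and_evaluate(
        trained_uncond, uncond_tasks, data.uncond.train, quota, budget, seed + 2,
        oracle, cond_tasks,
    )
    ad = ad_compare(
        [report_cond.satisfied_counts, report_uncond.satisfied_counts], alpha=alpha
    )
    return BenchmarkResult(
        report_cond=report_cond,
        report_uncond=report_uncond,
        ad=ad,
        mean_cond=float(np.mean(report_cond.satisfied_counts)),
        mean_uncond=float(np.mean(report_uncond.satisfied_counts)),
        trained_cond=trained_cond,
        trained_uncond=trained_uncond,
    )
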