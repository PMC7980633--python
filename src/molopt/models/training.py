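"""Teacher-forced training, checkpoint selection by validation accuracy, and
greedy / multinomial decoding.

The loss is the summed negative log likelihood of the target tokens (end token
included) under teacher forcing. A checkpoint is taken every epoch and the one
with the highest greedy-decoding validation accuracy — the fraction of
validation records whose single greedy decode canonicalizes to the target — is
returned. Generation samples token-by-token from the softmax until the end
token, and :func:`generate_unique_set` collects unique valid molecules distinct
from the starting molecule up to a quota, within a sampling budget.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from molopt.chemio import Molecule, TokenSequence, Vocabulary, canonicalize
from molopt.corpus import PairRecord
from molopt.models.autograd import Adam, Tensor, cross_entropy_sum, no_grad

logger = logging.getLogger(__name__)


class TrainingError(RuntimeError):
    """Raised when training diverges (non-finite loss)."""

    def __init__(self, epoch: int):
        self.epoch = epoch
        super().__init__(f"non-finite loss at epoch {epoch}")


class EncodingError(KeyError):
    """A token required strict encoding but is absent from the vocabulary."""


@dataclass(frozen=True)
class TrainConfig:
    """Optimization settings; the optimizer is Adam throughout."""

    lr: float = 1e-4
    batch: int = 128
    epochs: int = 10
    seed: int = 0

    def __post_init__(self):
        if self.lr <= 0:
            raise ValueError("learning rate must be positive")


@dataclass
class EpochLog:
    epoch: int
    train_nll_per_token: float
    valid_accuracy: float


@dataclass
class TrainedModel:
    """A model plus the bookkeeping needed to decode with it."""

    model: object  # Seq2SeqModel | TransformerModel
    vocab: Vocabulary
    arch: str
    conditional: bool
    max_len: int
    log: list[EpochLog] = field(default_factory=list)


# ---- batching ---------------------------------------------------------------


def encode_source_batch(
    vocab: Vocabulary, xs: Sequence[TokenSequence], strict: bool = False
) -> tuple[np.ndarray, np.ndarray]:
    """Right-padded id matrix (B, T) and float mask (B, T) for source sequences.

    Out-of-vocabulary tokens map to the unknown id and are logged; with
    ``strict`` they raise :class:`EncodingError` instead.
    """
    if strict:
        for x in xs:
            for t in x.tokens:
                if t not in vocab:
                    raise EncodingError(t)
    ids = [vocab.encode(x.tokens) for x in xs]
    for x, row in zip(xs, ids):
        if vocab.unk_id in row:
            logger.warning("unknown token(s) in %s", " ".join(x.tokens))
    T = max(len(r) for r in ids)
    out = np.full((len(ids), T), vocab.pad_id, dtype=np.int64)
    mask = np.zeros((len(ids), T))
    for i, row in enumerate(ids):
        out[i, : len(row)] = row
        mask[i, : len(row)] = 1.0
    return out, mask


def encode_target_batch(
    vocab: Vocabulary, ys: Sequence[TokenSequence]
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """(tgt_in, tgt_out, mask): start-prefixed inputs and end-suffixed outputs."""
    ids = [vocab.encode(y.tokens) for y in ys]
    T = max(len(r) for r in ids) + 1
    tgt_in = np.full((len(ids), T), vocab.pad_id, dtype=np.int64)
    tgt_out = np.full((len(ids), T), vocab.pad_id, dtype=np.int64)
    mask = np.zeros((len(ids), T))
    for i, row in enumerate(ids):
        tgt_in[i, 0] = vocab.start_id
        tgt_in[i, 1 : len(row) + 1] = row
        tgt_out[i, : len(row)] = row
        tgt_out[i, len(row)] = vocab.end_id
        mask[i, : len(row) + 1] = 1.0
    return tgt_in, tgt_out, mask


# ---- loss -------------------------------------------------------------------


def _nll_tensor(model, records: Sequence[PairRecord], train=False, rng=None) -> tuple[Tensor, float]:
    vocab = model.vocab
    src, src_mask = encode_source_batch(vocab, [r.x for r in records], strict=True)
    tgt_in, tgt_out, tgt_mask = encode_target_batch(vocab, [r.y for r in records])
    logits = model.forward_logits(src, src_mask, tgt_in, train=train, rng=rng)
    V = logits.shape[-1]
    flat = logits.reshape(-1, V)
    loss = cross_entropy_sum(flat, tgt_out.reshape(-1), tgt_mask.reshape(-1))
    ls = getattr(getattr(model, "cfg", None), "label_smoothing", 0.0)
    if ls > 0.0:
        from molopt.models.autograd import log_softmax

        logp = log_softmax(flat, axis=-1)
        uniform = -(logp.sum(axis=-1) * Tensor(tgt_mask.reshape(-1))).sum() / V
        loss = loss * (1.0 - ls) + uniform * ls
    return loss, float(tgt_mask.sum())


def nll(model, records: Sequence[PairRecord]) -> float:
    """Summed teacher-forced negative log likelihood of a batch of records."""
    loss, _ = _nll_tensor(model, records, train=False)
    return float(loss.data)


# ---- decoding ---------------------------------------------------------------


def sample_sequences(
    model,
    xs: Sequence[TokenSequence],
    max_len: int,
    rng: np.random.Generator | None = None,
    greedy: bool = False,
) -> list[list[str]]:
    """Decode one token sequence per source (batched).

    Greedy mode takes the argmax at every step; otherwise tokens are drawn from
    the per-step softmax (multinomial sampling). Sequences stop at the end
    token or after ``max_len`` tokens (overruns are returned unterminated; the
    caller decides whether to count them).
    """
    vocab = model.vocab
    src, src_mask = encode_source_batch(vocab, xs)
    B = src.shape[0]
    with no_grad():
        state = model.init_decode(src, src_mask)
        prev = np.full(B, vocab.start_id, dtype=np.int64)
        alive = np.ones(B, dtype=bool)
        outputs: list[list[int]] = [[] for _ in range(B)]
        for _ in range(max_len):
            logits = model.step(state, prev)
            if greedy:
                nxt = logits.argmax(axis=-1)
            else:
                shifted = logits - logits.max(axis=-1, keepdims=True)
                probs = np.exp(shifted)
                probs /= probs.sum(axis=-1, keepdims=True)
                cum = probs.cumsum(axis=-1)
                u = rng.random((B, 1))
                nxt = (u < cum).argmax(axis=-1)
            for i in range(B):
                if alive[i]:
                    if nxt[i] == vocab.end_id:
                        alive[i] = False
                    else:
                        outputs[i].append(int(nxt[i]))
            if not alive.any():
                break
            # frozen rows keep feeding their last token; their output is fixed
            prev = nxt
        rev = vocab.id_to_token
        return [[rev[i] for i in out] for out in outputs]


def greedy_decode(trained: TrainedModel, xs: Sequence[TokenSequence]) -> list[str]:
    """Deterministic argmax decode of each source into a SMILES string."""
    tokens = sample_sequences(trained.model, xs, trained.max_len, greedy=True)
    return ["".join(t) for t in tokens]


def record_target_smiles(rec: PairRecord) -> str:
    """Canonical target SMILES of a record (from provenance when present,
    otherwise by joining the target tokens)."""
    if rec.pair is not None:
        return rec.pair.target.smiles_canonical
    return "".join(rec.y.tokens)


def greedy_accuracy(trained: TrainedModel, records: Sequence[PairRecord], batch: int = 256) -> float:
    """Fraction of records whose greedy decode canonicalizes to the target."""
    if not records:
        return 0.0
    hits = 0
    for lo in range(0, len(records), batch):
        chunk = records[lo : lo + batch]
        decoded = greedy_decode(trained, [r.x for r in chunk])
        for rec, smi in zip(chunk, decoded):
            target = record_target_smiles(rec)
            try:
                hits += canonicalize(smi).smiles_canonical == target
            except Exception:
                pass  # invalid decode counts as a miss
    return hits / len(records)


def sample_multinomial(
    model,
    x: TokenSequence,
    n: int,
    seed: int,
    max_len: int,
) -> list[list[str]]:
    """Draw ``n`` token sequences for one source by multinomial sampling."""
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    return sample_sequences(model, [x] * n, max_len, rng=rng)


@dataclass
class GenerationResult:
    molecules: list[Molecule]
    exhausted: bool
    n_sampled: int
    n_valid: int
    raw_smiles: list[str] = field(default_factory=list)


def generate_unique_set(
    model,
    x: TokenSequence,
    start: Molecule,
    quota: int = 10,
    budget: int = 100,
    seed: int = 0,
    max_len: int = 120,
) -> GenerationResult:
    """Sample until ``quota`` unique valid molecules distinct from the start
    are collected, or the sampling budget is spent (then ``exhausted``)."""
    if quota < 1 or budget < quota:
        raise ValueError("need quota >= 1 and budget >= quota")
    rng = np.random.default_rng(seed)
    unique: dict[str, Molecule] = {}
    raw: list[str] = []
    n_sampled = n_valid = 0
    while len(unique) < quota and n_sampled < budget:
        chunk = min(2 * quota, budget - n_sampled)
        seqs = sample_sequences(model, [x] * chunk, max_len, rng=rng)
        n_sampled += chunk
        for tokens in seqs:
            smi = "".join(tokens)
            raw.append(smi)
            try:
                mol = canonicalize(smi)
            except Exception:
                continue
            n_valid += 1
            if mol.smiles_canonical == start.smiles_canonical:
                continue
            if mol.smiles_canonical not in unique and len(unique) < quota:
                unique[mol.smiles_canonical] = mol
    return GenerationResult(
        molecules=list(unique.values()),
        exhausted=len(unique) < quota,
        n_sampled=n_sampled,
        n_valid=n_valid,
        raw_smiles=raw,
    )


def save_checkpoint(trained: TrainedModel, path) -> None:
    """Persist parameters plus the config/vocabulary needed to rebuild."""
    import json

    from dataclasses import asdict

    model = trained.model
    meta = {
        "arch": trained.arch,
        "conditional": trained.conditional,
        "max_len": trained.max_len,
        "cfg": asdict(model.cfg),
        "vocab": model.vocab.token_to_id,
        "log": [asdict(e) for e in trained.log],
    }
    arrays = {f"p{i}": a for i, a in enumerate(model.state_arrays())}
    np.savez(path, meta=json.dumps(meta), **arrays)


def load_checkpoint(path) -> TrainedModel:
    import json

    from molopt.models.seq2seq import Seq2SeqConfig, Seq2SeqModel
    from molopt.models.transformer import TransformerConfig, TransformerModel

    data = np.load(path, allow_pickle=False)
    meta = json.loads(str(data["meta"]))
    vocab = Vocabulary(meta["vocab"])
    if meta["arch"] == "seq2seq":
        model = Seq2SeqModel(vocab, Seq2SeqConfig(**meta["cfg"]), meta["conditional"])
    else:
        model = TransformerModel(
            vocab, TransformerConfig(**meta["cfg"]), meta["conditional"]
        )
    arrays = [data[f"p{i}"] for i in range(len(data.files) - 1)]
    model.load_state_arrays(arrays)
    return TrainedModel(
        model=model,
        vocab=vocab,
        arch=meta["arch"],
        conditional=meta["conditional"],
        max_len=meta["max_len"],
        log=[EpochLog(**e) for e in meta["log"]],
    )


def generate_unique_sets(
    model,
    xs: Sequence[TokenSequence],
    starts: Sequence[Molecule],
    quota: int = 10,
    budget: int = 100,
    seed: int = 0,
    max_len: int = 120,
    chunk: int = 20,
    max_batch: int = 240,
) -> list[GenerationResult]:
    """Batched :func:`generate_unique_set` over many starting molecules.

    Sampling for several starts is packed into shared decode batches (up to
    ``max_batch`` sequences), drawing ``chunk`` samples per start per round
    until each start has its quota or its budget is spent. Deterministic for a
    fixed seed and argument set.
    """
    if len(xs) != len(starts):
        raise ValueError("xs and starts must align")
    rng = np.random.default_rng(seed)
    n_tasks = len(xs)
    unique: list[dict[str, Molecule]] = [{} for _ in range(n_tasks)]
    raw: list[list[str]] = [[] for _ in range(n_tasks)]
    sampled = [0] * n_tasks
    valid = [0] * n_tasks

    pending = list(range(n_tasks))
    while pending:
        batch_tasks: list[int] = []
        for i in pending:
            k = min(chunk, budget - sampled[i])
            if len(batch_tasks) + k > max_batch and batch_tasks:
                break
            batch_tasks.extend([i] * k)
        seqs = sample_sequences(
            model, [xs[i] for i in batch_tasks], max_len, rng=rng
        )
        for i, tokens in zip(batch_tasks, seqs):
            sampled[i] += 1
            smi = "".join(tokens)
            raw[i].append(smi)
            try:
                mol = canonicalize(smi)
            except Exception:
                continue
            valid[i] += 1
            if mol.smiles_canonical == starts[i].smiles_canonical:
                continue
            if mol.smiles_canonical not in unique[i] and len(unique[i]) < quota:
                unique[i][mol.smiles_canonical] = mol
        pending = [
            i for i in pending if len(unique[i]) < quota and sampled[i] < budget
        ]
    return [
        GenerationResult(
            molecules=list(unique[i].values()),
            exhausted=len(unique[i]) < quota,
            n_sampled=sampled[i],
            n_valid=valid[i],
            raw_smiles=raw[i],
        )
        for i in range(n_tasks)
    ]


# ---- training loop ----------------------------------------------------------


def train(
    model,
    train_records: Sequence[PairRecord],
    valid_records: Sequence[PairRecord],
    cfg: TrainConfig = TrainConfig(),
    max_len: int | None = None,
    stop_accuracy: float | None = None,
) -> TrainedModel:
    """Teacher-forced NLL training with per-epoch checkpoint selection.

    A checkpoint is recorded after every epoch; the returned model carries the
    parameters of the checkpoint with the highest greedy validation accuracy
    (ties keep the earliest). ``max_len`` defaults to 1.5x the longest training
    target. ``stop_accuracy`` stops early once the validation accuracy reaches
    the given level. Non-finite losses raise :class:`TrainingError`.
    """
    if max_len is None:
        longest = max((len(r.y) for r in train_records), default=0)
        max_len = int(np.ceil(1.5 * longest)) + 1
    trained = TrainedModel(
        model=model,
        vocab=model.vocab,
        arch=model.arch,
        conditional=model.conditional,
        max_len=max_len,
    )
    if cfg.epochs == 0:
        return trained

    rng = np.random.default_rng(cfg.seed)
    opt = Adam(model.parameters(), lr=cfg.lr)
    best_acc = -1.0
    best_state = None
    for epoch in range(cfg.epochs):
        order = rng.permutation(len(train_records))
        total_loss = 0.0
        total_tokens = 0.0
        for lo in range(0, len(order), cfg.batch):
            batch = [train_records[i] for i in order[lo : lo + cfg.batch]]
            loss, n_tok = _nll_tensor(model, batch, train=True, rng=rng)
            if not np.isfinite(loss.data):
                raise TrainingError(epoch)
            opt.zero_grad()
            (loss / n_tok).backward()
            opt.step()
            total_loss += float(loss.data)
            total_tokens += n_tok
        acc = greedy_accuracy(trained, valid_records)
        trained.log.append(
            EpochLog(
                epoch=epoch,
                train_nll_per_token=total_loss / max(total_tokens, 1.0),
                valid_accuracy=acc,
            )
        )
        if acc > best_acc:
            best_acc = acc
            best_state = model.state_arrays()
        if stop_accuracy is not None and acc >= stop_accuracy:
            break
    if best_state is not None:
        model.load_state_arrays(best_state)
    return trained
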