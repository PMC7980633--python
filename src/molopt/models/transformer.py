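"""Transformer encoder-decoder for molecular translation.

The standard architecture: sinusoidal positional encodings added to scaled
token embeddings; N identical encoder layers (multi-head self-attention +
position-wise feed-forward, residual connections followed by layer
normalization); N decoder layers with causally masked self-attention and
encoder-decoder attention over the top encoder output. Source padding is
masked out of every attention over the source, and future positions are masked
in the decoder so the prediction at position t depends only on tokens 1..t.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from molopt.chemio import Vocabulary
from molopt.models.autograd import (
    Module,
    Parameter,
    Tensor,
    dropout,
    layer_norm,
    softmax,
    take_rows,
)

NEG_INF = -1e9


@dataclass(frozen=True)
class TransformerConfig:
    """Architecture hyperparameters (defaults: full-scale training setup)."""

    d_model: int = 256
    n_layers: int = 6
    n_heads: int = 8
    ff_dim: int = 2048
    dropout: float = 0.1
    label_smoothing: float = 0.0

    def __post_init__(self):
        if self.d_model % self.n_heads:
            raise ValueError("d_model must be divisible by n_heads")

    @classmethod
    def desk(cls) -> "TransformerConfig":
        """CPU-sized preset used throughout the test-scale experiments."""
        return cls(d_model=64, n_layers=2, n_heads=4, ff_dim=128, dropout=0.0)


def sinusoidal_positions(max_len: int, d_model: int) -> np.ndarray:
    pos = np.arange(max_len)[:, None]
    i = np.arange(d_model)[None, :]
    angle = pos / np.power(10000.0, (2 * (i // 2)) / d_model)
    pe = np.where(i % 2 == 0, np.sin(angle), np.cos(angle))
    return pe


def _glorot(rng: np.random.Generator, fan_in: int, fan_out: int) -> np.ndarray:
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=(fan_in, fan_out))


class MultiHeadAttention(Module):
    def __init__(self, rng: np.random.Generator, d_model: int, n_heads: int):
        self.h = n_heads
        self.dh = d_model // n_heads
        self.w_q = Parameter(_glorot(rng, d_model, d_model))
        self.w_k = Parameter(_glorot(rng, d_model, d_model))
        self.w_v = Parameter(_glorot(rng, d_model, d_model))
        self.w_o = Parameter(_glorot(rng, d_model, d_model))

    def __call__(self, q_in: Tensor, kv_in: Tensor, bias: np.ndarray) -> Tensor:
        """bias is an additive mask broadcastable to (B, heads, Tq, Tk)."""
        B, Tq, d = q_in.shape
        Tk = kv_in.shape[1]

        def heads(x: Tensor, T: int) -> Tensor:
            return x.reshape(B, T, self.h, self.dh).transpose(0, 2, 1, 3)

        q = heads(q_in @ self.w_q, Tq)
        k = heads(kv_in @ self.w_k, Tk)
        v = heads(kv_in @ self.w_v, Tk)
        scores = q @ k.transpose(0, 1, 3, 2) * (1.0 / np.sqrt(self.dh))
        weights = softmax(scores + Tensor(bias), axis=-1)
        out = (weights @ v).transpose(0, 2, 1, 3).reshape(B, Tq, d)
        return out @ self.w_o


class FeedForward(Module):
    def __init__(self, rng: np.random.Generator, d_model: int, ff_dim: int):
        self.w1 = Parameter(_glorot(rng, d_model, ff_dim))
        self.b1 = Parameter(np.zeros(ff_dim))
        self.w2 = Parameter(_glorot(rng, ff_dim, d_model))
        self.b2 = Parameter(np.zeros(d_model))

    def __call__(self, x: Tensor) -> Tensor:
        return (x @ self.w1 + self.b1).relu() @ self.w2 + self.b2


class _SubLayerNorm(Module):
    def __init__(self, d_model: int):
        self.gamma = Parameter(np.ones(d_model))
        self.beta = Parameter(np.zeros(d_model))

    def __call__(self, x: Tensor) -> Tensor:
        return layer_norm(x, self.gamma, self.beta)


class EncoderLayer(Module):
    def __init__(self, rng, cfg: TransformerConfig):
        self.attn = MultiHeadAttention(rng, cfg.d_model, cfg.n_heads)
        self.ff = FeedForward(rng, cfg.d_model, cfg.ff_dim)
        self.ln1 = _SubLayerNorm(cfg.d_model)
        self.ln2 = _SubLayerNorm(cfg.d_model)
        self.p = cfg.dropout

    def __call__(self, x, bias, train, rng):
        x = self.ln1(x + dropout(self.attn(x, x, bias), self.p, rng, train))
        return self.ln2(x + dropout(self.ff(x), self.p, rng, train))


class DecoderLayer(Module):
    def __init__(self, rng, cfg: TransformerConfig):
        self.self_attn = MultiHeadAttention(rng, cfg.d_model, cfg.n_heads)
        self.cross_attn = MultiHeadAttention(rng, cfg.d_model, cfg.n_heads)
        self.ff = FeedForward(rng, cfg.d_model, cfg.ff_dim)
        self.ln1 = _SubLayerNorm(cfg.d_model)
        self.ln2 = _SubLayerNorm(cfg.d_model)
        self.ln3 = _SubLayerNorm(cfg.d_model)
        self.p = cfg.dropout

    def __call__(self, x, memory, causal_bias, src_bias, train, rng):
        x = self.ln1(x + dropout(self.self_attn(x, x, causal_bias), self.p, rng, train))
        x = self.ln2(
            x + dropout(self.cross_attn(x, memory, src_bias), self.p, rng, train)
        )
        return self.ln3(x + dropout(self.ff(x), self.p, rng, train))


class TransformerModel(Module):
    """Conditional (or unconditional) molecular translation Transformer."""

    arch = "transformer"
    MAX_POSITIONS = 512

    def __init__(
        self,
        vocab: Vocabulary,
        cfg: TransformerConfig = TransformerConfig(),
        conditional: bool = True,
        seed: int = 0,
    ):
        rng = np.random.default_rng(seed)
        self.vocab = vocab
        self.cfg = cfg
        self.conditional = conditional
        V, d = len(vocab), cfg.d_model
        self.emb = Parameter(rng.normal(0, d**-0.5, size=(V, d)))
        self.pe = sinusoidal_positions(self.MAX_POSITIONS, d)
        self.enc_layers = [EncoderLayer(rng, cfg) for _ in range(cfg.n_layers)]
        self.dec_layers = [DecoderLayer(rng, cfg) for _ in range(cfg.n_layers)]
        self.w_out = Parameter(_glorot(rng, d, V))
        self.b_out = Parameter(np.zeros(V))

    def _embed(self, ids: np.ndarray, train, rng) -> Tensor:
        T = ids.shape[1]
        x = take_rows(self.emb, ids) * np.sqrt(self.cfg.d_model) + Tensor(
            self.pe[None, :T, :]
        )
        return dropout(x, self.cfg.dropout, rng, train)

    def encode(self, src_ids, src_mask, train=False, rng=None) -> Tensor:
        bias = ((1.0 - src_mask) * NEG_INF)[:, None, None, :]  # (B,1,1,Tk)
        x = self._embed(src_ids, train, rng)
        for layer in self.enc_layers:
            x = layer(x, bias, train, rng)
        return x

    def _decode(self, memory, src_mask, tgt_in, train=False, rng=None) -> Tensor:
        T = tgt_in.shape[1]
        causal = np.triu(np.full((T, T), NEG_INF), k=1)[None, None, :, :]
        src_bias = ((1.0 - src_mask) * NEG_INF)[:, None, None, :]
        x = self._embed(tgt_in, train, rng)
        for layer in self.dec_layers:
            x = layer(x, memory, causal, src_bias, train, rng)
        return x @ self.w_out + self.b_out

    def forward_logits(
        self,
        src_ids: np.ndarray,
        src_mask: np.ndarray,
        tgt_in: np.ndarray,
        train: bool = False,
        rng: np.random.Generator | None = None,
    ) -> Tensor:
        """Teacher-forced logits (B, T_out, V)."""
        memory = self.encode(src_ids, src_mask, train, rng)
        return self._decode(memory, src_mask, tgt_in, train, rng)

    # ---- incremental decoding (raw ndarray path with key/value caches) ------

    def init_decode(self, src_ids: np.ndarray, src_mask: np.ndarray) -> dict:
        """Encode once and precompute cross-attention keys/values per layer.

        Decoding then runs token-by-token on plain ndarrays, appending each
        step's self-attention keys/values to a cache, which keeps the cost per
        generated token linear in the prefix length.
        """
        memory = self.encode(src_ids, src_mask, train=False).data
        B = memory.shape[0]
        h, dh = self.cfg.n_heads, self.cfg.d_model // self.cfg.n_heads

        def heads(x):
            return x.reshape(B, -1, h, dh).transpose(0, 2, 1, 3)

        layers = []
        for layer in self.dec_layers:
            layers.append(
                {
                    "cross_k": heads(memory @ layer.cross_attn.w_k.data),
                    "cross_v": heads(memory @ layer.cross_attn.w_v.data),
                    "self_k": np.zeros((B, h, 0, dh), dtype=memory.dtype),
                    "self_v": np.zeros((B, h, 0, dh), dtype=memory.dtype),
                }
            )
        return {
            "layers": layers,
            "src_bias": ((1.0 - src_mask) * NEG_INF)[:, None, None, :],
            "t": 0,
        }

    @staticmethod
    def _ln_np(x, ln: _SubLayerNorm, eps=1e-5):
        mu = x.mean(axis=-1, keepdims=True)
        sd = np.sqrt(x.var(axis=-1, keepdims=True) + eps)
        return (x - mu) / sd * ln.gamma.data + ln.beta.data

    @staticmethod
    def _attend_np(q, K, V, bias=None):
        # q (B,h,dh); K,V (B,h,T,dh); bias broadcastable to (B,h,T)
        scores = np.einsum("bhd,bhtd->bht", q, K) / np.sqrt(q.shape[-1])
        if bias is not None:
            scores = scores + bias
        scores -= scores.max(axis=-1, keepdims=True)
        w = np.exp(scores)
        w /= w.sum(axis=-1, keepdims=True)
        return np.einsum("bht,bhtd->bhd", w, V)

    def step(self, state: dict, prev_ids: np.ndarray) -> np.ndarray:
        """One decoding step; returns next-token logits (B, V)."""
        B = prev_ids.shape[0]
        d, h = self.cfg.d_model, self.cfg.n_heads
        dh = d // h
        x = self.emb.data[prev_ids] * np.sqrt(d) + self.pe[state["t"], :]
        for layer, cache in zip(self.dec_layers, state["layers"]):
            sa = layer.self_attn
            q = (x @ sa.w_q.data).reshape(B, h, dh)
            k = (x @ sa.w_k.data).reshape(B, h, 1, dh)
            v = (x @ sa.w_v.data).reshape(B, h, 1, dh)
            cache["self_k"] = np.concatenate([cache["self_k"], k], axis=2)
            cache["self_v"] = np.concatenate([cache["self_v"], v], axis=2)
            out = self._attend_np(q, cache["self_k"], cache["self_v"])
            x = self._ln_np(x + out.reshape(B, d) @ sa.w_o.data, layer.ln1)

            ca = layer.cross_attn
            q = (x @ ca.w_q.data).reshape(B, h, dh)
            out = self._attend_np(
                q, cache["cross_k"], cache["cross_v"], bias=state["src_bias"][:, 0]
            )
            x = self._ln_np(x + out.reshape(B, d) @ ca.w_o.data, layer.ln2)

            ff = layer.ff
            y = np.maximum(x @ ff.w1.data + ff.b1.data, 0.0) @ ff.w2.data + ff.b2.data
            x = self._ln_np(x + y, layer.ln3)
        state["t"] += 1
        return x @ self.w_out.data + self.b_out.data
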