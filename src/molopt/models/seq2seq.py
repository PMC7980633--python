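"""LSTM Seq2Seq with scaled-dot-product attention.

The encoder embeds the source tokens and runs them through stacked
bidirectional LSTM layers; at every time step the outputs of the two
directions are summed, both as the input to the next layer and as the
attention memory. The final states of the two directions are likewise summed,
layer by layer, and initialize the (unidirectional) decoder stack. At each
decoding step the attention weights are the softmax of the scaled dot product
between the decoder's top hidden state and the encoder outputs; the resulting
context vector is concatenated with the decoder state, passed through a tanh
projection and a vocabulary-sized linear layer.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from molopt.chemio import Vocabulary
from molopt.models.autograd import (
    Module,
    Parameter,
    Tensor,
    concat,
    dropout,
    softmax,
    take_rows,
)

NEG_INF = -1e9


@dataclass(frozen=True)
class Seq2SeqConfig:
    """Architecture hyperparameters (defaults: full-scale training setup)."""

    emb_dim: int = 256
    layers: int = 5
    hidden: int = 512
    dropout: float = 0.3

    @classmethod
    def desk(cls) -> "Seq2SeqConfig":
        """CPU-sized preset used throughout the test-scale experiments."""
        return cls(emb_dim=64, layers=2, hidden=128, dropout=0.0)


def _glorot(rng: np.random.Generator, fan_in: int, fan_out: int) -> np.ndarray:
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=(fan_in, fan_out))


class LSTMCell(Module):
    """One LSTM layer applied step by step; gate order [i, f, g, o]."""

    def __init__(self, rng: np.random.Generator, input_dim: int, hidden: int):
        self.hidden = hidden
        self.w_x = Parameter(_glorot(rng, input_dim, 4 * hidden))
        self.w_h = Parameter(_glorot(rng, hidden, 4 * hidden))
        b = np.zeros(4 * hidden)
        b[hidden : 2 * hidden] = 1.0  # forget-gate bias
        self.b = Parameter(b)

    def step(self, x: Tensor, h: Tensor, c: Tensor, mask: np.ndarray | None):
        """mask (B, 1): 1 keeps the update, 0 freezes the state (padding)."""
        H = self.hidden
        gates = x @ self.w_x + h @ self.w_h + self.b
        i = gates[:, 0:H].sigmoid()
        f = gates[:, H : 2 * H].sigmoid()
        g = gates[:, 2 * H : 3 * H].tanh()
        o = gates[:, 3 * H : 4 * H].sigmoid()
        c_new = f * c + i * g
        h_new = o * c_new.tanh()
        if mask is not None:
            m = Tensor(mask)
            c_new = c_new * m + c * (1.0 - m)
            h_new = h_new * m + h * (1.0 - m)
        return h_new, c_new


class Seq2SeqModel(Module):
    """Conditional (or unconditional) molecular translation Seq2Seq."""

    arch = "seq2seq"

    def __init__(
        self,
        vocab: Vocabulary,
        cfg: Seq2SeqConfig = Seq2SeqConfig(),
        conditional: bool = True,
        seed: int = 0,
    ):
        rng = np.random.default_rng(seed)
        self.vocab = vocab
        self.cfg = cfg
        self.conditional = conditional
        V, E, H = len(vocab), cfg.emb_dim, cfg.hidden
        self.emb_src = Parameter(rng.normal(0, 0.1, size=(V, E)))
        self.emb_tgt = Parameter(rng.normal(0, 0.1, size=(V, E)))
        self.enc_fwd = [
            LSTMCell(rng, E if l == 0 else H, H) for l in range(cfg.layers)
        ]
        self.enc_bwd = [
            LSTMCell(rng, E if l == 0 else H, H) for l in range(cfg.layers)
        ]
        self.dec = [LSTMCell(rng, E if l == 0 else H, H) for l in range(cfg.layers)]
        self.w_comb = Parameter(_glorot(rng, 2 * H, H))
        self.b_comb = Parameter(np.zeros(H))
        self.w_out = Parameter(_glorot(rng, H, V))
        self.b_out = Parameter(np.zeros(V))

    # ---- encoder ------------------------------------------------------------

    def _run_direction(self, cell: LSTMCell, steps, mask_cols, batch: int):
        H = cell.hidden
        h = Tensor(np.zeros((batch, H)))
        c = Tensor(np.zeros((batch, H)))
        outs = []
        for x_t, m_t in zip(steps, mask_cols):
            h, c = cell.step(x_t, h, c, m_t)
            outs.append(h)
        return outs, h, c

    def encode(self, src_ids: np.ndarray, src_mask: np.ndarray, train: bool = False,
               rng: np.random.Generator | None = None):
        """Returns (enc_outputs (B,T,H), init_states [(h,c)] per decoder layer)."""
        B, T = src_ids.shape
        x = take_rows(self.emb_src, src_ids)  # (B,T,E)
        steps = [x[:, t, :] for t in range(T)]
        mask_cols = [src_mask[:, t : t + 1] for t in range(T)]
        init_states = []
        for l, (fwd, bwd) in enumerate(zip(self.enc_fwd, self.enc_bwd)):
            out_f, hf, cf = self._run_direction(fwd, steps, mask_cols, B)
            out_b, hb, cb = self._run_direction(
                bwd, steps[::-1], mask_cols[::-1], B
            )
            out_b = out_b[::-1]
            summed = [f + b for f, b in zip(out_f, out_b)]
            if train and self.cfg.dropout > 0 and l < self.cfg.layers - 1:
                summed = [dropout(s, self.cfg.dropout, rng, train) for s in summed]
            steps = summed
            init_states.append((hf + hb, cf + cb))
        enc_out = concat([s.reshape(B, 1, -1) for s in steps], axis=1)
        return enc_out, init_states

    # ---- decoder ------------------------------------------------------------

    def _attend(self, h_top: Tensor, enc_out: Tensor, mask_bias: np.ndarray):
        """Scaled dot-product attention of one decoder state over the source."""
        H = self.cfg.hidden
        q = h_top.reshape(-1, 1, H)  # (B,1,H)
        scores = q @ enc_out.transpose(0, 2, 1) * (1.0 / np.sqrt(H))  # (B,1,T)
        weights = softmax(scores + Tensor(mask_bias[:, None, :]), axis=-1)
        ctx = (weights @ enc_out).reshape(-1, H)
        return ctx, weights

    def _decode_step(self, y_prev_emb, states, enc_out, mask_bias, train, rng):
        x = y_prev_emb
        new_states = []
        for l, cell in enumerate(self.dec):
            h, c = states[l]
            h, c = cell.step(x, h, c, None)
            new_states.append((h, c))
            x = h
            if train and self.cfg.dropout > 0 and l < self.cfg.layers - 1:
                x = dropout(x, self.cfg.dropout, rng, train)
        ctx, weights = self._attend(x, enc_out, mask_bias)
        combined = concat([x, ctx], axis=-1) @ self.w_comb + self.b_comb
        logits = combined.tanh() @ self.w_out + self.b_out
        return logits, new_states, weights

    # ---- interfaces used by training / decoding -----------------------------

    def forward_logits(
        self,
        src_ids: np.ndarray,
        src_mask: np.ndarray,
        tgt_in: np.ndarray,
        train: bool = False,
        rng: np.random.Generator | None = None,
    ) -> Tensor:
        """Teacher-forced logits (B, T_out, V)."""
        B, T_out = tgt_in.shape
        enc_out, states = self.encode(src_ids, src_mask, train, rng)
        mask_bias = (1.0 - src_mask) * NEG_INF
        y_emb = take_rows(self.emb_tgt, tgt_in)
        logits_steps = []
        for t in range(T_out):
            logits, states, _ = self._decode_step(
                y_emb[:, t, :], states, enc_out, mask_bias, train, rng
            )
            logits_steps.append(logits.reshape(B, 1, -1))
        return concat(logits_steps, axis=1)

    def init_decode(self, src_ids: np.ndarray, src_mask: np.ndarray) -> dict:
        enc_out, states = self.encode(src_ids, src_mask, train=False)
        return {
            "enc_out": enc_out,
            "states": states,
            "mask_bias": (1.0 - src_mask) * NEG_INF,
        }

    def step(self, state: dict, prev_ids: np.ndarray) -> np.ndarray:
        """One generation step; returns logits (B, V) and mutates state."""
        y_emb = take_rows(self.emb_tgt, prev_ids)
        logits, new_states, weights = self._decode_step(
            y_emb, state["states"], state["enc_out"], state["mask_bias"], False, None
        )
        state["states"] = new_states
        state["last_attention"] = weights.data[:, 0, :]
        return logits.data
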