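"""SMILES sequence encoder.

Token ids are embedded (padding id 0 maps to a frozen zero row), run
through a bidirectional GRU, and the two directional states at each step
are combined linearly, s_t = W_t s_fwd_t + V_t s_bwd_t + b_t.  The drug
vector is a fully connected readout of the masked mean of the combined
states over valid (non-padded) timesteps, giving one row of the sequence
feature matrix S per drug.

The embedding table is trained end-to-end; ``load_embedding_dictionary``
lets a user seed rows from a whitespace-separated ``token v1 ... v_dh``
text file.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np

from .autodiff import Embedding, GRUCell, Linear, Tensor, gather_rows
from .config import ModelConfig
from .data import PAD_ID, TokenSequence

__all__ = ["SSFEMParams", "embed_sequence", "bigru_encode",
           "encode_all_sequences", "load_embedding_dictionary"]


class SSFEMParams:
    """Embedding table, the two directional GRU cells, the direction
    combination (W_t, V_t, b_t) and the readout projection."""

    def __init__(self, vocab_size: int, config: ModelConfig,
                 rng: np.random.Generator):
        d = config.d_h
        self.config = config
        self.vocab_size = vocab_size
        # +1 row: dedicated unknown-token id (= vocab_size) for OOV tokens
        self.embedding = Embedding(vocab_size + 1, d, rng)
        self.gru_fwd = GRUCell(d, d, rng)
        self.gru_bwd = GRUCell(d, d, rng)
        self.comb_fwd = Linear(d, d, rng, bias=False)   # W_t
        self.comb_bwd = Linear(d, d, rng, bias=False)   # V_t
        self.comb_bias = Tensor(np.zeros(d), requires_grad=True)  # b_t
        self.readout = Linear(d, config.d_g, rng)

    def parameters(self) -> list[Tensor]:
        return (self.embedding.parameters() + self.gru_fwd.parameters()
                + self.gru_bwd.parameters() + self.comb_fwd.parameters()
                + self.comb_bwd.parameters() + [self.comb_bias]
                + self.readout.parameters())

    def grad_masks(self) -> dict[int, np.ndarray]:
        return {id(self.embedding.table): self.embedding.grad_mask}


def embed_sequence(tokens: TokenSequence, params: SSFEMParams) -> Tensor:
    """Embed one token sequence to an (L_s, d_h) matrix; padded rows are zero."""
    ids = tokens.token_ids
    if ids.max(initial=0) >= params.embedding.table.shape[0]:
        raise ValueError("token id out of vocabulary range")
    return params.embedding(ids)


def _bigru_states(ids: np.ndarray, valid: np.ndarray, params: SSFEMParams
                  ) -> Tensor:
    """Masked mean over valid steps of the combined BiGRU states.

    ids: (B, L) int; valid: (B,) valid lengths.  Steps beyond a sequence's
    valid length leave its hidden state untouched (mask), so the result is
    independent of the padded length.  The time loop only runs to the
    batch maximum valid length; later steps would be identities.
    """
    B, L = ids.shape
    d = params.config.d_h
    if (valid < 1).any():
        raise ValueError("valid_length must be >= 1")
    t_max = int(valid.max())
    # one embedding lookup per timestep keeps autodiff temporaries small
    x_steps = [params.embedding(ids[:, t]) for t in range(t_max)]
    masks = [Tensor((t < valid).astype(np.float64)[:, None])
             for t in range(t_max)]

    def run(cell: GRUCell, order: range) -> list[Tensor | None]:
        h = Tensor(np.zeros((B, d)))
        states: list[Tensor | None] = [None] * L
        for t in order:
            h_new = cell(x_steps[t], h)
            h = masks[t] * h_new + (1.0 - masks[t]) * h
            states[t] = h
        return states

    fwd = run(params.gru_fwd, range(t_max))
    bwd = run(params.gru_bwd, range(t_max - 1, -1, -1))

    acc: Tensor | None = None
    for t in range(t_max):
        s_t = (params.comb_fwd(fwd[t]) + params.comb_bwd(bwd[t])
               + params.comb_bias)
        term = masks[t] * s_t
        acc = term if acc is None else acc + term
    assert acc is not None
    return acc * Tensor(1.0 / valid.astype(np.float64)[:, None])


def bigru_encode(tokens: TokenSequence, params: SSFEMParams) -> Tensor:
    """Encode one token sequence to a d_g drug vector."""
    pooled = _bigru_states(tokens.token_ids[None, :],
                           np.array([tokens.valid_length]), params)
    return params.readout(pooled)


def encode_all_sequences(sequences: list[TokenSequence],
                         params: SSFEMParams) -> Tensor:
    """Encode a list of token sequences to the (n, d_g) matrix S.

    All sequences are processed as one batch; results match one-at-a-time
    encoding to numerical precision.
    """
    ids = np.stack([s.token_ids for s in sequences])
    valid = np.array([s.valid_length for s in sequences])
    return params.readout(_bigru_states(ids, valid, params))


def load_embedding_dictionary(path: str | Path, vocab: dict[str, int],
                              params: SSFEMParams) -> int:
    """Load a whitespace-separated ``token v1 ... v_dh`` file into the
    embedding table for tokens present in the vocabulary; returns the
    number of rows loaded."""
    rows: dict[int, np.ndarray] = {}
    with open(path) as fh:
        for line in fh:
            parts = line.split()
            if not parts:
                continue
            token, vec = parts[0], np.array([float(v) for v in parts[1:]])
            if token in vocab and len(vec) == params.config.d_h:
                rows[vocab[token]] = vec
    params.embedding.load_vectors(rows)
    return len(rows)
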