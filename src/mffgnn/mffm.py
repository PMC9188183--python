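"""Multi-type feature fusion over the DDI network.

Intra-drug vectors from the molecular encoder (G) and the sequence encoder
(S) are summed to H = G + S and used as initial node features of a
multi-layer GCN over the symmetrically normalized interaction adjacency
A~ = K^{-1/2} (A + I) K^{-1/2}.  A per-layer sigmoid gate (highway style)
controls how much neighborhood information replaces the previous state,
countering over-smoothing.  A contrastive objective with a dot-product
discriminator aligns each drug's intra-drug vector h_i with its fused
network vector z_i against a sampled non-neighbor corruption.

Feature-subset ablations: "M" contributes G and "S" contributes S to H
(sum of whichever are enabled); "I" enables the interaction adjacency in
the GCN (without it, A~ is replaced by the identity so no neighborhood
information flows); with "I" alone, H is a learnable projection of one-hot
node identities (featureless-GCN convention).
"""

from __future__ import annotations

import logging

import numpy as np

from .autodiff import Linear, Tensor, dropout, gather_rows, xavier_uniform
from .config import ModelConfig

logger = logging.getLogger("mffgnn")

__all__ = ["MFFMParams", "fuse_intra", "normalize_adjacency", "gcn_layer",
           "gate_layer", "encode_ddi", "contrastive_loss"]


class MFFMParams:
    """Per-layer GCN weights, gate weights/biases, and the projection used
    for one-hot identity features in the interaction-only ablation."""

    def __init__(self, n_drugs: int, config: ModelConfig,
                 rng: np.random.Generator):
        d = config.d_g
        self.config = config
        self.gcn = [Linear(d, d, rng, bias=False) for _ in range(config.L_gcn)]
        self.gate = [Linear(d, d, rng) for _ in range(config.L_gcn)]
        self.identity_proj = None
        if config.feature_set == {"I"}:
            self.identity_proj = Linear(n_drugs, d, rng, bias=False)

    def parameters(self) -> list[Tensor]:
        ps: list[Tensor] = []
        for lin in self.gcn:
            ps += lin.parameters()
        if self.config.use_gating:
            for lin in self.gate:
                ps += lin.parameters()
        if self.identity_proj is not None:
            ps += self.identity_proj.parameters()
        return ps


def fuse_intra(G: Tensor | None, S: Tensor | None, params: MFFMParams,
               n_drugs: int) -> Tensor:
    """Intra-drug features H.

    Full model: H = G + S (elementwise).  Subset ablations pass None for a
    disabled encoder; with both disabled (interaction-only) H is the
    projected one-hot identity matrix.
    """
    parts = [t for t in (G, S) if t is not None]
    if parts:
        H = parts[0]
        for t in parts[1:]:
            if t.shape != H.shape:
                raise ValueError("G and S shapes differ")
            H = H + t
        return H
    if params.identity_proj is None:
        raise ValueError("feature set excludes S and M but no identity "
                         "projection was built")
    return params.identity_proj(Tensor(np.eye(n_drugs)))


def normalize_adjacency(A: np.ndarray) -> np.ndarray:
    """A~ = K^{-1/2} (A + I) K^{-1/2} with K_ii the self-loop-augmented
    degree.  Symmetric with eigenvalues in [-1, 1]; isolated nodes get a
    pure self-loop entry of 1."""
    A = np.asarray(A, dtype=np.float64)
    if not np.array_equal(A, A.T):
        raise ValueError("adjacency must be symmetric")
    if A.diagonal().any():
        raise ValueError("adjacency must have zero diagonal")
    A_hat = A + np.eye(A.shape[0])
    d_inv_sqrt = 1.0 / np.sqrt(A_hat.sum(axis=1))
    return A_hat * d_inv_sqrt[:, None] * d_inv_sqrt[None, :]


def gcn_layer(Z_prev: Tensor, A_norm: np.ndarray, params: MFFMParams,
              r: int, training: bool = False,
              rng: np.random.Generator | None = None) -> Tensor:
    """Pre-gate propagation: Z~_r = ReLU(A~ Z_{r-1} W_u^r), with dropout in
    training mode."""
    out = (Tensor(A_norm) @ params.gcn[r](Z_prev)).relu()
    if training and rng is not None:
        out = dropout(out, params.config.dropout, rng, training)
    return out


def gate_layer(Z_tilde: Tensor, Z_prev: Tensor, params: MFFMParams,
               r: int) -> Tensor:
    """Per-node gate T = sigmoid(W z_{r-1} + b);
    Z_r = Z~_r * T + Z_{r-1} * (1 - T)."""
    T = params.gate[r](Z_prev).sigmoid()
    return Z_tilde * T + Z_prev * (1.0 - T)


def encode_ddi(H: Tensor, A: np.ndarray, params: MFFMParams,
               training: bool = False,
               rng: np.random.Generator | None = None) -> Tensor:
    """Run L_gcn gated GCN layers from Z_0 = H over the normalized
    adjacency (or the identity when the interaction feature is ablated)."""
    cfg = params.config
    if "I" in cfg.feature_set:
        A_norm = normalize_adjacency(A)
    else:
        A_norm = np.eye(A.shape[0])
    Z = H
    for r in range(cfg.L_gcn):
        Z_tilde = gcn_layer(Z, A_norm, params, r, training=training, rng=rng)
        Z = gate_layer(Z_tilde, Z, params, r) if cfg.use_gating else Z_tilde
    return Z


def contrastive_loss(H: Tensor, Z: Tensor, A: np.ndarray,
                     rng: np.random.Generator) -> Tensor:
    """Mean over drugs of -log sig(h_i . z_i) - log sig(1 - h~_i . z_i),
    where h~_i is the intra-drug vector of one uniformly sampled
    non-neighbor of i.  Drugs adjacent to every other drug contribute only
    the positive term (logged)."""
    n = H.shape[0]
    neg_idx = np.zeros(n, dtype=np.intp)
    neg_mask = np.ones(n)
    for i in range(n):
        nonneighbors = np.flatnonzero((A[i] == 0) & (np.arange(n) != i))
        if len(nonneighbors) == 0:
            logger.info("drug %d adjacent to all others; skipping its "
                        "negative contrastive term", i)
            neg_mask[i] = 0.0
        else:
            neg_idx[i] = nonneighbors[rng.integers(len(nonneighbors))]
    pos_score = (H * Z).sum(axis=1)                      # (n,)
    neg_score = (gather_rows(H, neg_idx) * Z).sum(axis=1)
    loss_vec = -pos_score.log_sigmoid() \
        - Tensor(neg_mask) * (1.0 - neg_score).log_sigmoid()
    return loss_vec.mean()
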