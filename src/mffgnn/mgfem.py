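"""Molecular-graph encoder.

A graph interaction network (edge-then-node updates) interleaved with a
graph warp unit: a supernode carrying global molecular state, a K-head
attention transmitter shuttling information between atoms and supernode,
sigmoid warp gates interpolating local and global updates, and two GRUs
(one shared across atoms, one for the supernode) applying the recurrent
state update each layer.  The sum of the final supernode state and the
mean-pooled atom states is projected to the drug dimension, giving one
row of the molecular feature matrix G per drug.

All molecules in a dataset are encoded in one disjoint-union batch:
atoms/edges of every molecule are stacked and per-molecule aggregation is
done with segment sums, which keeps the computation identical to the
per-molecule form while amortizing the cost.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .autodiff import (GRUCell, Linear, Tensor, concat, dropout,
                       gather_rows, segment_sum, xavier_uniform)
from .config import ModelConfig
from .data import ATOM_FEATURE_DIM, BOND_FEATURE_DIM, MolecularGraph

__all__ = ["MolBatch", "MGFEMParams", "MGFEMState", "project_inputs",
           "supernode_init", "edge_update", "node_update", "transmitter",
           "warp_gate_atoms", "warp_gate_super", "gru_step", "mgfem_layer",
           "encode_molecules", "encode_molecule"]


@dataclass
class MolBatch:
    """Disjoint union of molecular graphs with per-atom molecule ids."""

    atom_features: np.ndarray   # (N, ATOM_FEATURE_DIM)
    edge_src: np.ndarray        # (E,) global atom indices
    edge_dst: np.ndarray        # (E,)
    bond_features: np.ndarray   # (E, BOND_FEATURE_DIM)
    mol_id: np.ndarray          # (N,) molecule index per atom
    n_mols: int
    atom_counts: np.ndarray     # (n_mols,)

    @classmethod
    def from_graphs(cls, graphs: list[MolecularGraph]) -> "MolBatch":
        offsets = np.cumsum([0] + [g.n_atoms for g in graphs])
        atom_feats = np.concatenate([g.atom_features for g in graphs])
        src = np.concatenate([g.edge_src + off
                              for g, off in zip(graphs, offsets)]).astype(np.intp)
        dst = np.concatenate([g.edge_dst + off
                              for g, off in zip(graphs, offsets)]).astype(np.intp)
        bonds = np.concatenate([g.bond_features for g in graphs])
        mol_id = np.concatenate([np.full(g.n_atoms, i, dtype=np.intp)
                                 for i, g in enumerate(graphs)])
        counts = np.array([g.n_atoms for g in graphs], dtype=np.float64)
        return cls(atom_features=atom_feats, edge_src=src, edge_dst=dst,
                   bond_features=bonds, mol_id=mol_id,
                   n_mols=len(graphs), atom_counts=counts)


class MGFEMParams:
    """All learnable tensors of the molecular encoder (Xavier-initialized)."""

    def __init__(self, config: ModelConfig, rng: np.random.Generator):
        d, K, L = config.d_h, config.K, config.L_mol
        self.config = config

        def mk(a, b):
            return Tensor(xavier_uniform(rng, a, b), requires_grad=True)

        self.W_v0 = mk(ATOM_FEATURE_DIM, d)
        self.W_e0 = mk(BOND_FEATURE_DIM, d)
        self.edge_lin = [Linear(3 * d, d, rng) for _ in range(L)]
        self.node_lin = [Linear(2 * d, d, rng) for _ in range(L)]
        self.W_g = [mk(d, d) for _ in range(L)]
        self.W_a1 = [[mk(d, d) for _ in range(K)] for _ in range(L)]
        self.W_a2 = [[mk(d, d) for _ in range(K)] for _ in range(L)]
        self.W_a = [[mk(d, 1) for _ in range(K)] for _ in range(L)]
        self.W_vs = [mk(K * d, d) for _ in range(L)]
        self.W_sv = [mk(d, d) for _ in range(L)]
        self.W_b1 = [mk(d, d) for _ in range(L)]
        self.W_b2 = [mk(d, d) for _ in range(L)]
        self.W_s1 = [mk(d, d) for _ in range(L)]
        self.W_s2 = [mk(d, d) for _ in range(L)]
        self.gru_v = GRUCell(d, d, rng)
        self.gru_g = GRUCell(d, d, rng)
        self.readout = Linear(d, config.d_g, rng)

    def parameters(self) -> list[Tensor]:
        ps: list[Tensor] = [self.W_v0, self.W_e0]
        for lin in self.edge_lin + self.node_lin:
            ps += lin.parameters()
        if self.config.use_gwu:
            for l in range(self.config.L_mol):
                ps.append(self.W_g[l])
                for k in range(self.config.K):
                    ps += [self.W_a1[l][k], self.W_a2[l][k], self.W_a[l][k]]
                ps += [self.W_vs[l], self.W_sv[l], self.W_b1[l],
                       self.W_b2[l], self.W_s1[l], self.W_s2[l]]
            ps += self.gru_v.parameters() + self.gru_g.parameters()
        ps += self.readout.parameters()
        return ps


@dataclass
class MGFEMState:
    """Per-layer atom / edge / supernode states over a molecule batch."""

    batch: MolBatch
    atom_states: Tensor      # (N, d_h)
    edge_states: Tensor      # (E, d_h)
    supernode: Tensor        # (n_mols, d_h)
    layer_index: int = 0
    attention: list = field(default_factory=list)  # (N, K) weights per layer


# ----------------------------------------------------------------------
# individual update operations
# ----------------------------------------------------------------------

def project_inputs(batch: MolBatch, params: MGFEMParams) -> MGFEMState:
    """Initial projections v^(0) = ReLU(W_v0 v_in), e^(0) = ReLU(W_e0 e_in),
    then supernode initialization."""
    v0 = (Tensor(batch.atom_features) @ params.W_v0).relu()
    e0 = (Tensor(batch.bond_features) @ params.W_e0).relu()
    state = MGFEMState(batch=batch, atom_states=v0, edge_states=e0,
                       supernode=None, layer_index=0)  # type: ignore[arg-type]
    state.supernode = supernode_init(state)
    return state


def supernode_init(state: MGFEMState) -> Tensor:
    """g^(0) = sum of initial atom states per molecule."""
    return segment_sum(state.atom_states, state.batch.mol_id,
                       state.batch.n_mols)


def edge_update(state: MGFEMState, params: MGFEMParams, l: int) -> Tensor:
    """e_ij <- ReLU[(e_ij || v_i || v_j) W_e + b_e]; the two directions of
    a bond are updated independently (their concatenation order differs)."""
    b = state.batch
    cat = concat([state.edge_states,
                  gather_rows(state.atom_states, b.edge_src),
                  gather_rows(state.atom_states, b.edge_dst)], axis=1)
    return params.edge_lin[l](cat).relu()


def node_update(state: MGFEMState, new_edges: Tensor, params: MGFEMParams,
                l: int) -> Tensor:
    """v~_i <- ReLU[(v_i || sum_{j in N(i)} e_ij) W_v + b_v].

    The neighbor sum aggregates over directed edges pointing into i, which
    equals the undirected neighborhood since every bond is stored in both
    directions.  Isolated atoms get a zero neighbor sum.
    """
    b = state.batch
    agg = segment_sum(new_edges, b.edge_dst, len(b.mol_id))
    cat = concat([state.atom_states, agg], axis=1)
    return params.node_lin[l](cat).relu()


def transmitter(state: MGFEMState, params: MGFEMParams, l: int
                ) -> tuple[Tensor, Tensor, np.ndarray]:
    """K-head attentive aggregation of atoms into the supernode message
    v_{v->s}, and the projected supernode-to-atom message g_{s->v}.

    Returns (v_vs, g_sv, attention_weights) with attention of shape (N, K)
    summing to 1 within each molecule per head.
    """
    b = state.batch
    v_prev, g_prev = state.atom_states, state.supernode
    heads, alphas = [], []
    for k in range(params.config.K):
        o = (v_prev @ params.W_a1[l][k]).tanh() * \
            gather_rows((g_prev @ params.W_a2[l][k]).tanh(), b.mol_id)
        logits = o @ params.W_a[l][k]                       # (N, 1)
        # per-molecule softmax; max-shift is a constant for stability
        shift = np.full((b.n_mols, 1), -np.inf)
        np.maximum.at(shift, b.mol_id, logits.data)
        e = (logits - Tensor(shift[b.mol_id])).exp()
        denom = segment_sum(e, b.mol_id, b.n_mols)
        alpha = e / gather_rows(denom, b.mol_id)            # (N, 1)
        heads.append(segment_sum(alpha * v_prev, b.mol_id, b.n_mols))
        alphas.append(alpha.data[:, 0])
    v_vs = (concat(heads, axis=1) @ params.W_vs[l]).tanh()
    g_sv = (g_prev @ params.W_sv[l]).tanh()
    return v_vs, g_sv, np.stack(alphas, axis=1)


def warp_gate_atoms(v_tilde: Tensor, g_sv_per_atom: Tensor,
                    params: MGFEMParams, l: int) -> Tensor:
    """Gated interpolation of the local atom update with the global message:
    alpha = sigmoid(W_b1 v~ + W_b2 g_{s->v}); out = (1-alpha) v~ + alpha g."""
    alpha = (v_tilde @ params.W_b1[l] + g_sv_per_atom @ params.W_b2[l]).sigmoid()
    return (1.0 - alpha) * v_tilde + alpha * g_sv_per_atom


def warp_gate_super(g_tilde: Tensor, v_vs: Tensor, params: MGFEMParams,
                    l: int) -> Tensor:
    """Gated interpolation of the supernode self-update with the aggregated
    atom message."""
    alpha = (g_tilde @ params.W_s1[l] + v_vs @ params.W_s2[l]).sigmoid()
    return (1.0 - alpha) * g_tilde + alpha * v_vs


def gru_step(state: MGFEMState, v_si: Tensor, g_is: Tensor,
             params: MGFEMParams) -> tuple[Tensor, Tensor]:
    """v^(l) = GRU_v(v^(l-1), v_{s->i}); g^(l) = GRU_g(g^(l-1), g_{i->s}).
    GRU_v is shared across all atoms."""
    v = params.gru_v(v_si, state.atom_states)
    g = params.gru_g(g_is, state.supernode)
    return v, g


# ----------------------------------------------------------------------
# full layer and encoder
# ----------------------------------------------------------------------

def mgfem_layer(state: MGFEMState, params: MGFEMParams, l: int,
                training: bool = False,
                rng: np.random.Generator | None = None) -> MGFEMState:
    """One full encoder layer: edge update -> node update -> supernode
    self-update -> transmitter -> warp gates -> GRUs (-> dropout)."""
    cfg = params.config
    e_new = edge_update(state, params, l)
    v_tilde = node_update(state, e_new, params, l)
    if not cfg.use_gwu:
        new_atoms = v_tilde
        new_super = state.supernode
        att = None
    else:
        g_tilde = (state.supernode @ params.W_g[l]).tanh()
        v_vs, g_sv, att = transmitter(state, params, l)
        g_sv_atoms = gather_rows(g_sv, state.batch.mol_id)
        v_si = warp_gate_atoms(v_tilde, g_sv_atoms, params, l)
        g_is = warp_gate_super(g_tilde, v_vs, params, l)
        new_atoms, new_super = gru_step(state, v_si, g_is, params)
    if training and rng is not None:
        new_atoms = dropout(new_atoms, cfg.dropout, rng, training)
        if cfg.use_gwu:
            new_super = dropout(new_super, cfg.dropout, rng, training)
    out = MGFEMState(batch=state.batch, atom_states=new_atoms,
                     edge_states=e_new, supernode=new_super,
                     layer_index=l + 1, attention=list(state.attention))
    if att is not None:
        out.attention.append(att)
    return out


def encode_molecules(batch: MolBatch, params: MGFEMParams,
                     training: bool = False,
                     rng: np.random.Generator | None = None) -> Tensor:
    """Encode every molecule in the batch to a d_g vector (matrix G).

    The readout projects the sum of the final supernode state (the global
    information carrier) and the mean-pooled final atom states; pooling
    the atoms keeps the last interaction layer's local updates in the
    drug vector, which the supernode alone would not see because the
    transmitter reads the previous layer's atom states.  The -GWU
    ablation drops the supernode path and uses the atom mean only.
    """
    cfg = params.config
    state = project_inputs(batch, params)
    for l in range(cfg.L_mol):
        state = mgfem_layer(state, params, l, training=training, rng=rng)
    sums = segment_sum(state.atom_states, batch.mol_id, batch.n_mols)
    atom_mean = sums * Tensor(1.0 / batch.atom_counts[:, None])
    pooled = state.supernode + atom_mean if cfg.use_gwu else atom_mean
    return params.readout(pooled)


def encode_molecule(graph: MolecularGraph, params: MGFEMParams,
                    training: bool = False,
                    rng: np.random.Generator | None = None) -> Tensor:
    """Encode a single molecule (1 x d_g)."""
    return encode_molecules(MolBatch.from_graphs([graph]), params,
                            training=training, rng=rng)
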