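"""Independent straight-line re-implementations of the model equations.

Everything here is plain NumPy with explicit Python loops over atoms,
edges, timesteps and drugs — no autodiff, no segment ops, no batching —
so it serves as an oracle for the vectorized implementation.
"""

from __future__ import annotations

import numpy as np


def sigmoid(x):
    return 1.0 / (1.0 + np.exp(-x))


def relu(x):
    return np.maximum(x, 0.0)


def gru_oracle(cell, x: np.ndarray, h: np.ndarray) -> np.ndarray:
    """One GRU step from the gate definitions, on 1-D numpy vectors."""
    W = {k: getattr(cell, k).data for k in
         ("W_xr", "W_xu", "W_xc", "W_hr", "W_hu", "W_hc",
          "b_r", "b_u", "b_c")}
    r = sigmoid(x @ W["W_xr"] + h @ W["W_hr"] + W["b_r"])
    u = sigmoid(x @ W["W_xu"] + h @ W["W_hu"] + W["b_u"])
    c = np.tanh(x @ W["W_xc"] + r * (h @ W["W_hc"]) + W["b_c"])
    return (1.0 - u) * c + u * h


def mgfem_oracle(graph, params) -> np.ndarray:
    """Per-molecule molecular encoder: input projections, edge/node
    updates, supernode self-update, K-head transmitter, warp gates and
    GRU state updates, followed by the readout projection."""
    cfg = params.config
    n = graph.n_atoms
    src, dst = graph.edge_src, graph.edge_dst
    v = relu(graph.atom_features @ params.W_v0.data)
    e = relu(graph.bond_features @ params.W_e0.data)
    g = v.sum(axis=0)
    for l in range(cfg.L_mol):
        We, be = params.edge_lin[l].W.data, params.edge_lin[l].b.data
        Wv, bv = params.node_lin[l].W.data, params.node_lin[l].b.data
        e_new = np.stack([
            relu(np.concatenate([e[k], v[src[k]], v[dst[k]]]) @ We + be)
            for k in range(len(src))]) if len(src) else e
        v_tilde = np.zeros_like(v)
        for i in range(n):
            agg = np.zeros(cfg.d_h)
            for k in range(len(src)):
                if dst[k] == i:
                    agg = agg + e_new[k]
            v_tilde[i] = relu(np.concatenate([v[i], agg]) @ Wv + bv)
        if not cfg.use_gwu:
            v, e = v_tilde, e_new
            continue
        g_tilde = np.tanh(g @ params.W_g[l].data)
        heads = []
        for k in range(cfg.K):
            o = np.stack([np.tanh(v[i] @ params.W_a1[l][k].data)
                          * np.tanh(g @ params.W_a2[l][k].data)
                          for i in range(n)])
            logits = np.array([o[i] @ params.W_a[l][k].data[:, 0]
                               for i in range(n)])
            alpha = np.exp(logits) / np.exp(logits).sum()
            heads.append(sum(alpha[i] * v[i] for i in range(n)))
        v_vs = np.tanh(np.concatenate(heads) @ params.W_vs[l].data)
        g_sv = np.tanh(g @ params.W_sv[l].data)
        v_si = np.zeros_like(v)
        for i in range(n):
            a = sigmoid(v_tilde[i] @ params.W_b1[l].data
                        + g_sv @ params.W_b2[l].data)
            v_si[i] = (1.0 - a) * v_tilde[i] + a * g_sv
        a_s = sigmoid(g_tilde @ params.W_s1[l].data
                      + v_vs @ params.W_s2[l].data)
        g_is = (1.0 - a_s) * g_tilde + a_s * v_vs
        v = np.stack([gru_oracle(params.gru_v, v_si[i], v[i])
                      for i in range(n)])
        g = gru_oracle(params.gru_g, g_is, g)
        e = e_new
    pooled = g + v.mean(axis=0) if cfg.use_gwu else v.mean(axis=0)
    return pooled @ params.readout.W.data + params.readout.b.data


def bigru_oracle(token_ids: np.ndarray, valid: int, params) -> np.ndarray:
    """Single-sequence BiGRU encoding: forward pass over valid steps,
    backward pass in reverse, linear combination of directions, masked
    mean, readout."""
    d = params.config.d_h
    x = params.embedding.table.data[token_ids]
    fwd = []
    h = np.zeros(d)
    for t in range(valid):
        h = gru_oracle(params.gru_fwd, x[t], h)
        fwd.append(h)
    bwd = [None] * valid
    h = np.zeros(d)
    for t in range(valid - 1, -1, -1):
        h = gru_oracle(params.gru_bwd, x[t], h)
        bwd[t] = h
    s = [fwd[t] @ params.comb_fwd.W.data + bwd[t] @ params.comb_bwd.W.data
         + params.comb_bias.data for t in range(valid)]
    pooled = np.mean(s, axis=0)
    return pooled @ params.readout.W.data + params.readout.b.data


def normalized_adjacency_oracle(A: np.ndarray) -> np.ndarray:
    A_hat = A + np.eye(A.shape[0])
    D = np.diag(A_hat.sum(axis=1))
    D_inv_sqrt = np.diag(1.0 / np.sqrt(np.diag(D)))
    return D_inv_sqrt @ A_hat @ D_inv_sqrt


def gated_gcn_oracle(H: np.ndarray, A: np.ndarray, params) -> np.ndarray:
    """Per-node gated GCN: z_i^r = ReLU(sum_j A~_ij z_j^{r-1} W_u^r), then
    the highway gate T = sigmoid(W z^{r-1} + b)."""
    cfg = params.config
    if "I" in cfg.feature_set:
        An = normalized_adjacency_oracle(A)
    else:
        An = np.eye(A.shape[0])
    n = H.shape[0]
    Z = H.copy()
    for r in range(cfg.L_gcn):
        Wu = params.gcn[r].W.data
        Z_tilde = np.zeros_like(Z)
        for i in range(n):
            acc = np.zeros(Z.shape[1])
            for j in range(n):
                acc = acc + An[i, j] * (Z[j] @ Wu)
            Z_tilde[i] = relu(acc)
        if cfg.use_gating:
            Wg, bg = params.gate[r].W.data, params.gate[r].b.data
            Z_new = np.zeros_like(Z)
            for i in range(n):
                T = sigmoid(Z[i] @ Wg + bg)
                Z_new[i] = Z_tilde[i] * T + Z[i] * (1.0 - T)
            Z = Z_new
        else:
            Z = Z_tilde
    return Z


def contrastive_oracle(H: np.ndarray, Z: np.ndarray, A: np.ndarray,
                       seed_rng: np.random.Generator) -> float:
    """Scalar contrastive loss with the same negative-sampling sequence as
    the implementation (one uniform non-neighbor per drug)."""
    n = H.shape[0]
    total = 0.0
    neg_idx = np.zeros(n, dtype=int)
    has_neg = np.ones(n, dtype=bool)
    for i in range(n):
        nonneighbors = np.flatnonzero((A[i] == 0) & (np.arange(n) != i))
        if len(nonneighbors) == 0:
            has_neg[i] = False
        else:
            neg_idx[i] = nonneighbors[seed_rng.integers(len(nonneighbors))]
    for i in range(n):
        total += -np.log(sigmoid(H[i] @ Z[i]))
        if has_neg[i]:
            total += -np.log(sigmoid(1.0 - H[neg_idx[i]] @ Z[i]))
    return total / n


def pair_score_oracle(Z: np.ndarray, i: int, j: int, model) -> float:
    """sigmoid of the two-layer MLP on the elementwise product."""
    h = relu((Z[i] * Z[j]) @ model.mlp_hidden.W.data + model.mlp_hidden.b.data)
    return float(sigmoid(h @ model.mlp_out.W.data[:, 0]
                         + model.mlp_out.b.data[0]))


def bce_oracle(preds: np.ndarray, labels: np.ndarray,
               clamp: float = 1e-7) -> float:
    p = np.clip(preds, clamp, 1.0 - clamp)
    return float(-(labels * np.log(p) + (1 - labels) * np.log(1 - p)).sum())


def auroc_oracle(scores: np.ndarray, labels: np.ndarray) -> float:
    """Exhaustive concordant-pair counting with ties at 1/2."""
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    total = 0.0
    for p in pos:
        for q in neg:
            total += 1.0 if p > q else (0.5 if p == q else 0.0)
    return total / (len(pos) * len(neg))
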