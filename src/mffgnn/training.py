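"""End-to-end model assembly, losses and the training loop.

Each epoch runs a full transductive forward pass — molecular encoder over
every drug, sequence encoder over every SMILES, intra-drug fusion, gated
GCN over the *training* interaction adjacency (held-out edges never enter
message passing) — then a joint objective L = L_r + alpha * L_c combining
the supervised binary cross-entropy over labeled pairs with the
contrastive alignment term.  Optimization is Adam with an exponentially
decayed learning rate (lr0 * decay^epoch), Xavier initialization, and
early stopping on validation AUROC.
"""

from __future__ import annotations

import io
import json
import logging
import zipfile
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from sklearn.metrics import roc_auc_score

from .autodiff import Adam, Linear, Tensor
from .config import ModelConfig
from .data import InteractionDataset, SplitBundle, sample_negative_pairs
from .mffm import MFFMParams, contrastive_loss, encode_ddi, fuse_intra
from .mgfem import MGFEMParams, MolBatch, encode_molecules
from .ssfem import SSFEMParams, encode_all_sequences

logger = logging.getLogger("mffgnn")

__all__ = ["MFFGNNModel", "build_variant", "score_pairs", "score_pair",
           "bce_loss", "total_loss", "train", "save_checkpoint",
           "load_checkpoint", "TrainState"]

PRED_CLAMP = 1e-7  # guard against log(0); implementation detail


@dataclass
class TrainState:
    epoch: int = 0
    learning_rate: float = 0.0
    best_val_metric: float = -np.inf
    patience_counter: int = 0
    rng_seed: int = 0


class MFFGNNModel:
    """All parameter groups plus the pair-scoring MLP."""

    def __init__(self, config: ModelConfig, vocab: dict[str, int],
                 n_drugs: int, rng: np.random.Generator | None = None):
        if rng is None:
            rng = np.random.default_rng(config.seed)
        self.config = config
        self.vocab = vocab
        self.n_drugs = n_drugs
        self.mgfem = MGFEMParams(config, rng)
        self.ssfem = SSFEMParams(len(vocab), config, rng)
        self.mffm = MFFMParams(n_drugs, config, rng)
        # two fully connected layers on the elementwise pair product
        self.mlp_hidden = Linear(config.d_g, config.d_g, rng)
        self.mlp_out = Linear(config.d_g, 1, rng)

    # -- parameter bookkeeping -----------------------------------------
    def parameters(self) -> list[Tensor]:
        """Parameters reachable by the configured variant's forward pass."""
        fs = self.config.feature_set
        ps: list[Tensor] = []
        if "M" in fs:
            ps += self.mgfem.parameters()
        if "S" in fs:
            ps += self.ssfem.parameters()
        ps += self.mffm.parameters()
        ps += self.mlp_hidden.parameters() + self.mlp_out.parameters()
        return ps

    def grad_masks(self) -> dict[int, np.ndarray]:
        return self.ssfem.grad_masks() if "S" in self.config.feature_set else {}

    # -- forward --------------------------------------------------------
    def forward(self, dataset: InteractionDataset, A_message: np.ndarray,
                training: bool = False,
                rng: np.random.Generator | None = None
                ) -> tuple[Tensor, Tensor]:
        """Compute intra-drug features H and fused network features Z using
        `A_message` (training-positive adjacency) for message passing."""
        fs = self.config.feature_set
        G = S = None
        if "M" in fs:
            batch = MolBatch.from_graphs([d.graph for d in dataset.drugs])
            G = encode_molecules(batch, self.mgfem, training=training, rng=rng)
        if "S" in fs:
            S = encode_all_sequences([d.tokens for d in dataset.drugs],
                                     self.ssfem)
        H = fuse_intra(G, S, self.mffm, dataset.n_drugs)
        Z = encode_ddi(H, A_message, self.mffm, training=training, rng=rng)
        return H, Z


def build_variant(config: ModelConfig, dataset: InteractionDataset,
                  rng: np.random.Generator | None = None) -> MFFGNNModel:
    """Assemble the model variant selected by the configuration switches:
    use_gwu / use_gating / use_contrastive and the feature subset."""
    return MFFGNNModel(config, dataset.vocab, dataset.n_drugs, rng=rng)


# ----------------------------------------------------------------------
# scoring and losses
# ----------------------------------------------------------------------

def score_pairs(Z: Tensor, pairs: np.ndarray, model: MFFGNNModel) -> Tensor:
    """sigmoid(MLP(z_i * z_j)) for an (m, 2) index array; symmetric in
    (i, j) because the elementwise product commutes."""
    from .autodiff import gather_rows
    pairs = np.asarray(pairs, dtype=np.intp)
    prod = gather_rows(Z, pairs[:, 0]) * gather_rows(Z, pairs[:, 1])
    hidden = model.mlp_hidden(prod).relu()
    return model.mlp_out(hidden).sigmoid().reshape(-1)


def score_pair(Z: Tensor, i: int, j: int, model: MFFGNNModel) -> float:
    if i == j:
        raise ValueError("cannot score a drug against itself")
    return float(score_pairs(Z, np.array([[i, j]]), model).data[0])


def bce_loss(predictions: Tensor, labels: np.ndarray) -> Tensor:
    """Summed binary cross-entropy; predictions clamped to
    [1e-7, 1 - 1e-7]."""
    y = np.asarray(labels, dtype=np.float64)
    p = predictions.clip(PRED_CLAMP, 1.0 - PRED_CLAMP)
    return -(Tensor(y) * p.log() + Tensor(1.0 - y) * (1.0 - p).log()).sum()


def total_loss(L_r: Tensor, L_c: Tensor | None, alpha: float) -> Tensor:
    """Joint objective L = L_r + alpha * L_c."""
    if L_c is None or alpha == 0.0:
        return L_r
    return L_r + alpha * L_c


# ----------------------------------------------------------------------
# training loop
# ----------------------------------------------------------------------

def _adjacency_from_pairs(pairs, n: int) -> np.ndarray:
    A = np.zeros((n, n), dtype=np.int8)
    for i, j in pairs:
        A[i, j] = A[j, i] = 1
    return A


def train(dataset: InteractionDataset, splits: SplitBundle,
          config: ModelConfig) -> tuple[MFFGNNModel, list[dict]]:
    """Train a model on the split bundle; returns the best-validation model
    and the per-epoch history (epoch, lr, train_loss, val_auroc).

    Fully reproducible under config.seed (float64 arithmetic, seeded
    dropout and negative resampling).
    """
    master = np.random.default_rng(config.seed)
    model = build_variant(config, dataset,
                          rng=np.random.default_rng(master.integers(2**31)))
    drop_seed = int(master.integers(2**31))
    contrast_seed = int(master.integers(2**31))
    resample_seed = int(master.integers(2**31))

    n = dataset.n_drugs
    A_train = _adjacency_from_pairs(splits.train_pos, n)
    use_contrastive = config.use_contrastive and config.alpha > 0

    train_neg = list(splits.train_neg)
    val_pairs = np.array(splits.val_pos + splits.val_neg, dtype=np.intp)
    val_labels = np.array([1] * len(splits.val_pos) + [0] * len(splits.val_neg))

    opt = Adam(model.parameters(), lr=config.lr0,
               grad_masks=model.grad_masks())
    state = TrainState(rng_seed=config.seed)
    history: list[dict] = []
    best_params: list[np.ndarray] | None = None

    for epoch in range(config.max_epochs):
        lr = config.lr0 * config.lr_decay ** epoch
        opt.lr = lr
        if config.resample_negatives and epoch > 0:
            rng_rs = np.random.default_rng((resample_seed + epoch) % 2**31)
            train_neg = sample_negative_pairs(dataset.adjacency,
                                              len(splits.train_pos), rng_rs)
        pairs = np.array(list(splits.train_pos) + train_neg, dtype=np.intp)
        labels = np.array([1] * len(splits.train_pos) + [0] * len(train_neg))

        drop_rng = np.random.default_rng((drop_seed + epoch) % 2**31)
        H, Z = model.forward(dataset, A_train, training=True, rng=drop_rng)
        preds = score_pairs(Z, pairs, model)
        L_r = bce_loss(preds, labels)
        L_c = None
        if use_contrastive:
            c_rng = np.random.default_rng((contrast_seed + epoch) % 2**31)
            L_c = contrastive_loss(H, Z, A_train, c_rng)
        loss = total_loss(L_r, L_c, config.alpha if use_contrastive else 0.0)
        if not np.isfinite(loss.data):
            raise RuntimeError(
                f"non-finite loss at epoch {epoch}: L_r={L_r.data}, "
                f"L_c={None if L_c is None else L_c.data}")
        opt.zero_grad()
        loss.backward()
        opt.step()

        # validation in eval mode (no dropout)
        _, Z_eval = model.forward(dataset, A_train, training=False)
        val_scores = score_pairs(Z_eval, val_pairs, model).data
        val_auroc = float(roc_auc_score(val_labels, val_scores))
        history.append({"epoch": epoch, "lr": lr,
                        "train_loss": float(loss.data),
                        "val_auroc": val_auroc})

        state.epoch = epoch
        state.learning_rate = lr
        if val_auroc > state.best_val_metric:
            state.best_val_metric = val_auroc
            state.patience_counter = 0
            best_params = [p.data.copy() for p in model.parameters()]
        else:
            state.patience_counter += 1
            if state.patience_counter >= config.patience:
                logger.info("early stopping at epoch %d (best val AUROC "
                            "%.4f)", epoch, state.best_val_metric)
                break

    if config.restore_best and best_params is not None:
        for p, data in zip(model.parameters(), best_params):
            p.data = data
    return model, history


# ----------------------------------------------------------------------
# checkpointing (parameters + config + vocabulary in one archive)
# ----------------------------------------------------------------------

def _all_parameters(model: MFFGNNModel) -> list[Tensor]:
    """Every parameter tensor regardless of ablation switches, in a fixed
    order, for serialization."""
    ps: list[Tensor] = [model.mgfem.W_v0, model.mgfem.W_e0]
    m = model.mgfem
    for lin in m.edge_lin + m.node_lin:
        ps += lin.parameters()
    for l in range(model.config.L_mol):
        ps.append(m.W_g[l])
        for k in range(model.config.K):
            ps += [m.W_a1[l][k], m.W_a2[l][k], m.W_a[l][k]]
        ps += [m.W_vs[l], m.W_sv[l], m.W_b1[l], m.W_b2[l], m.W_s1[l],
               m.W_s2[l]]
    ps += m.gru_v.parameters() + m.gru_g.parameters() + m.readout.parameters()
    s = model.ssfem
    ps += (s.embedding.parameters() + s.gru_fwd.parameters()
           + s.gru_bwd.parameters() + s.comb_fwd.parameters()
           + s.comb_bwd.parameters() + [s.comb_bias] + s.readout.parameters())
    f = model.mffm
    for lin in f.gcn + f.gate:
        ps += lin.parameters()
    if f.identity_proj is not None:
        ps += f.identity_proj.parameters()
    ps += model.mlp_hidden.parameters() + model.mlp_out.parameters()
    return ps


def save_checkpoint(model: MFFGNNModel, path: str | Path) -> None:
    """Serialize parameters, configuration and vocabulary to one archive."""
    meta = {"config": model.config.to_dict(), "vocab": model.vocab,
            "n_drugs": model.n_drugs}
    buf = io.BytesIO()
    np.savez(buf, *[p.data for p in _all_parameters(model)])
    with zipfile.ZipFile(path, "w") as zf:
        zf.writestr("meta.json", json.dumps(meta))
        zf.writestr("params.npz", buf.getvalue())


def load_checkpoint(path: str | Path) -> MFFGNNModel:
    with zipfile.ZipFile(path) as zf:
        meta = json.loads(zf.read("meta.json"))
        npz = np.load(io.BytesIO(zf.read("params.npz")))
    config = ModelConfig.from_dict(meta["config"])
    model = MFFGNNModel(config, meta["vocab"], meta["n_drugs"])
    params = _all_parameters(model)
    arrays = [npz[k] for k in npz.files]
    if len(arrays) != len(params):
        raise ValueError("checkpoint parameter count mismatch")
    for p, a in zip(params, arrays):
        p.data = a.astype(np.float64)
    return model
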