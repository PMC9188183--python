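# mffgnn

Multi-type feature-fusion graph neural network for drug–drug interaction
(DDI) link prediction.

Adverse drug–drug interactions are a central safety concern in
polypharmacy, and experimentally screening all drug pairs is infeasible.
`mffgnn` treats DDI prediction as link prediction on an interaction graph
whose nodes are drugs, and fuses three complementary views of each drug:

- **M — molecular graph topology.** Each SMILES string is parsed (RDKit)
  into an atom/bond graph. A graph interaction network updates directed
  bond states from their endpoints, `e_ij ← ReLU[(e_ij ‖ v_i ‖ v_j) W_e + b_e]`,
  then atom states from incoming bonds. A *graph warp unit* adds a
  supernode `g` carrying global molecular state: a K-head attention
  transmitter aggregates atoms into a message for the supernode, sigmoid
  *warp gates* interpolate local updates with transmitted global
  information, and two GRUs (one shared across atoms, one for the
  supernode) apply the recurrent state update each layer.
- **S — SMILES chemical context.** Token sequences (bracket atoms and
  two-letter halogens are single tokens) are embedded and encoded by a
  bidirectional GRU; the directional states are combined linearly,
  `s_t = W_t s⃗_t + V_t s⃖_t + b_t`, mean-pooled over valid steps and
  projected.
- **I — interaction neighborhood.** The intra-drug vectors `H = G ⊕ S`
  initialize node features of a multi-layer GCN over the symmetrically
  normalized adjacency `Ã = K̂^{-1/2}(A + I)K̂^{-1/2}`; a per-layer highway
  gate `Z_r = Z̃_r ⊙ T + Z_{r-1} ⊙ (1−T)`, `T = σ(W z^{r-1} + b)`, counters
  over-smoothing. A contrastive term with a dot-product discriminator
  aligns each drug's intra-drug vector `h_i` with its fused vector `z_i`
  against sampled non-neighbors.

A pair `(i, j)` is scored by `ŷ_ij = σ(MLP(z_i ⊙ z_j))` (symmetric by
construction) and trained with `L = L_r + α·L_c`, where `L_r` is the
binary cross-entropy over labeled pairs and `L_c` the contrastive term.
Every component — the −GWU / −Gating / −Contrastive ablations and all
feature subsets of {S, M, I} — is switchable from the configuration.

The package is aimed at method researchers who want a fully inspectable,
deterministic CPU implementation: the tensor autodiff core
(`mffgnn.autodiff`) is ~400 lines of NumPy, all arithmetic is float64,
and every training run is exactly reproducible from its seed.

## Worked example

Synthetic datasets emulate the structure of public DDI corpora: valid
drug-like SMILES plus an undirected interaction graph with planted
scaffold-family communities (within-community interaction probability
`p_in`, between `p_out`), so the link pattern is learnable from both
chemistry and graph structure.

```python
from mffgnn import (ModelConfig, generate_synthetic, make_splits, train,
                    evaluate_checkpoint)

ds = generate_synthetic(n_drugs=20, n_communities=2, p_in=0.6,
                        p_out=0.05, seed=7)
splits = make_splits(ds, seed=0)             # 64/16/20 + matched negatives
cfg = ModelConfig.small_benchmark(seed=0)    # desk-scale width & schedule
model, history = train(ds, splits, cfg)
rep = evaluate_checkpoint(model, ds, splits)
print(f"test AUROC {rep.auroc:.3f}  AUPRC {rep.auprc:.3f}  F1 {rep.f1:.3f}")
```

Output:

```
test AUROC 0.743  AUPRC 0.710  F1 0.720
```

The dataset has 20 drugs and 62 positive interactions; training stops
early (131 epochs here) on validation AUROC. A test AUROC well above the
0.5 chance level shows the model recovered the planted community
structure from held-out pairs; the attainable ceiling is below 1.0
because, at `p_in = 0.6`, many within-community pairs are true non-edges
that are statistically indistinguishable from held-out edges.

The same pipeline is available from the shell:

```bash
mffgnn simulate --n-drugs 20 --communities 2 --p-in 0.6 --p-out 0.05 \
       --seed 7 --out data/
mffgnn train --drugs data/drugs.csv --edges data/edges.csv --out run/
mffgnn predict --checkpoint run/checkpoint.zip --drugs data/drugs.csv \
       --edges data/edges.csv --pairs pairs.csv --out scores.csv
mffgnn evaluate --checkpoint run/checkpoint.zip --drugs data/drugs.csv \
       --edges data/edges.csv --splits run/splits.csv --out metrics.json
mffgnn crossval --train-dir data/ --test-dirs other/ --out cross/
```

Ablations: `mffgnn train ... --ablate gwu --features S,M`.

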