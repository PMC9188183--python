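# Methods

## Problem setting

Drug–drug interaction (DDI) prediction is cast as transductive link
prediction. Given `n` drugs with SMILES strings and a symmetric 0/1
adjacency `A` of known interactions, the task is to score unobserved
pairs. All drugs are visible during training; only a subset of pairs is
labeled, and message passing uses the training-positive adjacency only,
so held-out edges never leak into the encoder.

## Model

### Molecular-graph encoder (feature channel M)

SMILES are parsed with RDKit. Atom descriptors are fixed-length
concatenations of one-hot blocks — element over
{C, N, O, S, F, Cl, Br, I, P, B, Si, Se, other}, formal charge clipped to
[−2, 2], aromatic flag, hybridization (S/SP/SP2/SP3/SP3D/SP3D2/other),
chirality tag, heavy-atom degree 0–6 (37 dimensions). Bond descriptors
are bond type (single/double/triple/aromatic), in-ring and conjugated
flags (6 dimensions). Every chemical bond is stored as two directed
edges sharing one descriptor.

Inputs are projected with ReLU to width `d_h`. Each of `L_mol` layers
then runs, in order: directed-edge update from the edge state and its two
endpoint states; atom update from the atom state and the sum of incoming
edge states; supernode self-update `g̃ = tanh(W_g g)`; the transmitter —
per head `k`, atom scores `o_i = tanh(W_a1 v_i) ⊙ tanh(W_a2 g)` are
mapped to scalar logits and softmax-normalized within the molecule, and
the attention-weighted atom sums of all K heads are concatenated and
mapped with tanh to the atoms→supernode message, while the
supernode→atoms message is `tanh(W_sv g)`; two sigmoid warp gates
interpolating (a) the updated atom state with the supernode message and
(b) the supernode self-update with the atom message; finally GRU state
updates for atoms (one cell shared across atoms) and supernode. The
transmitter and the GRUs read the *previous* layer's states, as the
recurrence requires.

The supernode warp gate uses its own gating coefficient
`α_{i→s} = σ(W_s1 g̃ + W_s2 v_{v→s})`; the alternative reading (reusing
the atom-side coefficient) would gate the supernode by a quantity of the
wrong shape and is treated as a notational slip.

**Readout.** The drug vector is a linear projection of
`g^(L) + mean_i v_i^(L)`. The supernode is the designated global carrier,
but because the transmitter reads layer-(l−1) atom states, a
supernode-only readout would make the last layer's edge/node weights
unreachable by any gradient; adding the mean-pooled atom states keeps
every parameter live while preserving permutation invariance. The −GWU
ablation (no supernode machinery) mean-pools atom states only.

### Sequence encoder (feature channel S)

SMILES are tokenized by a deterministic regex: bracket atoms `[...]` and
the two-letter halogens Cl/Br are single tokens; every other character
stands alone. Ids are assigned by first appearance (0 = padding; a
dedicated trailing id serves out-of-vocabulary tokens at transfer time).
Sequences are zero-padded or tail-cut to a fixed `L_s`.

The embedding table is trained end-to-end (Xavier init, frozen all-zero
padding row); `load_embedding_dictionary` can seed rows from a
`token v1 … v_dh` text file. A bidirectional GRU runs over the valid
steps (padded steps leave the hidden state untouched, so vectors are
independent of the padding length); the directional states are combined
linearly per step, mean-pooled over valid steps, and projected to `d_g`.
Pooling over steps rather than taking final states was chosen for length
robustness; the linear combination is not followed by a nonlinearity.

### Fusion over the DDI network (feature channel I)

`H = G + S` initializes node features of an `L_gcn`-layer GCN over
`Ã = K̂^{-1/2}(A + I)K̂^{-1/2}` (eigenvalues in [−1, 1]; isolated nodes
reduce to self-loops). Each layer computes
`Z̃_r = ReLU(Ã Z_{r−1} W_u^r)` followed by the highway gate
`Z_r = Z̃_r ⊙ T + Z_{r−1} ⊙ (1−T)`, `T = σ(W z^{r−1} + b)` — the gate is
computed from the previous layer's state, and the gated output is what
enters the next layer.

The contrastive objective averages, over drugs,
`−log σ(h_i·z_i) − log σ(1 − h̃_i·z_i)`, where `h̃_i` is the intra-drug
vector of one uniformly sampled non-neighbor (resampled each epoch). A
drug adjacent to all others contributes only its positive term (logged).

**Feature subsets.** The three information channels are switchable: M
contributes `G` and S contributes `S` to `H` (sum of the enabled ones);
I enables the interaction adjacency in the GCN — without it `Ã` is
replaced by the identity, so no neighborhood information flows; with I
alone, `H` is a learnable projection of one-hot node identities (the
standard featureless-GCN convention). The full S+M+I model is exactly
`H = G ⊕ S` with the GCN on `Ã`.

### Pair scoring and objective

`ŷ_ij = σ(MLP(z_i ⊙ z_j))` with a two-layer MLP (hidden width `d_g`,
ReLU); the elementwise product makes scores exactly symmetric. The
supervised loss is the summed binary cross-entropy over labeled pairs
(predictions clamped to `[1e−7, 1−1e−7]` as a log-guard), and the total
objective is `L = L_r + α L_c`.

## Training protocol

Positives are split 64/16/20 into train/validation/test, with an equal
number of negatives sampled uniformly without replacement from the
non-edges (no negative duplicated anywhere, none colliding with a
positive). Training is full-batch: one forward pass over all drugs, one
Adam step per epoch, learning rate `lr0 · decay^epoch`, Xavier
initialization, dropout 0.3 on intermediate atom/supernode/GCN states.
Validation AUROC is tracked every epoch; training stops after `patience`
epochs without improvement (default 30) or at `max_epochs` (default
300), and the best-validation parameters are restored
(`restore_best=False` keeps the final parameters, which the capacity
check needs). Supervised negatives are fixed at split time
(`resample_negatives=True` redraws them each epoch); contrastive
negatives are always resampled. With fixed seeds, float64 arithmetic
makes loss trajectories bitwise reproducible.

## Defaults and the small-benchmark configuration

Published defaults: `d_h = d_g = 256`, `K = 2`, `L_mol = 2`, `L_gcn = 3`,
`L_s = 150`, dropout 0.3, `lr0 = 1e−4` with decay 0.96 per epoch,
`α = 0.9`. These are tuned for corpora with tens of thousands of labeled
links.

The synthetic benchmark used by the test suite and the acceptance script
is orders of magnitude smaller (20 drugs, ~60 interactions, ~40 labeled
training pairs), and full-batch training takes a single optimizer step
per epoch, so the default schedule's total step budget
(`lr0/(1−decay) ≈ 2.5e−3`) cannot fit a model from scratch at this
scale. `ModelConfig.small_benchmark` therefore narrows the width to
`d_h = d_g = 32` and warms/flattens the schedule (`lr0 = 3e−3`, decay
0.997, up to 400 epochs, patience 80). This is a problem-size choice:
all architectural switches keep their defaults, and nothing else
changes.

## Synthetic data: what it emulates and what it does not

`generate_synthetic(n_drugs, n_communities, p_in, p_out, seed)` draws a
planted-partition interaction graph (within-community edge probability
`p_in`, between `p_out`) over drugs with valid SMILES. Each community is
assigned a small disjoint family of scaffolds from a built-in library of
100 drug-like molecules, and its drugs are random substituent-decorated
variants of those scaffolds (duplicate molecules are avoided where the
pool allows). This mirrors two robust properties of real DDI data:
interaction neighborhoods are informative, and interaction communities
are chemically coherent, so all three feature channels carry signal.

It does *not* emulate: realistic degree distributions or interaction
mechanisms, pharmacological interaction types, molecule sizes beyond the
library's range (~1–22 heavy atoms), or annotation noise. Passing the
behavioral checks therefore demonstrates that the implementation can
extract planted structure through every channel — not that it attains
any particular accuracy on real corpora.

Note a ranking ceiling inherent to the design: at `p_in = 0.6`, 40% of
within-community pairs are true non-edges and are statistically
indistinguishable from held-out edges, which caps expected test AUROC
near ~0.82 on the 20-drug benchmark; observed values (~0.74–0.95 per
seed) sit around this ceiling with small-sample noise (24 test pairs).

## Numerical and implementation choices

- All computation is float64 on a small in-repo reverse-mode autodiff
  core (`mffgnn.autodiff`): NumPy tensors, the exact operation set the
  model needs (including row-gather and segment-sum for batched graph
  message passing), Linear/GRU/Embedding layers and Adam.
- All molecules are encoded in one disjoint-union batch with per-molecule
  segment aggregation; per-molecule softmax uses a max-shift for
  stability. The BiGRU time loop runs to the batch's maximum valid
  length — masking makes later steps identities.
- Oracle tests compare against loop-based straight-line re-evaluations at
  1e−6 absolute tolerance (64-bit).
- Empty neighbor sums (isolated atoms) are the zero vector; single-atom
  molecules and edgeless graphs are handled throughout.
- AUROC uses the rank statistic with ties counted 1/2; AUPRC uses
  precision–recall step integration; F1 is computed at a fixed 0.5
  threshold (exposed as a flag).
- Ties in evaluation and all sampling are governed by explicit
  `numpy.random.Generator` seeds.

## Known limitations

- CPU-only and full-batch: fine up to a few thousand drugs, not tuned for
  the largest corpora; minibatched pair scoring is a config option but
  the encoders always run over all drugs.
- The Smi2Vec-style pre-trained token dictionary is replaced by a
  trainable embedding table (a loading hook accepts a user-supplied
  dictionary file).
- Single interaction type only; multi-type DDI event prediction is out of
  scope.
- Cross-dataset transfer re-fits nothing on the target dataset and maps
  unseen tokens to the unknown id; drug-count-dependent parameters (the
  identity projection of the I-only ablation) do not transfer.
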