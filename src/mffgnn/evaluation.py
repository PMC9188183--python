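"""Metrics and evaluation protocols.

AUROC (rank statistic, ties at 0.5), AUPRC (precision-recall step
integration) and F1 at a fixed 0.5 threshold, plus the evaluation
protocols: in-dataset test evaluation of a trained model, repeated runs
with mean +/- sd aggregation, cross-dataset transfer with a shared token
vocabulary, and hyperparameter sweeps emitting a tidy table.
"""

from __future__ import annotations

import itertools
from dataclasses import asdict, dataclass

import numpy as np
import pandas as pd
from sklearn.metrics import (average_precision_score, f1_score,
                             roc_auc_score)

from .config import ModelConfig
from .data import (InteractionDataset, SplitBundle, build_dataset,
                   fit_vocabulary, make_splits, sample_negative_pairs,
                   tokenize_smiles)
from .training import (MFFGNNModel, _adjacency_from_pairs, score_pairs,
                       train)

__all__ = ["MetricsReport", "compute_metrics", "evaluate_checkpoint",
           "repeat_evaluate", "cross_dataset_eval", "run_sweep"]


@dataclass
class MetricsReport:
    auroc: float
    auprc: float
    f1: float
    n_pos: int
    n_neg: int
    threshold: float
    seed: int

    def to_dict(self) -> dict:
        return asdict(self)


def compute_metrics(scores: np.ndarray, labels: np.ndarray,
                    threshold: float = 0.5, seed: int = 0) -> MetricsReport:
    """Threshold-free AUROC/AUPRC plus F1 at `threshold`.

    Raises on single-class label vectors (the metrics are undefined).
    """
    scores = np.asarray(scores, dtype=np.float64)
    labels = np.asarray(labels)
    n_pos = int((labels == 1).sum())
    n_neg = int((labels == 0).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("need at least one positive and one negative label")
    return MetricsReport(
        auroc=float(roc_auc_score(labels, scores)),
        auprc=float(average_precision_score(labels, scores)),
        f1=float(f1_score(labels, (scores >= threshold).astype(int))),
        n_pos=n_pos, n_neg=n_neg, threshold=threshold, seed=seed)


def evaluate_checkpoint(model: MFFGNNModel, dataset: InteractionDataset,
                        splits: SplitBundle, partition: str = "test",
                        threshold: float = 0.5) -> MetricsReport:
    """Score a partition's labeled pairs with a trained model.

    Message passing uses the training-positive adjacency only, so held-out
    edges never leak into the encoder.  Deterministic given model + splits.
    """
    pos, neg = splits.partition(partition)
    if not pos or not neg:
        raise ValueError(f"partition {partition!r} is empty")
    A_train = _adjacency_from_pairs(splits.train_pos, dataset.n_drugs)
    _, Z = model.forward(dataset, A_train, training=False)
    pairs = np.array(pos + neg, dtype=np.intp)
    labels = np.array([1] * len(pos) + [0] * len(neg))
    scores = score_pairs(Z, pairs, model).data
    return compute_metrics(scores, labels, threshold=threshold,
                           seed=splits.seed)


def repeat_evaluate(dataset: InteractionDataset, config: ModelConfig,
                    seeds: list[int], resplit: bool = True
                    ) -> tuple[pd.DataFrame, dict]:
    """Train/evaluate once per seed and aggregate mean +/- sd.

    With ``resplit=True`` both the split and the initialization are
    re-randomized per seed; otherwise the split of the first seed is
    reused and only the initialization varies.
    """
    base_splits = make_splits(dataset, seeds[0])
    rows = []
    for s in seeds:
        splits = make_splits(dataset, s) if resplit else base_splits
        cfg = ModelConfig.from_dict({**config.to_dict(), "seed": s})
        model, _ = train(dataset, splits, cfg)
        rep = evaluate_checkpoint(model, dataset, splits)
        rows.append({"seed": s, **rep.to_dict()})
    df = pd.DataFrame(rows)
    summary = {m: {"mean": float(df[m].mean()), "sd": float(df[m].std(ddof=1))
                   if len(df) > 1 else 0.0}
               for m in ("auroc", "auprc", "f1")}
    return df, summary


def cross_dataset_eval(train_dataset: InteractionDataset,
                       test_datasets: list[InteractionDataset],
                       config: ModelConfig, seed: int
                       ) -> list[MetricsReport]:
    """Train on one dataset, evaluate zero-shot on the others.

    A shared token vocabulary is fitted on the union of all datasets'
    SMILES; tokens unseen at vocabulary-fit time map to the dedicated
    unknown id.  Each test dataset is scored on all its positive pairs
    plus matched sampled negatives, using its own adjacency for message
    passing.
    """
    if not test_datasets:
        raise ValueError("need at least one test dataset")
    all_ds = [train_dataset] + list(test_datasets)
    corpus = [tokenize_smiles(d.smiles) for ds in all_ds for d in ds.drugs]
    shared_vocab = fit_vocabulary(corpus)

    def rebuild(ds: InteractionDataset) -> InteractionDataset:
        records = [(d.drug_id, d.smiles) for d in ds.drugs]
        pairs = [(ds.drugs[i].drug_id, ds.drugs[j].drug_id)
                 for i, j in sorted(ds.positive_pairs)]
        return build_dataset(records, pairs, L_s=config.L_s,
                             vocab=shared_vocab)

    train_ds = rebuild(train_dataset)
    splits = make_splits(train_ds, seed)
    cfg = ModelConfig.from_dict({**config.to_dict(), "seed": seed})
    model, _ = train(train_ds, splits, cfg)

    reports = []
    for k, raw in enumerate(test_datasets):
        ds = rebuild(raw)
        rng = np.random.default_rng((seed + 1000 * (k + 1)) % 2**31)
        pos = sorted(ds.positive_pairs)
        neg = sample_negative_pairs(ds.adjacency, len(pos), rng)
        model_t = MFFGNNModel(model.config, shared_vocab, ds.n_drugs)
        _transfer_parameters(model, model_t)
        _, Z = model_t.forward(ds, ds.adjacency, training=False)
        pairs = np.array(pos + neg, dtype=np.intp)
        labels = np.array([1] * len(pos) + [0] * len(neg))
        scores = score_pairs(Z, pairs, model_t).data
        reports.append(compute_metrics(scores, labels, seed=seed))
    return reports


def _transfer_parameters(src: MFFGNNModel, dst: MFFGNNModel) -> None:
    """Copy all shared (non-dataset-sized) parameters from src to dst."""
    from .training import _all_parameters
    for p_src, p_dst in zip(_all_parameters(src), _all_parameters(dst)):
        if p_src.data.shape == p_dst.data.shape:
            p_dst.data = p_src.data.copy()


def run_sweep(grid: dict[str, list], dataset: InteractionDataset,
              base_config: ModelConfig, seed: int) -> pd.DataFrame:
    """Train + evaluate once per grid point ('vary one knob, fix the
    rest' generalized to a full product grid); returns a tidy table."""
    keys = sorted(grid)
    rows = []
    for values in itertools.product(*(grid[k] for k in keys)):
        overrides = dict(zip(keys, values))
        cfg = ModelConfig.from_dict(
            {**base_config.to_dict(), **overrides, "seed": seed})
        splits = make_splits(dataset, seed)
        model, _ = train(dataset, splits, cfg)
        rep = evaluate_checkpoint(model, dataset, splits)
        rows.append({**overrides, "seed": seed, **rep.to_dict()})
    return pd.DataFrame(rows)
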