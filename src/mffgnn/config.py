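"""Model configuration: every hyperparameter and ablation switch in one record.

Defaults follow the published MFFGNN settings: 256-dimensional atom- and
drug-level representations, K=2 attention heads, sequence length 150,
dropout 0.3, Adam with initial learning rate 1e-4 decayed by 0.96 per
epoch, and contrastive weight alpha = 0.9.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path

import yaml

logger = logging.getLogger("mffgnn")

VALID_FEATURES = {"S", "M", "I"}


@dataclass
class ModelConfig:
    """Hyperparameters and ablation switches for the full pipeline.

    feature_set: which drug information enters the fusion module —
    "S" (SMILES sequence), "M" (molecular graph), "I" (interaction network).
    """

    d_h: int = 256          # atom / bond / token hidden dim
    d_g: int = 256          # drug representation dim
    K: int = 2              # attention heads in the transmitter
    L_mol: int = 2          # molecular-encoder layers
    L_gcn: int = 3          # fusion GCN layers
    L_s: int = 150          # fixed SMILES token-sequence length
    dropout: float = 0.3
    lr0: float = 1e-4
    lr_decay: float = 0.96  # multiplicative, per epoch
    alpha: float = 0.9      # contrastive-loss weight
    use_gwu: bool = True
    use_gating: bool = True
    use_contrastive: bool = True
    feature_set: frozenset = field(default_factory=lambda: frozenset({"S", "M", "I"}))
    max_epochs: int = 300
    patience: int = 30
    restore_best: bool = True   # restore best-validation parameters after training
    resample_negatives: bool = False  # resample supervised negatives per epoch
    seed: int = 0

    def __post_init__(self):
        if isinstance(self.feature_set, str):
            self.feature_set = frozenset(
                f.strip() for f in self.feature_set.split(",") if f.strip())
        else:
            self.feature_set = frozenset(self.feature_set)
        if not self.feature_set:
            raise ValueError("feature_set must be non-empty")
        unknown = self.feature_set - VALID_FEATURES
        if unknown:
            raise ValueError(f"unknown feature flags: {sorted(unknown)}")
        if not (0.0 <= self.dropout < 1.0):
            raise ValueError("dropout must be in [0, 1)")
        if self.alpha < 0:
            raise ValueError("alpha must be >= 0")
        if self.L_s < 1:
            raise ValueError("L_s must be >= 1")
        for name in ("d_h", "d_g", "K", "L_mol", "L_gcn", "max_epochs"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["feature_set"] = ",".join(sorted(self.feature_set))
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "ModelConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)

    @classmethod
    def small_benchmark(cls, seed: int = 0, **overrides) -> "ModelConfig":
        """Configuration for the package's small synthetic benchmark.

        Desk-scale planted-partition datasets (tens of drugs, tens of
        labeled pairs) are orders of magnitude smaller than public DDI
        corpora, so the benchmark uses a narrower width and a warmer,
        flatter learning-rate schedule than the publication defaults —
        full-batch training takes one optimizer step per epoch, and the
        default schedule's total step budget (lr0 / (1 - decay)) is far
        too small to fit from scratch at this scale.  All architectural
        switches keep their defaults.
        """
        base = dict(d_h=32, d_g=32, lr0=3e-3, lr_decay=0.997,
                    max_epochs=400, patience=80, seed=seed)
        base.update(overrides)
        return cls(**base)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "ModelConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        if not isinstance(data, dict):
            raise ValueError("config file must be a flat key-value mapping")
        return cls.from_dict(data)
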