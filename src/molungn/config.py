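"""Run configuration.

Defaults mirror the published hyperparameter table for the model: 200 epochs,
learning rate 0.008, 32 attention heads, 16 hidden dimensions, a 128-unit
fusion layer, loss trade-off delta = 1, and the 70/30 x 10 evaluation
protocol.  Everything else (graph density, feature-selection caps, dropout,
filter thresholds) is exposed here so ablations are plain config edits.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, replace
from pathlib import Path
from typing import Sequence

import yaml


@dataclass
class RunConfig:
    # optimization
    num_epochs: int = 200
    learning_rate: float = 0.008
    pretrain_epochs: int = 0
    # architecture
    num_heads: int = 32
    hidden_dims: int = 16
    vcdn_features: int = 128
    attention_layers: int = 2
    fc_dims: tuple[int, int] = (128, 64)
    dropout: float = 0.5
    leaky_slope: float = 0.2
    # loss
    delta: float = 1.0
    # evaluation protocol
    train_fraction: float = 0.7
    num_repeats: int = 10
    # graph
    avg_degree: float = 10.0
    graph_mode: str = "transductive"
    # preprocessing
    feature_cap: int = 5000
    feature_fraction: float = 0.25
    max_zero_fraction: float = 0.2
    max_missing_fraction: float = 0.2
    # numerics: float32 is the training dtype (standard for deep nets);
    # float64 available for high-precision checks
    compute_dtype: str = "float32"
    # run
    seed: int = 0
    views: Sequence[str] | None = None
    use_vcdn: bool = True

    def __post_init__(self):
        if self.num_epochs < 0:
            raise ValueError("num_epochs must be nonnegative")
        if self.learning_rate < 0:
            raise ValueError("learning_rate must be nonnegative")
        for name in ("num_heads", "hidden_dims", "vcdn_features",
                     "attention_layers", "num_repeats", "feature_cap"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be a positive integer")
        if not 0.0 < self.train_fraction < 1.0:
            raise ValueError("train_fraction must lie in (0, 1)")
        if not 0.0 < self.feature_fraction <= 1.0:
            raise ValueError("feature_fraction must lie in (0, 1]")
        if self.delta < 0:
            raise ValueError("delta must be nonnegative")
        if self.avg_degree <= 0:
            raise ValueError("avg_degree must be positive")
        if self.graph_mode not in ("transductive", "inductive"):
            raise ValueError("graph_mode must be 'transductive' or 'inductive'")
        if not 0.0 <= self.dropout < 1.0:
            raise ValueError("dropout must lie in [0, 1)")
        if self.compute_dtype not in ("float32", "float64"):
            raise ValueError("compute_dtype must be float32 or float64")
        self.fc_dims = tuple(int(d) for d in self.fc_dims)
        if self.views is not None:
            self.views = tuple(self.views)

    # -- serialization ----------------------------------------------------
    def to_dict(self) -> dict:
        d = asdict(self)
        d["fc_dims"] = list(self.fc_dims)
        if self.views is not None:
            d["views"] = list(self.views)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()) or {})

    def updated(self, **kwargs) -> "RunConfig":
        return replace(self, **kwargs)
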