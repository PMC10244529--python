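"""Training configuration.

Defaults follow the published recipe: AdamW with initial learning rate 1e-3,
batch size 64, dropout 0.2, and a plateau learning-rate decay with factor 0.1
("learning factor"); grid 3×3, four cross-attention heads, separable
3×3/1×3/3×1 kernels.  Module toggles reproduce the ablation variants A–E.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field

import yaml

from .model import ModelConfig

__all__ = ["TrainConfig", "load_config", "save_config"]


@dataclass
class TrainConfig:
    # optimisation
    optimizer: str = "adamw"
    lr: float = 1e-3
    weight_decay: float = 1e-2
    lr_decay_factor: float = 0.1
    plateau_patience: int = 3
    batch_size: int = 64
    epochs: int = 10
    seed: int = 0
    # loss
    loss_eps: float = 1e-6
    use_partition: bool = True
    # data
    image_size: int = 224
    # model
    model: ModelConfig = field(default_factory=ModelConfig)

    def __post_init__(self):
        if self.lr <= 0:
            raise ValueError("lr must be positive")
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "TrainConfig":
        d = dict(d)
        model = d.pop("model", {})
        return cls(model=ModelConfig(**model), **d)


def load_config(path) -> TrainConfig:
    with open(path) as fh:
        return TrainConfig.from_dict(yaml.safe_load(fh) or {})


def save_config(cfg: TrainConfig, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(cfg.to_dict(), fh, sort_keys=False)
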