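"""The full hybrid multi-head cross-attention network (HMHN).

Pipeline:  image g → [GWA grid re-weighting] → [DFF fusion of g and g̃] →
ResNet-18 trunk (no head) → [k cross-attention heads] → AFB fusion →
BDI-II score.  Every attention stage can be toggled off, reproducing the
ablation variants:

    A  backbone only                 (use_gwa=False, use_dff=False, use_mab=False)
    B  backbone + GWA                (use_gwa=True,  use_dff=False, use_mab=False)
    C  backbone + GWA + DFF          (use_gwa=True,  use_dff=True,  use_mab=False)
    D  backbone + MAB + AFB          (use_gwa=False, use_dff=False, use_mab=True)
    E  full model                    (all True)

When DFF is disabled but GWA is enabled, the weighted image feeds the
backbone directly; when both are disabled the raw image does.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import nn
from .backbone import DFFBlock, ResNet18Backbone
from .fusion import AFBBlock, total_loss_t
from .gwa import GWABlock, LGFEConfig
from .heads import HeadConfig, MABBlock
from .nn.tensor import Tensor

__all__ = ["ModelConfig", "HMHN", "ABLATION_VARIANTS", "build_model"]

ABLATION_VARIANTS = {
    "A": dict(use_gwa=False, use_dff=False, use_mab=False),
    "B": dict(use_gwa=True, use_dff=False, use_mab=False),
    "C": dict(use_gwa=True, use_dff=True, use_mab=False),
    "D": dict(use_gwa=False, use_dff=False, use_mab=True),
    "E": dict(use_gwa=True, use_dff=True, use_mab=True),
}


@dataclass
class ModelConfig:
    in_channels: int = 3
    grid_h: int = 3
    grid_w: int = 3
    lgfe_expansion: int = 4
    pad_policy: str = "reflect"
    ft_hidden: int = 16
    num_heads: int = 4
    kernel_config: str = "k313"
    reduce_channels: int = 256
    mid1: int = 233
    mid2: int = 1712
    dropout: float = 0.2
    fusion: str = "mean"
    use_gwa: bool = True
    use_dff: bool = True
    use_mab: bool = True

    def head_config(self) -> HeadConfig:
        return HeadConfig(self.num_heads, self.kernel_config,
                          self.reduce_channels, self.mid1, self.mid2)


class HMHN(nn.Module):
    def __init__(self, cfg: ModelConfig = ModelConfig()):
        super().__init__()
        self.cfg = cfg
        if cfg.use_gwa:
            self.gwa = GWABlock(cfg.in_channels, cfg.grid_h, cfg.grid_w,
                                LGFEConfig(cfg.lgfe_expansion), cfg.pad_policy)
        if cfg.use_dff:
            self.dff = DFFBlock(cfg.in_channels, cfg.ft_hidden)
        self.backbone = ResNet18Backbone(cfg.in_channels)
        if cfg.use_mab:
            self.mab = MABBlock(self.backbone.out_channels, cfg.head_config())
        self.afb = AFBBlock(self.backbone.out_channels,
                            cfg.num_heads if cfg.use_mab else 1,
                            cfg.dropout, cfg.fusion)

    def features(self, g: Tensor) -> tuple:
        """Returns (head_outputs, backbone_features)."""
        x = g
        if self.cfg.use_gwa:
            x = self.gwa(g)
        if self.cfg.use_dff:
            x = self.dff(g, x)
        feats = self.backbone(x)
        heads = self.mab(feats) if self.cfg.use_mab else [feats]
        return heads, feats

    def forward(self, g: Tensor) -> tuple:
        """Returns (scores (N,), head_outputs)."""
        heads, _ = self.features(g)
        return self.afb(heads), heads

    def predict_scores(self, images: np.ndarray) -> np.ndarray:
        """Eval-mode scores for a (N, C, H, W) float array."""
        was_training = self.training
        self.eval()
        with nn.no_grad():
            scores, _ = self(Tensor(np.asarray(images, dtype=np.float32)))
        if was_training:
            self.train()
        return scores.numpy().astype(np.float64)

    def loss(self, g: Tensor, truth: Tensor, eps: float = 1e-6,
             use_partition: bool = True) -> tuple:
        """(l_sum, l_mse, l_att) tensors for a training batch."""
        scores, heads = self(g)
        return total_loss_t(scores, truth, heads if self.cfg.use_mab else None,
                            eps, use_partition)


def build_model(cfg: ModelConfig | None = None, seed: int | None = None,
                variant: str | None = None) -> HMHN:
    """Construct an HMHN; ``variant`` selects an ablation row (A–E)."""
    cfg = cfg or ModelConfig()
    if variant is not None:
        if variant not in ABLATION_VARIANTS:
            raise ValueError(f"variant must be one of {sorted(ABLATION_VARIANTS)}")
        cfg = ModelConfig(**{**cfg.__dict__, **ABLATION_VARIANTS[variant]})
    if seed is not None:
        nn.manual_seed(seed)
    return HMHN(cfg)
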