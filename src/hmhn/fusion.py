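"""Attention fusion block (AFB): head fusion, score regression, and the
joint training objective.

The ``k`` head outputs are merged (element-wise mean by default) and reduced
to a single scalar per sample by global average pooling, dropout and one
linear layer — the predicted BDI-II depression score.  Training minimises

    L_sum = L_att + L_mse

where ``L_mse`` is the squared regression error and ``L_att`` is the
*partition loss*: with σ²_ij the variance across the k heads of the globally
pooled channel-j activation of sample i,

    L_att = (1/NC) Σ_ij log(1 + k / (σ²_ij + eps)).

The loss is strictly decreasing in every σ²_ij, so minimising it pushes the
heads' pooled channel profiles apart — each head is driven to attend to a
different facial region instead of collapsing onto one.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import nn
from .nn import functional as F
from .nn.tensor import Tensor, stack

__all__ = ["LossBundle", "AFBBlock", "fuse_heads", "regress_score",
           "partition_loss", "total_loss"]


@dataclass
class LossBundle:
    """Scalar loss triple with its bookkeeping; ``l_sum = l_att + l_mse``
    exactly (a float sum, not a re-derivation)."""

    l_mse: float
    l_att: float
    l_sum: float
    n: int
    channels: int
    num_heads: int
    sigma_sq: np.ndarray    # (N, C) per-sample per-channel variance across heads


def _pooled_head_matrix(heads: list) -> Tensor:
    """Stack globally pooled head outputs: (k, N, C)."""
    return stack([F.global_avg_pool(h) for h in heads], axis=0)


def partition_loss_t(heads: list, eps: float = 1e-6) -> Tensor:
    """Differentiable partition loss over a list of (N, C, H, W) head maps."""
    k = len(heads)
    if k < 2:
        return Tensor(np.zeros((), dtype=np.float32))
    pooled = _pooled_head_matrix(heads)              # (k, N, C)
    sigma_sq = pooled.var(axis=0)                    # population variance, (N, C)
    return ((sigma_sq + eps) ** -1.0 * float(k) + 1.0).log().mean()


class AFBBlock(nn.Module):
    """Head fusion + regression output layer.

    ``fusion`` is ``"mean"`` (default) or ``"concat"`` (channel concatenation
    followed by a 1×1 convolution back to the feature width).
    """

    def __init__(self, in_channels: int = 512, num_heads: int = 4,
                 dropout_rate: float = 0.2, fusion: str = "mean"):
        super().__init__()
        if fusion not in ("mean", "concat"):
            raise ValueError("fusion must be 'mean' or 'concat'")
        self.fusion = fusion
        self.dropout = nn.Dropout(dropout_rate)
        if fusion == "concat":
            self.mix = nn.Conv2d(in_channels * num_heads, in_channels, 1)
        self.fc = nn.Linear(in_channels, 1)
        # Zero-init the regression output layer: the initial prediction is then
        # exactly the bias, so early optimisation grows the weights toward the
        # pooled features instead of collapsing the attention gates to lift a
        # randomly signed initial score.
        self.fc.weight.data[...] = 0.0
        self.fc.bias.data[...] = 0.0

    def fuse(self, heads: list) -> Tensor:
        if len(heads) == 0:
            raise ValueError("need at least one head output")
        if self.fusion == "concat" and len(heads) > 1:
            n, c = heads[0].shape[0], heads[0].shape[1]
            cat = stack(heads, axis=2).reshape(n, len(heads) * c, *heads[0].shape[2:])
            return self.mix(cat)
        out = heads[0]
        for h in heads[1:]:
            out = out + h
        return out * (1.0 / len(heads))

    def forward(self, heads: list) -> Tensor:
        fused = self.fuse(heads)
        v = self.dropout(F.global_avg_pool(fused))
        return self.fc(v).reshape(fused.shape[0])   # (N,) scores


# -- numpy-facing API -------------------------------------------------------

def fuse_heads(heads: list) -> np.ndarray:
    """Element-wise mean of the head maps (the default fusion)."""
    if len(heads) == 0:
        raise ValueError("need at least one head output")
    return np.mean([np.asarray(h, dtype=np.float64) for h in heads], axis=0)


def regress_score(fused: np.ndarray, afb: AFBBlock) -> np.ndarray:
    """Pool + dropout (train mode only) + linear → one score per sample."""
    arr = np.asarray(fused, dtype=np.float32)
    single = arr.ndim == 3
    if single:
        arr = arr[None]
    v = afb.dropout(F.global_avg_pool(Tensor(arr)))
    out = afb.fc(v).numpy().reshape(-1)
    return float(out[0]) if single else out


def partition_loss(heads: list, eps: float = 1e-6) -> float:
    """Partition loss on numpy head maps (batch (N,C,H,W) or single (C,H,W))."""
    arrs = []
    for h in heads:
        a = np.asarray(h, dtype=np.float64)
        if not np.all(np.isfinite(a)):
            raise ValueError("non-finite head activations")
        arrs.append(a[None] if a.ndim == 3 else a)
    return float(partition_loss_t([Tensor(a) for a in arrs], eps).item())


def total_loss(pred, truth, heads: list | None = None, eps: float = 1e-6,
               use_partition: bool = True) -> LossBundle:
    """Joint objective on numpy inputs; ``heads`` may be omitted (L_att = 0)."""
    pred = np.asarray(pred, dtype=np.float64).reshape(-1)
    truth = np.asarray(truth, dtype=np.float64).reshape(-1)
    if pred.shape != truth.shape:
        raise ValueError(f"length mismatch: {pred.shape} vs {truth.shape}")
    l_mse = float(np.mean((pred - truth) ** 2))
    if heads and use_partition and len(heads) >= 2:
        arrs = [np.asarray(h, dtype=np.float64) for h in heads]
        arrs = [a[None] if a.ndim == 3 else a for a in arrs]
        pooled = np.stack([a.mean(axis=(-2, -1)) for a in arrs])   # (k, N, C)
        sigma_sq = pooled.var(axis=0)
        k = len(arrs)
        l_att = float(np.mean(np.log1p(k / (sigma_sq + eps))))
        n, c = sigma_sq.shape
    else:
        l_att, sigma_sq = 0.0, np.zeros((len(pred), 0))
        k = len(heads) if heads else 0
        n, c = len(pred), 0
    return LossBundle(l_mse=l_mse, l_att=l_att, l_sum=l_att + l_mse,
                      n=n, channels=c, num_heads=k, sigma_sq=sigma_sq)


def total_loss_t(pred: Tensor, truth: Tensor, heads: list | None,
                 eps: float = 1e-6, use_partition: bool = True) -> tuple:
    """Differentiable joint objective; returns (l_sum, l_mse, l_att) tensors."""
    diff = pred - truth
    l_mse = (diff * diff).mean()
    if heads and use_partition and len(heads) >= 2:
        l_att = partition_loss_t(heads, eps)
    else:
        l_att = Tensor(np.zeros((), dtype=np.float32))
    return l_mse + l_att, l_mse, l_att
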