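"""Deep feature fusion (DFF) and the ResNet-18 trunk.

Two structurally identical but independently parameterised feature
transformation networks (FT1, FT2) map the raw image ``g`` and the
grid-attention-weighted image ``g̃`` into a common space; their sum passes
through a small fusion network and then a ResNet-18 whose average pooling,
flattening and fully connected head have been removed, yielding a
512×(H/32)×(W/32) feature map.  All weights are trained from scratch — the
framework is trained end to end rather than fine-tuned from a pretrained
classifier.
"""

from __future__ import annotations

import numpy as np

from . import nn
from .nn import functional as F
from .nn.tensor import Tensor

__all__ = ["FTNet", "DFFBlock", "ResNet18Backbone", "ft_forward", "dff_fuse",
           "backbone_forward"]


class FTNet(nn.Module):
    """Shape-preserving feature transformation:
    conv3×3 (C→hidden) → BN → LeakyReLU → conv3×3 (hidden→C) → BN → LeakyReLU."""

    def __init__(self, channels: int = 3, hidden: int = 16):
        super().__init__()
        self.net = nn.Sequential(
            nn.Conv2d(channels, hidden, 3, padding=1),
            nn.BatchNorm2d(hidden),
            nn.LeakyReLU(),
            nn.Conv2d(hidden, channels, 3, padding=1),
            nn.BatchNorm2d(channels),
            nn.LeakyReLU(),
        )

    def forward(self, x: Tensor) -> Tensor:
        return self.net(x)


class DFFBlock(nn.Module):
    """Fusion of raw and attention-weighted images.

    ``forward(g, g_tilde)`` computes ``fusion(FT1(g) + FT2(g_tilde))`` where
    the fusion network is conv1×1 → BN → LeakyReLU, shape-preserving so the
    result can feed the backbone directly.
    """

    def __init__(self, channels: int = 3, ft_hidden: int = 16):
        super().__init__()
        self.ft1 = FTNet(channels, ft_hidden)
        self.ft2 = FTNet(channels, ft_hidden)
        self.fusion = nn.Sequential(
            nn.Conv2d(channels, channels, 1),
            nn.BatchNorm2d(channels),
            nn.LeakyReLU(),
        )

    def ft(self, x: Tensor, which: int) -> Tensor:
        if which not in (1, 2):
            raise ValueError("which must be 1 or 2")
        return (self.ft1 if which == 1 else self.ft2)(x)

    def forward(self, g: Tensor, g_tilde: Tensor) -> Tensor:
        if g.shape != g_tilde.shape:
            raise ValueError(f"shape mismatch: {g.shape} vs {g_tilde.shape}")
        return self.fusion(self.ft(g, 1) + self.ft(g_tilde, 2))


class _BasicBlock(nn.Module):
    def __init__(self, in_ch: int, out_ch: int, stride: int = 1):
        super().__init__()
        self.conv1 = nn.Conv2d(in_ch, out_ch, 3, stride=stride, padding=1, bias=False)
        self.bn1 = nn.BatchNorm2d(out_ch)
        self.conv2 = nn.Conv2d(out_ch, out_ch, 3, padding=1, bias=False)
        self.bn2 = nn.BatchNorm2d(out_ch)
        if stride != 1 or in_ch != out_ch:
            self.down_conv = nn.Conv2d(in_ch, out_ch, 1, stride=stride, bias=False)
            self.down_bn = nn.BatchNorm2d(out_ch)
            self._has_down = True
        else:
            self._has_down = False

    def forward(self, x: Tensor) -> Tensor:
        out = F.relu(self.bn1(self.conv1(x)))
        out = self.bn2(self.conv2(out))
        identity = self.down_bn(self.down_conv(x)) if self._has_down else x
        return F.relu(out + identity)


class ResNet18Backbone(nn.Module):
    """ResNet-18 with the average pooling, flattening and fully connected
    layers removed: stem (7×7/2 conv + 3×3/2 max pool) and four two-block
    stages at widths 64/128/256/512.  224×224 input → 512×7×7 output
    (spatial downsampling by 32)."""

    out_channels = 512

    def __init__(self, in_channels: int = 3):
        super().__init__()
        self.conv1 = nn.Conv2d(in_channels, 64, 7, stride=2, padding=3, bias=False)
        self.bn1 = nn.BatchNorm2d(64)
        self.maxpool = nn.MaxPool2d(3, stride=2, padding=1)
        self.layer1 = nn.Sequential(_BasicBlock(64, 64), _BasicBlock(64, 64))
        self.layer2 = nn.Sequential(_BasicBlock(64, 128, 2), _BasicBlock(128, 128))
        self.layer3 = nn.Sequential(_BasicBlock(128, 256, 2), _BasicBlock(256, 256))
        self.layer4 = nn.Sequential(_BasicBlock(256, 512, 2), _BasicBlock(512, 512))

    def forward(self, x: Tensor) -> Tensor:
        x = self.maxpool(F.relu(self.bn1(self.conv1(x))))
        x = self.layer1(x)
        x = self.layer2(x)
        x = self.layer3(x)
        return self.layer4(x)


# -- numpy-facing helpers ---------------------------------------------------

def ft_forward(x: np.ndarray, dff: DFFBlock, which: int) -> np.ndarray:
    """Run FT1 or FT2 on a (C, H, W) image or (N, C, H, W) batch."""
    arr = np.asarray(x, dtype=np.float32)
    single = arr.ndim == 3
    if single:
        arr = arr[None]
    out = dff.ft(Tensor(arr), which).numpy()
    return out[0] if single else out


def dff_fuse(g: np.ndarray, g_tilde: np.ndarray, dff: DFFBlock) -> np.ndarray:
    """Fuse raw and weighted images through the DFF block (numpy in/out)."""
    ga = np.asarray(g, dtype=np.float32)
    gt = np.asarray(g_tilde, dtype=np.float32)
    single = ga.ndim == 3
    if single:
        ga, gt = ga[None], gt[None]
    out = dff(Tensor(ga), Tensor(gt)).numpy()
    return out[0] if single else out


def backbone_forward(x: np.ndarray, backbone: ResNet18Backbone) -> np.ndarray:
    arr = np.asarray(x, dtype=np.float32)
    single = arr.ndim == 3
    if single:
        arr = arr[None]
    out = backbone(Tensor(arr)).numpy()
    return out[0] if single else out
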