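"""Grid-wise attention (GWA): low-level re-weighting of a facial image.

The image is split into an ``h``×``w`` lattice of grids; a small shared
bottleneck network (local grid feature extraction, LGFE) embeds each grid; a
scaled dot-product attention score is computed per grid and channel; adaptive
average pooling squeezes each attention matrix to a scalar importance weight,
which is broadcast back over its grid block and multiplied into the original
image.  The result has the same shape as the input and emphasises grid cells
whose local structure is informative, giving the downstream convolutional
backbone access to long-range relationships between facial regions (mouth,
eyes, brows) that plain local convolutions cannot see at this depth.

Functional operations (``partition_grid`` … ``ungrid_and_weight``) accept and
return plain numpy arrays; the trainable :class:`GWABlock` composes the same
computations on autograd tensors.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import nn
from .nn import functional as F
from .nn.tensor import Tensor

__all__ = [
    "GridSpec", "GridSet", "LGFEConfig", "LGFE", "GWABlock",
    "partition_grid", "lgfe_forward", "grid_attention", "squeeze_expand",
    "grid_weights", "ungrid_and_weight",
]


@dataclass(frozen=True)
class GridSpec:
    """Geometry of the grid partition of a ``C``×``H``×``W`` image.

    ``H`` and ``W`` are padded up to the smallest multiples of ``h`` and ``w``;
    ``pad_policy`` is ``"reflect"`` (default, preserves border statistics) or
    ``"zero"``.
    """

    h: int
    w: int
    H: int
    W: int
    C: int
    pad_policy: str = "reflect"

    def __post_init__(self):
        if self.h < 1 or self.w < 1:
            raise ValueError("grid dimensions h, w must be >= 1")
        if self.h > self.H or self.w > self.W:
            raise ValueError("grid must not exceed image dimensions")
        if self.pad_policy not in ("reflect", "zero"):
            raise ValueError(f"unknown pad_policy {self.pad_policy!r}")

    @property
    def H_pad(self) -> int:
        return -(-self.H // self.h) * self.h

    @property
    def W_pad(self) -> int:
        return -(-self.W // self.w) * self.w

    @property
    def grid_h(self) -> int:
        """Rows per grid cell (H/h after padding)."""
        return self.H_pad // self.h

    @property
    def grid_w(self) -> int:
        """Columns per grid cell (W/w after padding)."""
        return self.W_pad // self.w

    @property
    def d_k(self) -> int:
        """Attention scaling dimension: the grid-cell width W/w."""
        return self.grid_w


@dataclass
class GridSet:
    """Row-major collection of the ``h*w`` grid cells of one image."""

    grids: np.ndarray                 # (h*w, C, grid_h, grid_w)
    origins: list = field(default_factory=list)   # [(i, j)] per grid
    spec: GridSpec | None = None


@dataclass(frozen=True)
class LGFEConfig:
    """LGFE bottleneck: hidden width = C * expansion."""

    expansion: int = 4

    def __post_init__(self):
        if self.expansion < 1:
            raise ValueError("expansion factor must be >= 1")


# ---------------------------------------------------------------------------
# tensor-level building blocks (shared by the functional API and GWABlock)
# ---------------------------------------------------------------------------

def _pad_to_grid(x: Tensor, spec: GridSpec) -> Tensor:
    pb = spec.H_pad - x.shape[-2]
    pr = spec.W_pad - x.shape[-1]
    return F.pad2d(x, (0, pb, 0, pr), "reflect" if spec.pad_policy == "reflect" else "zero")


def _partition(x: Tensor, spec: GridSpec) -> Tensor:
    """(..., C, H_pad, W_pad) -> (..., h*w, C, grid_h, grid_w), row-major."""
    lead = x.shape[:-3]
    C, p, q = spec.C, spec.grid_h, spec.grid_w
    x = x.reshape(*lead, C, spec.h, p, spec.w, q)
    n = len(lead)
    x = x.transpose(*range(n), n + 1, n + 3, n, n + 2, n + 4)   # (..., h, w, C, p, q)
    return x.reshape(*lead, spec.h * spec.w, C, p, q)


def _ungrid(g: Tensor, spec: GridSpec) -> Tensor:
    """Inverse of :func:`_partition`: (..., h*w, C, p, q) -> (..., C, H_pad, W_pad)."""
    lead = g.shape[:-4]
    C, p, q = spec.C, spec.grid_h, spec.grid_w
    g = g.reshape(*lead, spec.h, spec.w, C, p, q)
    n = len(lead)
    g = g.transpose(*range(n), n + 2, n, n + 3, n + 1, n + 4)   # (..., C, h, p, w, q)
    return g.reshape(*lead, C, spec.H_pad, spec.W_pad)


def _attention(feat: Tensor, spec: GridSpec) -> Tensor:
    """Scaled dot-product attention per grid and channel.

    ``feat``: (..., h*w, C, p, q); query is the feature map, key its spatial
    transpose, d_k the grid-cell width; softmax over the last axis gives a
    row-stochastic (p × p) map per grid/channel.
    """
    if spec.d_k <= 0:
        raise ValueError("grid-cell width d_k must be positive")
    q = feat
    k = feat.swapaxes(-1, -2)
    scores = (q @ k) * (1.0 / np.sqrt(spec.d_k))
    return F.softmax(scores, axis=-1)


def _squeeze(att: Tensor, spec: GridSpec) -> Tensor:
    """Adaptive average pooling of each matrix to a scalar, then broadcast
    onto an all-ones (p × q) block."""
    scal = att.mean(axis=(-2, -1), keepdims=True)          # (..., h*w, C, 1, 1)
    ones = Tensor(np.ones((spec.grid_h, spec.grid_w), dtype=scal.dtype))
    return scal * ones


def _grid_weights(feat: Tensor, spec: GridSpec) -> Tensor:
    """Per-grid, per-channel scalar weights broadcast to (p × q) blocks.

    The attention matrix is applied to the grid features (Att · q) and the
    attended map is squeezed to one scalar per grid and channel.  Pooling the
    row-stochastic attention matrix alone would give the constant 1/p for
    every grid — no discrimination and no gradient into the LGFE — so the
    scalar comes from the attended features instead.
    """
    att = _attention(feat, spec)
    return _squeeze(att @ feat, spec)


# ---------------------------------------------------------------------------
# functional (numpy-facing) API
# ---------------------------------------------------------------------------

def partition_grid(image: np.ndarray, spec: GridSpec) -> GridSet:
    """Split a ``C``×``H``×``W`` image into ``h*w`` grids (row-major), padding
    to multiples of the grid shape first."""
    image = np.asarray(image)
    if image.ndim != 3:
        raise ValueError(f"expected a 3-D C×H×W image, got ndim={image.ndim}")
    t = _partition(_pad_to_grid(Tensor(image), spec), spec)
    origins = [(i, j) for i in range(spec.h) for j in range(spec.w)]
    return GridSet(grids=t.numpy(), origins=origins, spec=spec)


def lgfe_forward(grids: GridSet, lgfe: "LGFE") -> np.ndarray:
    """Apply the shared LGFE network to every grid; shape is preserved."""
    g = np.asarray(grids.grids, dtype=np.float32)
    if g.shape[0] == 0:
        raise ValueError("empty grid set")
    out = lgfe(Tensor(g))
    return out.numpy()


def grid_attention(features: np.ndarray, spec: GridSpec) -> np.ndarray:
    """Attention maps (h*w, C, p, p); each row sums to one."""
    return _attention(Tensor(np.asarray(features)), spec).numpy()


def squeeze_expand(att: np.ndarray, spec: GridSpec) -> np.ndarray:
    """Per-(grid, channel) mean of the attention matrix broadcast to a
    (p × q) constant block."""
    return _squeeze(Tensor(np.asarray(att)), spec).numpy()


def grid_weights(features: np.ndarray, spec: GridSpec) -> np.ndarray:
    """Scalar grid/channel weights from LGFE features: attention applied to
    the features, then squeezed to (p × q) constant blocks."""
    return _grid_weights(Tensor(np.asarray(features)), spec).numpy()


def ungrid_and_weight(weights: np.ndarray, image: np.ndarray, spec: GridSpec) -> np.ndarray:
    """Reassemble grid weights to image shape, crop padding, multiply into the
    original image."""
    weights = np.asarray(weights)
    if weights.shape[-4] != spec.h * spec.w:
        raise ValueError(f"expected {spec.h * spec.w} grids, got {weights.shape[-4]}")
    wmap = _ungrid(Tensor(weights), spec)
    wmap = F.crop2d(wmap, spec.H, spec.W)
    return (wmap * Tensor(np.asarray(image))).numpy()


# ---------------------------------------------------------------------------
# trainable modules
# ---------------------------------------------------------------------------

class LGFE(nn.Module):
    """Local grid feature extraction: a shared 1×1-conv bottleneck.

    conv1×1 (C → C·k) → BN → LeakyReLU → conv1×1 (C·k → C) → BN → LeakyReLU;
    one parameter set is applied to every grid cell.
    """

    def __init__(self, channels: int, cfg: LGFEConfig = LGFEConfig()):
        super().__init__()
        hidden = channels * cfg.expansion
        self.net = nn.Sequential(
            nn.Conv2d(channels, hidden, 1),
            nn.BatchNorm2d(hidden),
            nn.LeakyReLU(),
            nn.Conv2d(hidden, channels, 1),
            nn.BatchNorm2d(channels),
            nn.LeakyReLU(),
        )

    def forward(self, grids: Tensor) -> Tensor:
        return self.net(grids)


class GWABlock(nn.Module):
    """End-to-end grid-wise attention over a batch of images.

    Input and output are (N, C, H, W); the output is the input multiplied by a
    per-grid, per-channel scalar weight map derived from attention over LGFE
    features.
    """

    def __init__(self, channels: int = 3, grid_h: int = 3, grid_w: int = 3,
                 lgfe_cfg: LGFEConfig = LGFEConfig(), pad_policy: str = "reflect"):
        super().__init__()
        self.grid_h, self.grid_w = grid_h, grid_w
        self.channels = channels
        self.pad_policy = pad_policy
        self.lgfe = LGFE(channels, lgfe_cfg)

    def spec_for(self, H: int, W: int) -> GridSpec:
        return GridSpec(self.grid_h, self.grid_w, H, W, self.channels, self.pad_policy)

    def forward(self, g: Tensor) -> Tensor:
        N, C, H, W = g.shape
        spec = self.spec_for(H, W)
        grids = _partition(_pad_to_grid(g, spec), spec)        # (N, hw, C, p, q)
        feats = self.lgfe(grids.reshape(N * spec.h * spec.w, C, spec.grid_h, spec.grid_w))
        feats = feats.reshape(N, spec.h * spec.w, C, spec.grid_h, spec.grid_w)
        weights = _grid_weights(feats, spec)
        wmap = F.crop2d(_ungrid(weights, spec), H, W)
        return wmap * g
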