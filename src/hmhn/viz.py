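"""Attention-heatmap export: per-head spatial gates overlaid on the face."""

from __future__ import annotations

from pathlib import Path

import numpy as np
from PIL import Image

from .model import HMHN
from .nn.tensor import Tensor
from . import nn

__all__ = ["attention_gates", "save_heatmaps"]


def attention_gates(model: HMHN, image: np.ndarray) -> np.ndarray:
    """Per-head spatial gate maps upsampled to the image size, each
    min-max normalised to [0, 1].  ``image``: (3, H, W) in [0, 1].
    Returns (k, H, W)."""
    if not model.cfg.use_mab:
        raise ValueError("model has no cross-attention heads (use_mab=False)")
    H, W = image.shape[-2:]
    model.eval()
    with nn.no_grad():
        x = image[None].astype(np.float32)
        g = Tensor(x)
        feats_in = g
        if model.cfg.use_gwa:
            feats_in = model.gwa(g)
        if model.cfg.use_dff:
            feats_in = model.dff(g, feats_in)
        feats = model.backbone(feats_in)
        gates = model.mab.spatial_gates(feats)          # (k, h', w')
    out = np.empty((gates.shape[0], H, W), dtype=np.float32)
    for i, gmap in enumerate(gates):
        lo, hi = float(gmap.min()), float(gmap.max())
        norm = (gmap - lo) / (hi - lo) if hi > lo else np.zeros_like(gmap)
        im = Image.fromarray((norm * 255).astype(np.uint8)).resize((W, H), Image.BILINEAR)
        out[i] = np.asarray(im, dtype=np.float32) / 255.0
    return out


def save_heatmaps(model: HMHN, image: np.ndarray, out_dir) -> list:
    """Write one overlay PNG per head; returns the file paths."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.cm as cm

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    gates = attention_gates(model, image)
    base = image.transpose(1, 2, 0)
    paths = []
    for i, gmap in enumerate(gates):
        heat = cm.jet(gmap)[..., :3]
        overlay = np.clip(0.55 * base + 0.45 * heat, 0, 1)
        p = out / f"head_{i}.png"
        Image.fromarray((overlay * 255 + 0.5).astype(np.uint8)).save(p)
        paths.append(p)
    return paths
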