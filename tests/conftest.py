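"""Shared fixtures.

The two seeded smoke-training runs (a 400-image learnability run and a
200-image pair with/without the partition loss) are session-scoped: several
tests read different properties off the same runs, and a full run is the
expensive part of the suite.  Desk-scale images are 48×48 — the network is
fully convolutional, so the resolution only sets the feature-map sizes.
"""

from __future__ import annotations

import numpy as np
import pytest

from hmhn import TrainConfig, generate_arrays, train_on_arrays
from hmhn.model import ModelConfig

SMOKE_SIZE = 48


def tiny_model_config(**over) -> ModelConfig:
    """A structurally complete but very small model for fast unit tests."""
    base = dict(grid_h=2, grid_w=2, ft_hidden=4, num_heads=2,
                reduce_channels=8, mid1=6, mid2=10)
    base.update(over)
    return ModelConfig(**base)


@pytest.fixture(scope="session")
def learn_run():
    """Seeded 400-train / 100-test run, 10 epochs, batch 16, full model."""
    xtr, ytr = generate_arrays(400, 11, size=SMOKE_SIZE)
    xte, yte = generate_arrays(100, 12, size=SMOKE_SIZE)
    cfg = TrainConfig(epochs=10, batch_size=16, seed=0, image_size=SMOKE_SIZE)
    result = train_on_arrays(cfg, xtr, ytr)
    return {"result": result, "train": (xtr, ytr), "test": (xte, yte), "cfg": cfg}


def _cosine_run(use_partition: bool):
    xtr, ytr = generate_arrays(200, 21, size=SMOKE_SIZE)
    cfg = TrainConfig(epochs=5, batch_size=16, seed=3, image_size=SMOKE_SIZE,
                      use_partition=use_partition)
    return train_on_arrays(cfg, xtr, ytr)


@pytest.fixture(scope="session")
def partition_ablation_pair():
    """Same seed, same data: one run with the partition loss, one without."""
    return {"with": _cosine_run(True), "without": _cosine_run(False)}


def mean_pairwise_head_cosine(model, images: np.ndarray) -> float:
    """Mean over samples and head pairs of the cosine similarity between the
    globally pooled per-head channel vectors."""
    from hmhn import nn
    from hmhn.nn.tensor import Tensor

    model.eval()
    with nn.no_grad():
        heads, _ = model.features(Tensor(images.astype(np.float32)))
    pooled = np.stack([h.numpy().mean(axis=(-2, -1)) for h in heads])  # (k, N, C)
    k = pooled.shape[0]
    norms = np.linalg.norm(pooled, axis=-1)
    sims = []
    for i in range(k):
        for j in range(i + 1, k):
            sims.append((pooled[i] * pooled[j]).sum(-1) / (norms[i] * norms[j] + 1e-12))
    return float(np.mean(sims))
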