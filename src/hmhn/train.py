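"""End-to-end training, checkpointing and prediction.

The whole network — grid attention, feature fusion, backbone, heads,
regression — is trained jointly on L_sum = L_att + L_mse with AdamW.  The
learning rate decays by ``lr_decay_factor`` when the dev-set MAE plateaus.
Checkpoints bundle the weights, the full configuration snapshot and the seed,
so evaluation is self-describing.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from . import nn
from .config import TrainConfig
from .metrics import mae, rmse, severity_from_score
from .model import HMHN, build_model
from .nn.tensor import Tensor

__all__ = ["EpochLog", "TrainResult", "train", "train_on_arrays",
           "save_checkpoint", "load_checkpoint", "predict", "PredictionRecord",
           "evaluate"]

CHECKPOINT_FORMAT = 1


@dataclass
class EpochLog:
    epoch: int
    l_mse: float
    l_att: float
    l_sum: float
    dev_mae: float
    dev_rmse: float
    lr: float


@dataclass
class TrainResult:
    model: HMHN
    history: list              # [EpochLog]
    best_dev_mae: float
    best_state: dict
    checkpoint_path: Path | None


def _batches(n: int, batch_size: int, rng: np.random.Generator):
    order = rng.permutation(n)
    for i in range(0, n, batch_size):
        yield order[i:i + batch_size]


def evaluate(model: HMHN, images: np.ndarray, scores: np.ndarray,
             batch_size: int = 32) -> tuple:
    """Eval-mode (MAE, RMSE) over a dataset."""
    preds = []
    for i in range(0, len(images), batch_size):
        preds.append(model.predict_scores(images[i:i + batch_size]))
    preds = np.concatenate(preds)
    return mae(scores, preds), rmse(scores, preds)


def train_on_arrays(cfg: TrainConfig, train_images: np.ndarray, train_scores: np.ndarray,
                    dev_images: np.ndarray | None = None,
                    dev_scores: np.ndarray | None = None,
                    checkpoint_path=None, log_path=None,
                    verbose: bool = False) -> TrainResult:
    """Train a fresh model on in-memory arrays; fully seeded and deterministic.

    ``dev_*`` default to the training data (the plateau scheduler and the
    best-checkpoint selection then track training MAE).
    """
    nn.manual_seed(cfg.seed)
    model = build_model(cfg.model)
    opt = nn.AdamW(model.parameters(), lr=cfg.lr, weight_decay=cfg.weight_decay)
    sched = nn.ReduceLROnPlateau(opt, factor=cfg.lr_decay_factor,
                                 patience=cfg.plateau_patience)
    data_rng = np.random.default_rng([cfg.seed, 17])
    if dev_images is None:
        dev_images, dev_scores = train_images, train_scores

    history: list = []
    best = np.inf
    best_state = model.state_dict()
    x_all = np.asarray(train_images, dtype=np.float32)
    y_all = np.asarray(train_scores, dtype=np.float32)
    for epoch in range(1, cfg.epochs + 1):
        model.train()
        sums = np.zeros(3)
        nb = 0
        for idx in _batches(len(x_all), cfg.batch_size, data_rng):
            xb = Tensor(x_all[idx])
            yb = Tensor(y_all[idx])
            l_sum, l_mse, l_att = model.loss(xb, yb, cfg.loss_eps, cfg.use_partition)
            if not np.isfinite(l_sum.item()):
                raise RuntimeError(
                    f"non-finite loss at epoch {epoch} (l_mse={l_mse.item()}, "
                    f"l_att={l_att.item()}); aborting")
            opt.zero_grad()
            l_sum.backward()
            opt.step()
            sums += (l_mse.item(), l_att.item(), l_sum.item())
            nb += 1
        dev_mae, dev_rmse = evaluate(model, dev_images, dev_scores,
                                     max(cfg.batch_size, 16))
        log = EpochLog(epoch, sums[0] / nb, sums[1] / nb, sums[2] / nb,
                       dev_mae, dev_rmse, opt.lr)
        history.append(log)
        if verbose:
            print(f"epoch {epoch:3d}  L_mse {log.l_mse:9.3f}  L_att {log.l_att:7.4f}  "
                  f"L_sum {log.l_sum:9.3f}  dev MAE {dev_mae:6.3f}  RMSE {dev_rmse:6.3f}")
        if dev_mae < best:
            best = dev_mae
            best_state = model.state_dict()
        sched.step(dev_mae)

    model.load_state_dict(best_state)
    ckpt = None
    if checkpoint_path is not None:
        ckpt = Path(checkpoint_path)
        save_checkpoint(model, cfg, ckpt)
    if log_path is not None:
        with open(log_path, "w") as fh:
            for log in history:
                fh.write(json.dumps(vars(log)) + "\n")
    return TrainResult(model, history, best, best_state, ckpt)


def train(cfg: TrainConfig, train_manifest, dev_manifest=None,
          checkpoint_path=None, log_path=None, verbose: bool = False) -> TrainResult:
    """Train from manifest CSVs (see :func:`hmhn.data.load_manifest`)."""
    from .data import load_manifest, load_split

    recs = load_manifest(train_manifest)
    splits = {r.split for r in recs}
    tr_split = "train" if "train" in splits else None
    xs, ys = load_split(recs, tr_split, cfg.image_size)
    xd = yd = None
    if dev_manifest is not None:
        drecs = load_manifest(dev_manifest)
        dsplits = {r.split for r in drecs}
        xd, yd = load_split(drecs, "dev" if "dev" in dsplits else None, cfg.image_size)
    elif "dev" in splits:
        xd, yd = load_split(recs, "dev", cfg.image_size)
    return train_on_arrays(cfg, xs, ys, xd, yd, checkpoint_path, log_path, verbose)


# -- checkpointing ----------------------------------------------------------

def save_checkpoint(model: HMHN, cfg: TrainConfig, path) -> None:
    state = model.state_dict()
    meta = json.dumps({"format": CHECKPOINT_FORMAT, "config": cfg.to_dict()})
    np.savez(path, __meta__=np.frombuffer(meta.encode(), dtype=np.uint8), **state)


def load_checkpoint(path) -> tuple:
    """Returns ``(model, cfg)`` rebuilt from a checkpoint file."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"checkpoint not found: {path}")
    with np.load(path) as z:
        if "__meta__" not in z:
            raise ValueError(f"{path} is not a recognised checkpoint")
        meta = json.loads(bytes(z["__meta__"]).decode())
        if meta.get("format") != CHECKPOINT_FORMAT:
            raise ValueError(f"checkpoint format {meta.get('format')!r} not supported "
                             f"(expected {CHECKPOINT_FORMAT})")
        cfg = TrainConfig.from_dict(meta["config"])
        model = build_model(cfg.model, seed=cfg.seed)
        model.load_state_dict({k: z[k] for k in z.files if k != "__meta__"})
    model.eval()
    return model, cfg


# -- prediction -------------------------------------------------------------

@dataclass(frozen=True)
class PredictionRecord:
    sample_id: str
    score: float               # raw regression output (unclamped)
    clamped_score: float       # clamped to [0, 63]
    severity: str
    truth: float | None = None


def predict(checkpoint_path, image_paths, truths=None) -> list:
    """Eval-mode per-image predictions from a saved checkpoint."""
    from .data import preprocess_image

    model, cfg = load_checkpoint(checkpoint_path)
    records = []
    truths = list(truths) if truths is not None else [None] * len(image_paths)
    for p, t in zip(image_paths, truths):
        img = preprocess_image(p, cfg.image_size)[None]
        raw = float(model.predict_scores(img)[0])
        clamped = min(max(raw, 0.0), 63.0)
        records.append(PredictionRecord(str(p), raw, clamped,
                                        severity_from_score(clamped).label, t))
    return records
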