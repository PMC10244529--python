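"""Manifest and image I/O.

A dataset is a CSV manifest (columns ``path,bdi2_score[,split]``) next to
pre-cropped, pre-aligned face images.  Images are decoded to RGB, bilinearly
resized to the working resolution (224² by default) and scaled to [0, 1],
channels-first.  Face detection/alignment is assumed done upstream.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image

__all__ = ["ManifestRecord", "load_manifest", "preprocess_image", "load_split"]

REQUIRED_COLUMNS = ("path", "bdi2_score")


@dataclass(frozen=True)
class ManifestRecord:
    path: Path
    score: float
    split: str


def load_manifest(path) -> list:
    """Read and validate a manifest CSV; returns a list of ManifestRecord.

    Scores must lie in [0, 63]; violations are reported with their row number
    (1-based, excluding the header).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"manifest not found: {path}")
    try:
        df = pd.read_csv(path)
    except pd.errors.EmptyDataError:
        raise ValueError(f"empty manifest: {path}") from None
    if len(df) == 0:
        raise ValueError(f"empty manifest: {path}")
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"manifest {path} lacks required column(s) {missing}")
    root = path.parent
    records = []
    for i, row in enumerate(df.itertuples(index=False), start=1):
        try:
            score = float(row.bdi2_score)
        except (TypeError, ValueError):
            raise ValueError(f"manifest {path} row {i}: malformed score "
                             f"{row.bdi2_score!r}") from None
        if not (0.0 <= score <= 63.0):
            raise ValueError(f"manifest {path} row {i}: score {score} outside [0, 63]")
        split = str(getattr(row, "split", "train") or "train")
        records.append(ManifestRecord(root / str(row.path), score, split))
    return records


def preprocess_image(path, size: int = 224) -> np.ndarray:
    """Decode → RGB → bilinear resize to ``size``² → float32 CHW in [0, 1].

    Grayscale inputs are replicated to three channels; alpha is dropped.
    """
    try:
        with Image.open(path) as im:
            im = im.convert("RGB")
            if im.size != (size, size):
                im = im.resize((size, size), Image.BILINEAR)
            arr = np.asarray(im, dtype=np.float32) / 255.0
    except FileNotFoundError:
        raise
    except OSError as exc:
        raise OSError(f"cannot read image {path}: {exc}") from exc
    return arr.transpose(2, 0, 1)


def load_split(records: list, split: str | None = None, size: int = 224) -> tuple:
    """Materialise (images, scores) arrays for one split (or all records)."""
    recs = [r for r in records if split is None or r.split == split]
    if not recs:
        raise ValueError(f"no records for split {split!r}")
    imgs = np.stack([preprocess_image(r.path, size) for r in recs])
    scores = np.asarray([r.score for r in recs], dtype=np.float64)
    return imgs, scores
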