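"""File I/O: 8-bit PNG frames/masks and CSV manifests.

Frames are stored as 8-bit grayscale PNG; in memory they are floats in
[0, 1] quantized to the 256-level grid (k/255), so a write/read round
trip is bit-exact. Masks are stored with 0 = background, 255 = glottis.

Two manifest schemas are used, both CSV with paths relative to the
manifest's own directory:

* pair manifests: ``frame_path, mask_path, split`` (phantom datasets);
* scored manifests: ``frame_path, gt_mask_path, candidate_mask_path,
  iou, split`` (perturbed / model-failure datasets).
"""

from __future__ import annotations

import os
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd

from .metrics import ScoredSample, as_frame, as_mask

__all__ = [
    "quantize_frame",
    "write_frame",
    "read_frame",
    "write_mask",
    "read_mask",
    "write_pair_manifest",
    "read_pair_manifest",
    "write_scored_manifest",
    "read_scored_manifest",
    "load_scored_samples",
]

PAIR_COLUMNS = ["frame_path", "mask_path", "split"]
SCORED_COLUMNS = ["frame_path", "gt_mask_path", "candidate_mask_path", "iou", "split"]


def quantize_frame(frame: np.ndarray) -> np.ndarray:
    """Snap a [0, 1] float frame onto the 8-bit grid (values k/255)."""
    f = as_frame(frame)
    return np.round(f * 255.0) / 255.0


def write_frame(path, frame: np.ndarray) -> None:
    f = as_frame(frame)
    iio.imwrite(os.fspath(path), np.round(f * 255.0).astype(np.uint8))


def read_frame(path) -> np.ndarray:
    a = iio.imread(os.fspath(path))
    if a.ndim == 3:  # defensively collapse accidental RGB
        a = a[..., 0]
    return a.astype(np.float64) / 255.0


def write_mask(path, mask: np.ndarray) -> None:
    m = as_mask(mask)
    iio.imwrite(os.fspath(path), np.where(m, 255, 0).astype(np.uint8))


def read_mask(path) -> np.ndarray:
    a = iio.imread(os.fspath(path))
    if a.ndim == 3:
        a = a[..., 0]
    return as_mask(a)


def _check_columns(df: pd.DataFrame, cols, what: str) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise ValueError(f"{what} manifest is missing columns {missing}")


def write_pair_manifest(path, rows: pd.DataFrame) -> None:
    _check_columns(rows, PAIR_COLUMNS, "pair")
    rows.to_csv(path, index=False)


def read_pair_manifest(path) -> pd.DataFrame:
    path = Path(path)
    df = pd.read_csv(path)
    _check_columns(df, PAIR_COLUMNS, "pair")
    df.attrs["root"] = str(path.parent)
    return df


def write_scored_manifest(path, rows: pd.DataFrame) -> None:
    _check_columns(rows, SCORED_COLUMNS, "scored")
    rows = rows.copy()
    # shortest-repr serialization so labels survive the round trip bit-exactly
    rows["iou"] = rows["iou"].map(lambda v: repr(float(v)))
    rows.to_csv(path, index=False)


def read_scored_manifest(path) -> pd.DataFrame:
    path = Path(path)
    df = pd.read_csv(path, float_precision="round_trip")
    _check_columns(df, SCORED_COLUMNS, "scored")
    df.attrs["root"] = str(path.parent)
    return df


def load_scored_samples(manifest) -> list[ScoredSample]:
    """Materialize :class:`ScoredSample` records from a scored manifest.

    *manifest* is a path or a DataFrame returned by
    :func:`read_scored_manifest` (whose ``attrs['root']`` anchors the
    relative paths). Each sample's stored IoU is re-validated against the
    masks on load.
    """
    if not isinstance(manifest, pd.DataFrame):
        manifest = read_scored_manifest(manifest)
    root = Path(manifest.attrs.get("root", "."))
    samples = []
    for row in manifest.itertuples(index=False):
        samples.append(
            ScoredSample(
                frame=read_frame(root / row.frame_path),
                gt_mask=read_mask(root / row.gt_mask_path),
                candidate_mask=read_mask(root / row.candidate_mask_path),
                iou=float(row.iou),
                meta={"split": row.split},
            )
        )
    return samples
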