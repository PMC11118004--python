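"""Knowledge-driven corruption of ground-truth masks with exact IoU labels.

Six randomized operators mimic characteristic glottis-segmentation
mistakes:

* **rotate** — the shape is kept but its position/orientation becomes
  implausible;
* **dilate** — over-segmentation with smoothed contours;
* **erode** — under-segmentation with irregular contours;
* **break** — holes and missing fragments (random disks subtracted);
* **copy** — a displaced, rescaled duplicate is unioned in, forcing a
  quality model to attend to position;
* **ellipse** — a glottis-like filled ellipse is inserted; on an *empty*
  ground truth its selection probability is boosted, emulating spurious
  segmentations of a closed glottis.

A target IoU is drawn from a 6-bin distribution over [0, 1]; operators
are then applied one at a time — each gated by its own Bernoulli
probability ``p``, in randomized order — until the candidate's IoU
against the pristine ground truth lands within ``target_tolerance`` of
the target. Overshoot (or iteration exhaustion) triggers a restart from
the pristine mask; after ``max_restarts`` the state closest to the
target wins. The stored label is always the exactly recomputed IoU of
the returned candidate, never the sampled target.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field, asdict, replace
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage import draw as skdraw

from . import data
from .metrics import ScoredSample, as_mask, compute_iou

__all__ = [
    "PerturbationConfig",
    "rotate_mask",
    "dilate_mask",
    "erode_mask",
    "break_mask",
    "copy_mask",
    "insert_ellipse",
    "sample_target_iou",
    "perturb_to_target",
    "perturb_pairs",
    "build_perturbed_dataset",
]

OPERATOR_NAMES = ("rotate", "dilate", "erode", "break", "copy", "ellipse")

#: Operators that can only shrink a mask / only grow it (area monotonicity).
SHRINKING_OPS = frozenset({"erode", "break"})
GROWING_OPS = frozenset({"dilate", "copy", "ellipse"})


@dataclass(frozen=True)
class PerturbationConfig:
    """Operator gates, target-IoU bins, and per-operator parameter ranges.

    ``bin_edges`` are 7 ascending reals from 0 to 1; ``bin_probabilities``
    are the corresponding 6 bin weights (sum 1). The default bins put the
    most mass on borderline scores around the 0.6 acceptance threshold
    (empirical mean ≈ 0.5, std ≈ 0.28).

    Kernel sizes and blob radii are in pixels; copy offsets are fractions
    of the image side; ellipse axes are fractions of the image side.
    """

    op_probabilities: dict = field(
        default_factory=lambda: {
            "rotate": 0.3,
            "dilate": 0.5,
            "erode": 0.5,
            "break": 0.4,
            "copy": 0.2,
            "ellipse": 0.2,
        }
    )
    bin_edges: tuple = (0.0, 0.1, 0.3, 0.5, 0.7, 0.9, 1.0)
    bin_probabilities: tuple = (0.10, 0.15, 0.20, 0.30, 0.15, 0.10)
    target_tolerance: float = 0.05
    max_iterations: int = 30
    max_restarts: int = 5
    rotation_degrees_range: tuple = (15.0, 180.0)
    dilation_kernel_range: tuple = (3, 9)
    erosion_kernel_range: tuple = (3, 9)
    break_blob_count_range: tuple = (1, 4)
    break_blob_radius_range: tuple = (2.0, 10.0)
    copy_offset_range: tuple = (0.05, 0.4)
    copy_scale_range: tuple = (0.5, 1.5)
    ellipse_axis_range: tuple = (0.04, 0.16)
    ellipse_on_empty_boost: float = 4.0
    copy_replaces: bool = False
    seed: int = 0

    def __post_init__(self):
        if set(self.op_probabilities) != set(OPERATOR_NAMES):
            raise ValueError(
                f"op_probabilities must name exactly {OPERATOR_NAMES}, "
                f"got {sorted(self.op_probabilities)}"
            )
        for name, p in self.op_probabilities.items():
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"op probability for {name!r} must be in [0,1], got {p}")
        edges = np.asarray(self.bin_edges, dtype=np.float64)
        if edges.shape != (7,) or edges[0] != 0.0 or edges[-1] != 1.0:
            raise ValueError("bin_edges must be 7 values from 0 to 1")
        if np.any(np.diff(edges) <= 0):
            raise ValueError("bin_edges must be strictly ascending (no degenerate bins)")
        probs = np.asarray(self.bin_probabilities, dtype=np.float64)
        if probs.shape != (6,) or np.any(probs < 0):
            raise ValueError("bin_probabilities must be 6 non-negative values")
        if abs(probs.sum() - 1.0) > 1e-9:
            raise ValueError(f"bin_probabilities must sum to 1, got {probs.sum()!r}")
        if not 0.0 < self.target_tolerance < 0.5:
            raise ValueError("target_tolerance must be in (0, 0.5)")
        if self.max_iterations < 1 or self.max_restarts < 0:
            raise ValueError("max_iterations >= 1 and max_restarts >= 0 required")
        if self.ellipse_on_empty_boost < 1.0:
            raise ValueError("ellipse_on_empty_boost must be >= 1")

    def to_json(self, path) -> None:
        d = asdict(self)
        with open(path, "w") as fh:
            json.dump(d, fh, indent=2)

    @classmethod
    def from_json(cls, path) -> "PerturbationConfig":
        with open(path) as fh:
            d = json.load(fh)
        for k, v in list(d.items()):
            if isinstance(v, list):
                d[k] = tuple(v)
        return cls(**d)


# ---------------------------------------------------------------------------
# Operators


def rotate_mask(mask, angle: float, rng=None) -> np.ndarray:
    """Rotate a mask about its own centroid (nearest-neighbor, re-binarized).

    Pixels rotated off the grid are dropped; empty masks pass through.
    """
    m = as_mask(mask)
    if not m.any() or angle % 360 == 0:
        return m.copy()
    cy, cx = ndimage.center_of_mass(m)
    theta = np.deg2rad(angle)
    c, s = np.cos(theta), np.sin(theta)
    rot = np.array([[c, -s], [s, c]])  # inverse map: output -> input coords
    center = np.array([cy, cx])
    offset = center - rot @ center
    out = ndimage.affine_transform(
        m.astype(np.uint8), rot, offset=offset, order=0, mode="constant", cval=0
    )
    return out.astype(bool)


def _footprint(kernel_px: int, element: str) -> np.ndarray:
    if kernel_px < 3 or kernel_px % 2 == 0:
        raise ValueError(f"kernel_px must be an odd integer >= 3, got {kernel_px}")
    if element == "square":
        return np.ones((kernel_px, kernel_px), dtype=bool)
    if element == "ellipse":
        r = kernel_px // 2
        yy, xx = np.mgrid[-r : r + 1, -r : r + 1]
        return (xx / r) ** 2 + (yy / r) ** 2 <= 1.0
    raise ValueError(f"unknown structuring element {element!r}")


def dilate_mask(mask, kernel_px: int, iterations: int = 1, rng=None, element: str = "ellipse"):
    """Morphological dilation; the area never decreases."""
    m = as_mask(mask)
    fp = _footprint(kernel_px, element)
    return ndimage.binary_dilation(m, structure=fp, iterations=iterations)


def erode_mask(mask, kernel_px: int, iterations: int = 1, rng=None, element: str = "ellipse"):
    """Morphological erosion; the area never increases and may reach zero."""
    m = as_mask(mask)
    fp = _footprint(kernel_px, element)
    return ndimage.binary_erosion(m, structure=fp, iterations=iterations)


def break_mask(mask, blob_count: int, blob_radius_range, rng) -> np.ndarray:
    """Subtract random disks centered inside the mask's bounding box.

    Output is always a subset of the input; empty masks pass through.
    """
    m = as_mask(mask)
    if not m.any():
        return m.copy()
    rows = np.any(m, axis=1).nonzero()[0]
    cols = np.any(m, axis=0).nonzero()[0]
    r0, r1 = rows[0], rows[-1]
    c0, c1 = cols[0], cols[-1]
    out = m.copy()
    lo, hi = blob_radius_range
    for _ in range(blob_count):
        cy = rng.integers(r0, r1 + 1)
        cx = rng.integers(c0, c1 + 1)
        radius = rng.uniform(lo, hi)
        rr, cc = skdraw.disk((cy, cx), radius, shape=m.shape)
        out[rr, cc] = False
    return out


def copy_mask(mask, offset, scale: float, rng=None, replace: bool = False) -> np.ndarray:
    """Union the mask with a translated, rescaled copy of itself.

    *offset* is ``(dy, dx)`` in pixels; copy pixels falling off the grid
    are dropped. With ``replace=True`` the copy replaces the original
    instead of being unioned.
    """
    m = as_mask(mask)
    if not m.any():
        return m.copy()
    if scale <= 0:
        raise ValueError(f"scale must be > 0, got {scale}")
    rows = np.any(m, axis=1).nonzero()[0]
    cols = np.any(m, axis=0).nonzero()[0]
    crop = m[rows[0] : rows[-1] + 1, cols[0] : cols[-1] + 1]
    if scale != 1.0:
        crop = ndimage.zoom(crop.astype(np.uint8), scale, order=0).astype(bool)
        if crop.size == 0:
            return m.copy() if not replace else np.zeros_like(m)
    dy, dx = int(round(offset[0])), int(round(offset[1]))
    top = rows[0] + dy
    left = cols[0] + dx
    placed = np.zeros_like(m)
    h, w = crop.shape
    y0, y1 = max(0, top), min(m.shape[0], top + h)
    x0, x1 = max(0, left), min(m.shape[1], left + w)
    if y0 < y1 and x0 < x1:
        placed[y0:y1, x0:x1] = crop[y0 - top : y1 - top, x0 - left : x1 - left]
    return placed if replace else (m | placed)


def insert_ellipse(mask, center, axes, angle: float, rng=None) -> np.ndarray:
    """Union the mask with a filled rotated ellipse.

    Raises ``ValueError`` if the ellipse rasterizes to zero pixels on the
    grid (fully off-grid); the sampling loop treats that as a rejected
    draw and resamples.
    """
    m = as_mask(mask)
    if axes[0] <= 0 or axes[1] <= 0:
        raise ValueError(f"ellipse axes must be positive, got {axes}")
    rr, cc = skdraw.ellipse(
        center[0], center[1], axes[0], axes[1], shape=m.shape, rotation=np.deg2rad(angle)
    )
    if rr.size == 0:
        raise ValueError("ellipse lies fully off the grid")
    out = m.copy()
    out[rr, cc] = True
    return out


# ---------------------------------------------------------------------------
# Target sampling and the perturbation procedure


def sample_target_iou(config: PerturbationConfig, rng) -> float:
    """Draw a target IoU: pick a bin by weight, then uniformly inside it."""
    idx = rng.choice(6, p=np.asarray(config.bin_probabilities, dtype=np.float64))
    lo, hi = config.bin_edges[idx], config.bin_edges[idx + 1]
    return float(rng.uniform(lo, hi))


def _apply_random_op(name, candidate, config: PerturbationConfig, rng):
    """Sample the operator's parameters from the config ranges and apply."""
    n = candidate.shape[0]
    if name == "rotate":
        lo, hi = config.rotation_degrees_range
        angle = rng.uniform(lo, hi) * (1 if rng.random() < 0.5 else -1)
        return rotate_mask(candidate, angle, rng)
    if name == "dilate":
        k = _odd_in(config.dilation_kernel_range, rng)
        return dilate_mask(candidate, k, 1, rng)
    if name == "erode":
        k = _odd_in(config.erosion_kernel_range, rng)
        return erode_mask(candidate, k, 1, rng)
    if name == "break":
        lo, hi = config.break_blob_count_range
        count = int(rng.integers(lo, hi + 1))
        return break_mask(candidate, count, config.break_blob_radius_range, rng)
    if name == "copy":
        lo, hi = config.copy_offset_range
        off = []
        for _ in range(2):
            mag = rng.uniform(lo, hi) * n
            off.append(mag * (1 if rng.random() < 0.5 else -1))
        scale = rng.uniform(*config.copy_scale_range)
        return copy_mask(candidate, tuple(off), scale, rng, replace=config.copy_replaces)
    if name == "ellipse":
        lo, hi = config.ellipse_axis_range
        for _ in range(10):  # resample rejected (off-grid) draws
            center = (rng.uniform(0, n), rng.uniform(0, n))
            axes = (rng.uniform(lo, hi) * n, rng.uniform(lo, hi) * n)
            angle = rng.uniform(0.0, 180.0)
            try:
                return insert_ellipse(candidate, center, axes, angle, rng)
            except ValueError:
                continue
        return candidate.copy()
    raise ValueError(f"unknown operator {name!r}")  # pragma: no cover


def _odd_in(bounds, rng) -> int:
    lo, hi = bounds
    odds = [k for k in range(int(lo), int(hi) + 1) if k % 2 == 1 and k >= 3]
    return int(rng.choice(odds))


def perturb_to_target(
    gt_mask,
    target: float,
    config: PerturbationConfig,
    rng,
    log: list | None = None,
) -> tuple[np.ndarray, float]:
    """Corrupt *gt_mask* until its IoU against the original ≈ *target*.

    Returns ``(candidate_mask, achieved_iou)`` where ``achieved_iou`` is
    the exactly recomputed IoU of the candidate. The procedure always
    returns some candidate; the pristine mask (IoU 1.0) is the degenerate
    fallback. If *log* is a list, one ``(op_name, area_before,
    area_after)`` tuple is appended per operator application.
    """
    gt = as_mask(gt_mask)
    gt_empty = not gt.any()
    op_names = list(OPERATOR_NAMES)
    probs = dict(config.op_probabilities)
    if gt_empty:
        probs["ellipse"] = min(1.0, probs["ellipse"] * config.ellipse_on_empty_boost)
    tol = config.target_tolerance

    best = gt.copy()
    best_iou = 1.0
    if abs(best_iou - target) <= tol:
        return best, best_iou

    for _restart in range(config.max_restarts + 1):
        candidate = gt.copy()
        iou = 1.0
        overshoot = False
        for _it in range(config.max_iterations):
            order = rng.permutation(len(op_names))
            for idx in order:
                name = op_names[idx]
                if rng.random() >= probs[name]:
                    continue
                new_candidate = _apply_random_op(name, candidate, config, rng)
                if log is not None:
                    log.append(
                        (
                            name,
                            int(np.count_nonzero(candidate)),
                            int(np.count_nonzero(new_candidate)),
                        )
                    )
                candidate = new_candidate
                iou = compute_iou(candidate, gt)
                if abs(iou - target) < abs(best_iou - target):
                    best = candidate.copy()
                    best_iou = iou
                if abs(iou - target) <= tol:
                    return candidate, iou
                if iou < target - tol:
                    overshoot = True
                    break
            if overshoot:
                break
    return best, best_iou


def perturb_pairs(
    pairs,
    config: PerturbationConfig,
    rng,
    samples_per_pair: int = 1,
) -> list[ScoredSample]:
    """Generate exactly-labeled samples from in-memory (frame, gt) pairs.

    The frames are reused unmodified — only the segmentations vary — so
    a downstream model cannot extract novel glottis appearance from the
    corrupted data.
    """
    if samples_per_pair < 1:
        raise ValueError("samples_per_pair must be >= 1")
    pairs = list(pairs)
    if not pairs:
        raise ValueError("perturb_pairs requires at least one (frame, mask) pair")
    out = []
    for frame, gt in pairs:
        for _ in range(samples_per_pair):
            target = sample_target_iou(config, rng)
            candidate, iou = perturb_to_target(gt, target, config, rng)
            out.append(
                ScoredSample(
                    frame=frame,
                    gt_mask=gt,
                    candidate_mask=candidate,
                    iou=iou,
                    meta={"target": target, "source": "procedure"},
                )
            )
    return out


def build_perturbed_dataset(
    pair_manifest,
    config: PerturbationConfig,
    rng,
    out_dir,
    samples_per_pair: int = 1,
    split: str = "train",
) -> pd.DataFrame:
    """Disk-level wrapper: read a pair manifest, write candidates + manifest.

    Candidate masks are written as PNGs under *out_dir*; frame and
    ground-truth paths reference the original files (relative to
    *out_dir*), since frames are never modified. Returns the scored
    manifest (also written to ``out_dir/manifest.csv``).
    """
    if not isinstance(pair_manifest, pd.DataFrame):
        pair_manifest = data.read_pair_manifest(pair_manifest)
    if len(pair_manifest) == 0:
        raise ValueError("pair manifest is empty")
    root = Path(pair_manifest.attrs.get("root", "."))
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    k = 0
    for row in pair_manifest.itertuples(index=False):
        frame = data.read_frame(root / row.frame_path)
        gt = data.read_mask(root / row.mask_path)
        for _ in range(samples_per_pair):
            target = sample_target_iou(config, rng)
            candidate, iou = perturb_to_target(gt, target, config, rng)
            cand_rel = f"candidate_{k:05d}.png"
            data.write_mask(out_dir / cand_rel, candidate)
            rows.append(
                {
                    "frame_path": os.path.relpath(root / row.frame_path, out_dir),
                    "gt_mask_path": os.path.relpath(root / row.mask_path, out_dir),
                    "candidate_mask_path": cand_rel,
                    "iou": iou,
                    "split": split,
                }
            )
            k += 1
    manifest = pd.DataFrame(rows, columns=data.SCORED_COLUMNS)
    data.write_scored_manifest(out_dir / "manifest.csv", manifest)
    manifest.attrs["root"] = str(out_dir)
    return manifest
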