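"""Model-driven segmentation failures via an augmentation-intensity ramp.

A pluggable segmenter (any callable mapping a [0, 1] grayscale frame to a
same-shape binary mask) is fed frames whose corruption level is governed
by a single intensity factor ``amp``: every augmentation range's
deviation from its neutral point is multiplied by ``amp`` and then
clipped to a physically sensible domain. Feeding harder frames makes the
segmenter fail in diverse, realistic ways; the resulting candidate masks
are labeled with their exact IoU against the *clean* ground truth, and
the clean frame is what enters downstream training — only the
segmentations vary.

The base ranges at ``amp = 1`` are: in-plane rotation ±10°, out-of-plane
(view-axis) rotations ±5° — approximated as affine shears, since the 3-D
camera geometry is not recoverable from 2-D frames — gamma 80–120 (on a
0–100–x scale, neutral 100), brightness ±20%, contrast ±20%, and
additive Gaussian noise with variance drawn from [0.10, 0.50].

The repository ships :func:`reference_segmenter`, a deliberately weak
fixed-threshold-plus-morphology baseline whose accuracy collapses as
``amp`` grows; a trained network can be plugged in the same way.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage

from . import data
from .metrics import ScoredSample, as_frame, as_mask, compute_iou

__all__ = [
    "AugmentationRamp",
    "scale_ranges",
    "degrade_frame",
    "reference_segmenter",
    "generate_model_failures",
]


@dataclass(frozen=True)
class AugmentationRamp:
    """Intensity factor plus the base (amp = 1) augmentation ranges."""

    amp: float = 1.0
    rotation_x_deg: float = 10.0
    rotation_yz_deg: float = 5.0
    gamma_range: tuple = (80.0, 120.0)
    brightness_limit: float = 0.2
    contrast_limit: float = 0.2
    gauss_variance_range: tuple = (0.10, 0.50)
    seed: int = 0

    def __post_init__(self):
        if self.amp < 0:
            raise ValueError(f"amp must be >= 0, got {self.amp}")


# Hard caps keeping scaled ranges in physically sensible domains.
_GAMMA_EXP_MIN = 0.05
_BRIGHTNESS_CAP = 0.8
_CONTRAST_CAP = 0.95  # contrast factor stays within [1-cap, 1+cap], > 0


def scale_ranges(ramp: AugmentationRamp) -> dict:
    """Concrete sampling ranges at the ramp's ``amp``.

    Each range's half-width (deviation from its neutral point — 0° for
    rotations, 100 for gamma, 0 for brightness/noise, 1 for contrast) is
    multiplied by ``amp`` and clipped to its valid domain. ``amp = 0``
    collapses everything to a no-op.
    """
    a = ramp.amp
    g_lo, g_hi = ramp.gamma_range
    gamma_lo = max(100.0 - (100.0 - g_lo) * a, 100.0 * _GAMMA_EXP_MIN)
    gamma_hi = 100.0 + (g_hi - 100.0) * a
    v_lo, v_hi = ramp.gauss_variance_range
    return {
        "rotation_x_deg": ramp.rotation_x_deg * a,
        "rotation_yz_deg": ramp.rotation_yz_deg * a,
        "gamma": (gamma_lo, gamma_hi),
        "brightness_limit": min(ramp.brightness_limit * a, _BRIGHTNESS_CAP),
        "contrast_limit": min(ramp.contrast_limit * a, _CONTRAST_CAP),
        "gauss_variance": (v_lo * a, v_hi * a),
    }


def degrade_frame(frame, ramp: AugmentationRamp, rng) -> np.ndarray:
    """Apply one random draw of the ramped augmentations to a frame.

    Order: geometric (rotation + shears), gamma, brightness/contrast,
    Gaussian noise; the output is clamped to [0, 1] and keeps the shape.
    ``amp = 0`` returns the frame unchanged.
    """
    f = as_frame(frame)
    if ramp.amp == 0:
        return f.copy()
    r = scale_ranges(ramp)

    # Geometric: in-plane rotation about the frame center plus two small
    # shears standing in for the out-of-plane view rotations.
    theta = np.deg2rad(rng.uniform(-r["rotation_x_deg"], r["rotation_x_deg"]))
    shy = np.tan(np.deg2rad(rng.uniform(-r["rotation_yz_deg"], r["rotation_yz_deg"])))
    shx = np.tan(np.deg2rad(rng.uniform(-r["rotation_yz_deg"], r["rotation_yz_deg"])))
    c, s = np.cos(theta), np.sin(theta)
    mat = np.array([[c, -s], [s, c]]) @ np.array([[1.0, shy], [shx, 1.0]])
    center = (np.array(f.shape) - 1) / 2.0
    offset = center - mat @ center
    out = ndimage.affine_transform(f, mat, offset=offset, order=1, mode="nearest")

    g_lo, g_hi = r["gamma"]
    gamma = rng.uniform(g_lo, g_hi) / 100.0
    out = np.clip(out, 0.0, 1.0) ** gamma

    brightness = rng.uniform(-r["brightness_limit"], r["brightness_limit"])
    contrast = 1.0 + rng.uniform(-r["contrast_limit"], r["contrast_limit"])
    out = (out - 0.5) * contrast + 0.5 + brightness

    v_lo, v_hi = r["gauss_variance"]
    var = rng.uniform(v_lo, v_hi)
    if var > 0:
        out = out + rng.normal(0.0, np.sqrt(var), size=out.shape)
    return np.clip(out, 0.0, 1.0)


def reference_segmenter(frame) -> np.ndarray:
    """Weak baseline: smooth, fixed dark threshold, keep the largest blob.

    Intentionally brittle — its fixed absolute threshold breaks under
    brightness/gamma shifts and heavy noise, which is exactly the failure
    behavior the degrader needs to harvest.
    """
    f = as_frame(frame)
    smooth = ndimage.gaussian_filter(f, sigma=1.5)
    mask = smooth < 0.28
    if not mask.any():
        return mask
    mask = ndimage.binary_opening(mask, iterations=1)
    if not mask.any():
        return mask
    labels, n = ndimage.label(mask)
    if n > 1:
        sizes = ndimage.sum_labels(np.ones_like(labels), labels, index=range(1, n + 1))
        mask = labels == (int(np.argmax(sizes)) + 1)
    return ndimage.binary_fill_holes(mask)


def generate_model_failures(
    segmenter,
    pairs,
    ramp: AugmentationRamp,
    rng,
    on_bad_output: str = "skip",
) -> list[ScoredSample]:
    """Harvest model failures from in-memory (frame, gt) pairs.

    Each frame is degraded at the ramp's ``amp`` and segmented; the
    candidate mask is labeled with its exact IoU against the clean
    ground truth, and the sample stores the *clean* frame. Segmenter
    outputs with a wrong shape or non-binary values are skipped with a
    warning, or rejected when ``on_bad_output='raise'``.
    """
    samples = []
    skipped = 0
    for frame, gt in pairs:
        f = as_frame(frame)
        g = as_mask(gt)
        degraded = degrade_frame(f, ramp, rng)
        candidate = segmenter(degraded)
        try:
            candidate = as_mask(candidate)
            if candidate.shape != g.shape:
                raise ValueError(
                    f"segmenter returned shape {candidate.shape}, expected {g.shape}"
                )
        except ValueError:
            if on_bad_output == "raise":
                raise
            skipped += 1
            continue
        samples.append(
            ScoredSample(
                frame=f,
                gt_mask=g,
                candidate_mask=candidate,
                iou=compute_iou(candidate, g),
                meta={"amp": ramp.amp, "source": "model_failures"},
            )
        )
    if skipped:
        import warnings

        warnings.warn(f"skipped {skipped} samples with invalid segmenter output")
    return samples


def model_failures_to_manifest(samples, out_dir, split: str = "train") -> pd.DataFrame:
    """Write model-failure samples (frames, GT and candidate masks) to disk."""
    from pathlib import Path

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    for i, s in enumerate(samples):
        fr, gtr, cr = (
            f"frame_{i:05d}.png",
            f"gt_{i:05d}.png",
            f"candidate_{i:05d}.png",
        )
        data.write_frame(out_dir / fr, s.frame)
        data.write_mask(out_dir / gtr, s.gt_mask)
        data.write_mask(out_dir / cr, s.candidate_mask)
        rows.append(
            {
                "frame_path": fr,
                "gt_mask_path": gtr,
                "candidate_mask_path": cr,
                "iou": s.iou,
                "split": split,
            }
        )
    manifest = pd.DataFrame(rows, columns=data.SCORED_COLUMNS)
    data.write_scored_manifest(out_dir / "manifest.csv", manifest)
    manifest.attrs["root"] = str(out_dir)
    return manifest
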