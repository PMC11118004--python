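"""Synthetic laryngoscopy phantoms: frame/ground-truth-mask pairs.

Real high-speed videolaryngoscopy frames show a dark, roughly elliptical
glottal opening between brighter vocal-fold tissue on a noisy, textured
background; the opening varies in size and is absent when the folds are
closed. The generator emulates exactly that structure — and nothing more —
so that every downstream stage (perturbation, degradation, training,
evaluation) is testable without clinical data.

Geometry: the opening is a rotated super-ellipse (exponent sampled around
2) with a low-amplitude radial boundary perturbation, deliberately *not*
a plain ellipse so that the ellipse-insertion corruption operator cannot
trivially reproduce ground truth. The mask area fraction is driven into
the configured range by bisection on the shape scale, so non-empty masks
always satisfy the range exactly. With probability ``closed_probability``
the glottis is closed: the mask is empty and the frame shows only the
fold seam.

Frames are quantized to the 8-bit grid before being returned, so writing
and re-reading PNGs is bit-exact.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage

from . import data
from .metrics import as_frame, as_mask

__all__ = ["GlottisPhantomParams", "generate_pair", "generate_dataset"]


@dataclass(frozen=True)
class GlottisPhantomParams:
    """Knobs of the phantom generator.

    All brightness values are gray levels in [0, 1]; the glottal opening
    must be darker than the folds. ``opening_area_range`` is the allowed
    mask area as a fraction of the image; it is enforced exactly for
    every non-empty mask.
    """

    image_size: int = 256
    opening_area_range: tuple[float, float] = (0.01, 0.08)
    closed_probability: float = 0.2
    fold_brightness: float = 0.55
    glottis_brightness: float = 0.15
    noise_sigma: float = 0.03
    texture_scale: float = 8.0
    texture_amplitude: float = 0.05
    seed: int = 0

    def __post_init__(self):
        if self.image_size < 8:
            raise ValueError(f"image_size must be >= 8, got {self.image_size}")
        lo, hi = self.opening_area_range
        if not (0.0 <= lo < hi < 1.0) or hi > 0.15:
            raise ValueError(
                "opening_area_range must satisfy 0 <= lo < hi <= 0.15, "
                f"got {self.opening_area_range}"
            )
        if not 0.0 <= self.closed_probability <= 1.0:
            raise ValueError(
                f"closed_probability must be in [0, 1], got {self.closed_probability}"
            )
        for name in ("fold_brightness", "glottis_brightness"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.glottis_brightness >= self.fold_brightness:
            raise ValueError(
                "invariant violated: glottis_brightness must be strictly below "
                f"fold_brightness ({self.glottis_brightness} >= {self.fold_brightness})"
            )
        if self.noise_sigma < 0:
            raise ValueError(f"noise_sigma must be >= 0, got {self.noise_sigma}")
        if self.texture_scale <= 0:
            raise ValueError(f"texture_scale must be > 0, got {self.texture_scale}")


def _boundary_radius(theta, rot, semi_minor, semi_major, exponent, pert_coeffs):
    """Radius of the perturbed super-ellipse boundary at polar angle theta."""
    c = np.cos(theta - rot)
    s = np.sin(theta - rot)
    r_se = (np.abs(c / semi_minor) ** exponent + np.abs(s / semi_major) ** exponent) ** (
        -1.0 / exponent
    )
    pert = np.zeros_like(theta)
    for k, (amp, phase) in enumerate(pert_coeffs, start=2):
        pert += amp * np.sin(k * theta + phase)
    return r_se * (1.0 + pert)


def _sample_shape(params: GlottisPhantomParams, rng: np.random.Generator):
    n = params.image_size
    cy = n / 2 + rng.uniform(-0.08, 0.08) * n
    cx = n / 2 + rng.uniform(-0.08, 0.08) * n
    aspect = rng.uniform(0.2, 0.5)  # glottis is elongated
    rot = np.deg2rad(rng.uniform(-20.0, 20.0))  # near-vertical major axis
    exponent = rng.uniform(1.7, 2.8)
    pert_coeffs = [(rng.uniform(0.0, 0.06), rng.uniform(0, 2 * np.pi)) for _ in range(3)]
    return cy, cx, aspect, rot, exponent, pert_coeffs


def _rasterize_opening(params, rng, target_fraction):
    """Bisection on the shape scale until the mask area hits the range."""
    n = params.image_size
    cy, cx, aspect, rot, exponent, pert_coeffs = _sample_shape(params, rng)
    yy, xx = np.mgrid[0:n, 0:n]
    dy = yy - cy
    dx = xx - cx
    r = np.hypot(dx, dy)
    theta = np.arctan2(dy, dx)
    # Unit-scale boundary: semi-major 1, semi-minor = aspect, rotated so the
    # major axis is near-vertical (x-axis of the shape frame is the minor one).
    base = _boundary_radius(theta, rot + np.pi / 2, aspect, 1.0, exponent, pert_coeffs)
    lo_f, hi_f = params.opening_area_range
    total = n * n
    s_lo, s_hi = 0.0, float(n)
    mask = np.zeros((n, n), dtype=bool)
    for _ in range(60):
        s = 0.5 * (s_lo + s_hi)
        mask = r <= s * base
        frac = mask.sum() / total
        if lo_f < frac < hi_f and abs(frac - target_fraction) < 0.1 * (hi_f - lo_f):
            break
        if frac < target_fraction:
            s_lo = s
        else:
            s_hi = s
    frac = mask.sum() / total
    if not (lo_f <= frac <= hi_f) or not mask.any():
        raise RuntimeError(  # pragma: no cover - bisection failed to converge
            f"phantom area fraction {frac:.5f} escaped range {params.opening_area_range}"
        )
    return mask, (cy, cx, rot)


def _render_frame(params, rng, mask, geometry):
    n = params.image_size
    cy, cx, rot, *_ = geometry
    yy, xx = np.mgrid[0:n, 0:n]
    # Fold band: a vertical-ish bright corridor around the opening.
    u = (xx - cx) * np.cos(rot) + (yy - cy) * np.sin(rot)
    half_width = rng.uniform(0.18, 0.28) * n
    fold_band = np.abs(u) <= half_width
    img = np.full((n, n), 0.72 * params.fold_brightness)
    img[fold_band] = params.fold_brightness
    if mask.any():
        img[mask] = params.glottis_brightness
    else:
        # Closed glottis: a thin dark seam along the fold midline.
        seam = np.abs(u) <= max(1.0, 0.006 * n)
        img[seam] = 0.5 * (params.glottis_brightness + params.fold_brightness)
    img = ndimage.gaussian_filter(img, sigma=1.0)
    texture = ndimage.gaussian_filter(rng.standard_normal((n, n)), params.texture_scale)
    tstd = texture.std()
    if tstd > 0:
        img = img + params.texture_amplitude * texture / tstd
    if params.noise_sigma > 0:
        img = img + rng.normal(0.0, params.noise_sigma, size=(n, n))
    return data.quantize_frame(np.clip(img, 0.0, 1.0))


def generate_pair(
    params: GlottisPhantomParams, rng: np.random.Generator | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Draw one (frame, ground-truth mask) phantom pair.

    With probability ``closed_probability`` the mask is empty (closed
    glottis). Otherwise the mask is a perturbed rotated super-ellipse
    whose area fraction lies inside ``opening_area_range``. The frame is
    a [0, 1] grayscale rendering (8-bit quantized) in which the mask
    region is darker than its surroundings.
    """
    if rng is None:
        rng = np.random.default_rng(params.seed)
    n = params.image_size
    closed = rng.random() < params.closed_probability
    if closed:
        geometry = _sample_shape(params, rng)[:4]  # consume shape draws anyway
        mask = np.zeros((n, n), dtype=bool)
        cy, cx, _, rot = geometry
        frame = _render_frame(params, rng, mask, (cy, cx, rot))
        return frame, mask
    lo_f, hi_f = params.opening_area_range
    width = hi_f - lo_f
    target = rng.uniform(lo_f + 0.15 * width, hi_f - 0.15 * width)
    mask, geometry = _rasterize_opening(params, rng, target)
    frame = _render_frame(params, rng, mask, geometry)
    return as_frame(frame), as_mask(mask)


def generate_dataset(
    n: int,
    params: GlottisPhantomParams,
    out_dir,
    rng: np.random.Generator | None = None,
    split: str = "train",
) -> pd.DataFrame:
    """Write *n* phantom pairs plus a ``manifest.csv`` under *out_dir*.

    Returns the manifest (paths relative to *out_dir*). Re-reading the
    PNGs reproduces the in-memory arrays bit-exactly.
    """
    if n < 1:
        raise ValueError(f"n must be >= 1, got {n}")
    if rng is None:
        rng = np.random.default_rng(params.seed)
    out_dir = Path(out_dir)
    try:
        out_dir.mkdir(parents=True, exist_ok=True)
        probe = out_dir / ".write_probe"
        probe.touch()
        probe.unlink()
    except OSError as exc:
        raise OSError(f"output directory {out_dir} is not writable: {exc}") from exc
    rows = []
    for i in range(n):
        frame, mask = generate_pair(params, rng)
        frame_rel = f"frame_{i:05d}.png"
        mask_rel = f"mask_{i:05d}.png"
        data.write_frame(out_dir / frame_rel, frame)
        data.write_mask(out_dir / mask_rel, mask)
        rows.append({"frame_path": frame_rel, "mask_path": mask_rel, "split": split})
    manifest = pd.DataFrame(rows, columns=data.PAIR_COLUMNS)
    data.write_pair_manifest(out_dir / "manifest.csv", manifest)
    manifest.attrs["root"] = str(out_dir)
    return manifest
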