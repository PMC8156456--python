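"""Deterministic generator of dermoscopy-like image/mask pairs.

Each sample is a skin-tone background with a smooth illumination gradient
and one star-convex lesion whose boundary radius is a harmonically
perturbed circle r(theta) = r0 * (1 + sum_j a_j sin(k_j theta + phi_j)).
Hair curves, bright bubbles and optional ruler ticks are overlaid *after*
the mask is rasterised, mirroring clinician ground truth where occluders do
not change the lesion outline.

All randomness flows through ``numpy.random.default_rng`` (PCG64), so a
fixed seed reproduces samples bit-for-bit on any platform with the same
numpy generator.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from PIL import Image
from scipy import ndimage

__all__ = ["SyntheticParams", "LesionSample", "generate_lesion_sample", "generate_dataset"]

# fixed RGB gamuts (uint8) -- documented constants, no external references
SKIN_LO = np.array([185.0, 135.0, 105.0])
SKIN_HI = np.array([230.0, 180.0, 150.0])
LESION_LO = np.array([80.0, 50.0, 35.0])
LESION_HI = np.array([150.0, 105.0, 85.0])


@dataclass
class SyntheticParams:
    image_size: int = 256
    area_range: tuple = (0.05, 0.35)
    harmonics: int = 5
    boundary_amplitude: float = 0.18   # total radial perturbation budget
    hair_count: int = 5
    hair_thickness: int = 2
    bubble_count: int = 3
    ruler_ticks: int = 0
    noise_sigma: float = 4.0
    contrast_gap: float = 60.0   # minimum skin-vs-lesion channel gap (uint8 units)

    def __post_init__(self):
        amin, amax = self.area_range
        if not (0.0 < amin < amax < 0.9):
            raise ValueError("area_range must satisfy 0 < amin < amax < 0.9")
        for name in ("harmonics", "hair_count", "hair_thickness", "bubble_count", "ruler_ticks"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be >= 0")
        if self.contrast_gap <= 0:
            raise ValueError("contrast_gap must be > 0")
        if self.image_size < 16:
            raise ValueError("image_size must be >= 16")


@dataclass
class LesionSample:
    image: np.ndarray        # (H,W,3) uint8
    mask: np.ndarray         # (H,W) uint8 {0,1}
    metadata: dict = field(default_factory=dict)


def _smooth_noise(rng, shape, sigma):
    return ndimage.gaussian_filter(rng.standard_normal(shape), sigma)


def _rasterize_lesion(rng, p: SyntheticParams):
    """Returns (mask, area_fraction, meta) or None if out of range."""
    n = p.image_size
    amin, amax = p.area_range
    target = rng.uniform(amin, amax)
    r0 = np.sqrt(target * n * n / np.pi)
    cy = rng.uniform(0.32 * n, 0.68 * n)
    cx = rng.uniform(0.32 * n, 0.68 * n)
    if p.harmonics > 0:
        raw = rng.uniform(0.3, 1.0, p.harmonics)
        amps = raw / raw.sum() * p.boundary_amplitude
        ks = rng.integers(2, 7, p.harmonics)
        phases = rng.uniform(0, 2 * np.pi, p.harmonics)
    else:
        amps = np.zeros(0)
        ks = np.zeros(0, dtype=int)
        phases = np.zeros(0)
    yy, xx = np.mgrid[0:n, 0:n]
    dy, dx = yy - cy, xx - cx
    theta = np.arctan2(dy, dx)
    rad = np.hypot(dy, dx)
    boundary = r0 * (1.0 + sum(a * np.sin(k * theta + ph)
                               for a, k, ph in zip(amps, ks, phases)))
    mask = (rad <= boundary).astype(np.uint8)
    frac = float(mask.mean())
    if not (amin <= frac <= amax):
        return None
    meta = {"area_fraction": frac, "r0": float(r0), "center": (float(cy), float(cx))}
    return mask, frac, meta


def _draw_hair(rng, img, n, thickness):
    """One dark quadratic curve across the field."""
    pts = rng.uniform(0, n, (3, 2))
    t = np.linspace(0, 1, 4 * n)[:, None]
    curve = ((1 - t) ** 2 * pts[0] + 2 * t * (1 - t) * pts[1] + t ** 2 * pts[2])
    shade = rng.uniform(15, 60)
    alpha = rng.uniform(0.6, 0.95)
    canvas = np.zeros((n, n), dtype=bool)
    ij = np.round(curve).astype(int)
    ij = ij[(ij[:, 0] >= 0) & (ij[:, 0] < n) & (ij[:, 1] >= 0) & (ij[:, 1] < n)]
    canvas[ij[:, 0], ij[:, 1]] = True
    if thickness > 1:
        canvas = ndimage.binary_dilation(canvas, iterations=thickness - 1)
    img[canvas] = (1 - alpha) * img[canvas] + alpha * shade


def _draw_bubble(rng, img, n):
    cy, cx = rng.uniform(0, n, 2)
    radius = rng.uniform(3, max(4.0, 0.035 * n))
    yy, xx = np.mgrid[0:n, 0:n]
    d = np.hypot(yy - cy, xx - cx)
    inside = d <= radius
    rim = (d <= radius) & (d >= radius - 1.5)
    img[inside] = np.minimum(img[inside] * 0.35 + 0.65 * 235.0, 255.0)
    img[rim] = np.minimum(img[rim] + 40.0, 255.0)


def generate_lesion_sample(params: SyntheticParams, seed: int) -> LesionSample:
    rng = np.random.default_rng(seed)
    n = params.image_size

    # lesion geometry first (rejection-sampled into the area window)
    result = None
    for _ in range(100):
        result = _rasterize_lesion(rng, params)
        if result is not None:
            break
    if result is None:
        raise RuntimeError("could not place a lesion inside the area range in 100 attempts")
    mask, frac, meta = result

    # background: skin tone + illumination gradient
    skin = rng.uniform(SKIN_LO, SKIN_HI)
    yy, xx = np.mgrid[0:n, 0:n]
    angle = rng.uniform(0, 2 * np.pi)
    ramp = (np.cos(angle) * (xx - n / 2) + np.sin(angle) * (yy - n / 2)) / n
    illum = 1.0 + rng.uniform(0.05, 0.15) * ramp
    vign = 1.0 - rng.uniform(0.0, 0.08) * ((np.hypot(yy - n / 2, xx - n / 2) / (0.7 * n)) ** 2)
    img = skin[None, None, :] * (illum * vign)[..., None]

    # lesion fill: darker than skin by construction, plus internal texture
    lesion = rng.uniform(np.minimum(LESION_LO, skin - params.contrast_gap - 1.0),
                         np.minimum(LESION_HI, skin - params.contrast_gap))
    texture = _smooth_noise(rng, (n, n), 0.02 * n) * 60.0
    soft = ndimage.gaussian_filter(mask.astype(np.float64), 0.008 * n + 1.0)
    opacity = rng.uniform(0.85, 0.97)
    fill = lesion[None, None, :] + texture[..., None]
    img = img * (1.0 - opacity * soft[..., None]) + fill * opacity * soft[..., None]

    # artifacts drawn after the mask was fixed
    for _ in range(params.hair_count):
        _draw_hair(rng, img, n, params.hair_thickness)
    for _ in range(params.bubble_count):
        _draw_bubble(rng, img, n)
    for k in range(params.ruler_ticks):
        x0 = int((k + 1) * n / (params.ruler_ticks + 1))
        img[2:10, max(x0 - 1, 0) : x0 + 1] = 245.0

    if params.noise_sigma > 0:
        img = img + rng.normal(0.0, params.noise_sigma, img.shape)
    img = np.clip(np.round(img), 0, 255).astype(np.uint8)

    meta.update({
        "seed": int(seed),
        "hairs": params.hair_count,
        "bubbles": params.bubble_count,
        "ruler_ticks": params.ruler_ticks,
    })
    return LesionSample(image=img, mask=mask, metadata=meta)


def generate_dataset(n: int, params: SyntheticParams, seed: int, out_dir=None):
    """n samples with per-sample seeds ``seed + index``; optionally written
    to ``out_dir`` as PNGs plus a CSV manifest.  Returns (samples, manifest)."""
    if n < 1:
        raise ValueError("n must be >= 1")
    samples = [generate_lesion_sample(params, seed + i) for i in range(n)]
    rows = []
    for i, s in enumerate(samples):
        digest = hashlib.sha256(s.image.tobytes() + s.mask.tobytes()).hexdigest()[:16]
        rows.append({
            "index": i,
            "seed": s.metadata["seed"],
            "area_fraction": s.metadata["area_fraction"],
            "sha256_16": digest,
            "image": f"image_{i:04d}.png",
            "mask": f"mask_{i:04d}.png",
        })
    manifest = pd.DataFrame(rows)
    if out_dir is not None:
        from pathlib import Path

        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for i, s in enumerate(samples):
            Image.fromarray(s.image).save(out / f"image_{i:04d}.png")
            Image.fromarray(s.mask * 255).save(out / f"mask_{i:04d}.png")
        manifest.to_csv(out / "manifest.csv", index=False)
    return samples, manifest
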