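"""Input standardisation and the 8x training-set expansion.

Images are scaled so the width becomes 256 px (aspect ratio preserved,
bilinear), then padded with black rows split between top and bottom to a
256x256 canvas; portrait inputs are handled by the symmetric rule (height
to 256, black columns left/right).  Masks follow the same geometry with
nearest-neighbour resampling and re-binarisation at 128.

The training expansion emits, per standardized pair, an RGB and an HSV
copy, each under the 4-member flip family (identity, horizontal, vertical,
both): exactly 8N pairs, ordered by (source index, color space, flip code).
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from PIL import Image

__all__ = [
    "StandardizedImage",
    "resize_and_pad",
    "rgb_to_hsv_image",
    "hsv_to_rgb_array",
    "flip_family",
    "FLIP_CODES",
    "build_training_set",
    "AugmentedDataset",
]

TARGET = 256
FLIP_CODES = ("none", "horizontal", "vertical", "both")


@dataclass
class StandardizedImage:
    pixels: np.ndarray                  # (256,256,3) uint8
    mask: np.ndarray | None             # (256,256) uint8 {0,1}, same geometry
    pad_top: int
    pad_bottom: int
    pad_left: int
    pad_right: int
    original_size: tuple                # (width, height)
    color_space: str = "RGB"


def _round_half_away(x: float) -> int:
    return int(np.floor(x + 0.5))


def resize_and_pad(image, mask=None, target: int = TARGET) -> StandardizedImage:
    """Standardise an RGB image (H,W,3 uint8 array or PIL image) to target^2."""
    if isinstance(image, Image.Image):
        image = np.asarray(image.convert("RGB"))
    image = np.asarray(image)
    if image.ndim != 3 or image.shape[2] != 3:
        raise ValueError(f"expected an (H,W,3) RGB image, got shape {image.shape}")
    if image.size == 0:
        raise ValueError("empty image")
    h, w = image.shape[:2]

    new_w = target
    new_h = _round_half_away(target * h / w)
    if new_h > target:  # portrait after scaling: fix height, pad the width
        new_h = target
        new_w = _round_half_away(target * w / h)

    pil = Image.fromarray(image.astype(np.uint8))
    resized = np.asarray(pil.resize((new_w, new_h), Image.BILINEAR))

    pad_v = target - new_h
    pad_h = target - new_w
    pad_top, pad_bottom = pad_v // 2, pad_v - pad_v // 2
    pad_left, pad_right = pad_h // 2, pad_h - pad_h // 2
    canvas = np.zeros((target, target, 3), dtype=np.uint8)
    canvas[pad_top : pad_top + new_h, pad_left : pad_left + new_w] = resized

    out_mask = None
    if mask is not None:
        mask = np.asarray(mask)
        if mask.shape[:2] != (h, w):
            raise ValueError("mask geometry does not match the image")
        mpil = Image.fromarray((np.asarray(mask) > 0).astype(np.uint8) * 255)
        mres = np.asarray(mpil.resize((new_w, new_h), Image.NEAREST))
        mcanvas = np.zeros((target, target), dtype=np.uint8)
        mcanvas[pad_top : pad_top + new_h, pad_left : pad_left + new_w] = (mres >= 128).astype(np.uint8)
        out_mask = mcanvas

    return StandardizedImage(
        pixels=canvas, mask=out_mask,
        pad_top=pad_top, pad_bottom=pad_bottom, pad_left=pad_left, pad_right=pad_right,
        original_size=(w, h), color_space="RGB",
    )


# ---------------------------------------------------------------------------
# color space
# ---------------------------------------------------------------------------

def rgb_to_hsv_array(rgb: np.ndarray) -> np.ndarray:
    """Vectorised 8-bit RGB -> 8-bit HSV (H scaled to 0..255)."""
    x = rgb.astype(np.float64) / 255.0
    r, g, b = x[..., 0], x[..., 1], x[..., 2]
    v = x.max(axis=-1)
    c = v - x.min(axis=-1)
    s = np.where(v > 0, c / np.where(v > 0, v, 1.0), 0.0)
    hp = np.zeros_like(v)
    nz = c > 0
    rmax = nz & (v == r)
    gmax = nz & (v == g) & ~rmax
    bmax = nz & ~(rmax | gmax)
    cc = np.where(nz, c, 1.0)
    hp[rmax] = (((g - b) / cc) % 6.0)[rmax]
    hp[gmax] = ((b - r) / cc + 2.0)[gmax]
    hp[bmax] = ((r - g) / cc + 4.0)[bmax]
    h = hp / 6.0
    out = np.stack([h, s, v], axis=-1)
    return np.clip(np.round(out * 255.0), 0, 255).astype(np.uint8)


def hsv_to_rgb_array(hsv: np.ndarray) -> np.ndarray:
    """Inverse of :func:`rgb_to_hsv_array` up to 8-bit quantisation."""
    x = hsv.astype(np.float64) / 255.0
    h, s, v = x[..., 0] * 6.0, x[..., 1], x[..., 2]
    c = v * s
    xx = c * (1.0 - np.abs(h % 2.0 - 1.0))
    m = v - c
    zeros = np.zeros_like(c)
    idx = np.floor(h).astype(int) % 6
    r = np.choose(idx, [c, xx, zeros, zeros, xx, c])
    g = np.choose(idx, [xx, c, c, xx, zeros, zeros])
    b = np.choose(idx, [zeros, zeros, xx, c, c, xx])
    rgb = np.stack([r + m, g + m, b + m], axis=-1)
    return np.clip(np.round(rgb * 255.0), 0, 255).astype(np.uint8)


def rgb_to_hsv_image(image: StandardizedImage) -> StandardizedImage:
    if image.color_space != "RGB":
        raise ValueError("input is already HSV; refusing a double conversion")
    return replace(image, pixels=rgb_to_hsv_array(image.pixels), color_space="HSV")


# ---------------------------------------------------------------------------
# flips
# ---------------------------------------------------------------------------

def apply_flip(arr: np.ndarray, code: str) -> np.ndarray:
    if code == "none":
        return arr.copy()
    if code == "horizontal":
        return arr[:, ::-1].copy()
    if code == "vertical":
        return arr[::-1, :].copy()
    if code == "both":
        return arr[::-1, ::-1].copy()
    raise ValueError(f"unknown flip code {code!r}")


def flip_family(image: np.ndarray, mask: np.ndarray | None = None):
    """[original, horizontal, vertical, both]; masks transformed identically."""
    images = [apply_flip(image, code) for code in FLIP_CODES]
    if mask is None:
        return images
    masks = [apply_flip(mask, code) for code in FLIP_CODES]
    return images, masks


# ---------------------------------------------------------------------------
# training-set expansion
# ---------------------------------------------------------------------------

class AugmentedDataset:
    """Lazy 8x expansion of standardized pairs.

    Item ``j`` decodes to (source ``j // 8``, color space ``(j // 4) % 2``
    with 0=RGB/1=HSV, flip code ``j % 4``); nothing is materialised until
    indexed, so counting is O(1) and iteration is constant-memory.
    """

    def __init__(self, standardized: list):
        if not standardized:
            raise ValueError("need at least one standardized pair")
        for s in standardized:
            if s.mask is None:
                raise ValueError("training expansion requires masks for every image")
            if s.color_space != "RGB":
                raise ValueError("expansion expects RGB standardized inputs")
        self.sources = list(standardized)

    def __len__(self) -> int:
        return 8 * len(self.sources)

    def description(self, j: int) -> tuple:
        src, rem = divmod(j, 8)
        space = "RGB" if rem < 4 else "HSV"
        return src, space, FLIP_CODES[rem % 4]

    def __getitem__(self, j: int):
        if not 0 <= j < len(self):
            raise IndexError(j)
        src_idx, space, code = self.description(j)
        s = self.sources[src_idx]
        pixels = s.pixels if space == "RGB" else rgb_to_hsv_array(s.pixels)
        return apply_flip(pixels, code), apply_flip(s.mask, code)

    def manifest(self):
        import pandas as pd

        rows = [dict(zip(("source_index", "color_space", "flip_code"), self.description(j)))
                for j in range(len(self))]
        return pd.DataFrame(rows)


def build_training_set(images, masks=None) -> AugmentedDataset:
    """8x expansion (RGB+HSV, 4 flips each) of standardized image/mask pairs.

    Accepts a list of :class:`StandardizedImage` (with masks attached) or
    parallel lists of images and masks.
    """
    if masks is not None:
        images = list(images)
        masks = list(masks)
        if len(images) != len(masks):
            raise ValueError(f"{len(images)} images but {len(masks)} masks")
        std = []
        for img, m in zip(images, masks):
            if isinstance(img, StandardizedImage):
                std.append(replace(img, mask=np.asarray(m).astype(np.uint8)))
            else:
                std.append(StandardizedImage(
                    pixels=np.asarray(img, dtype=np.uint8),
                    mask=(np.asarray(m) > 0).astype(np.uint8),
                    pad_top=0, pad_bottom=0, pad_left=0, pad_right=0,
                    original_size=(np.asarray(img).shape[1], np.asarray(img).shape[0])))
        return AugmentedDataset(std)
    return AugmentedDataset(list(images))
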