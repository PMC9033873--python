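"""Stochastic training-time image augmentation for viability regression.

The policy applies, in order: a random 90-degree-multiple rotation, a random
crop to 70% of each dimension, independent horizontal/vertical flips, then
photometric jitter — brightness delta in [-0.2, 0.2], saturation factor in
[0.6, 1.6], contrast factor in [0.7, 1.3], and hue shift in [-0.08, 0.08]
of the hue circle.  Geometric operations permute pixels; photometric
operations are clipped to keep intensities in [0, 1].

Augmentation applies only to training images; evaluation images get a
deterministic center crop of the same size so train and test views share
scale without photometric leakage.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .simulate import PlateImage

__all__ = ["AugmentationPolicy", "crop_size", "augment_image", "center_crop"]

_LUMA = np.array([0.299, 0.587, 0.114])


@dataclass(frozen=True)
class AugmentationPolicy:
    """Numeric ranges of the stochastic augmentation policy."""

    crop_fraction: float = 0.7
    rotations: tuple[int, ...] = (0, 90, 180, 270)
    hflip_prob: float = 0.5
    vflip_prob: float = 0.5
    brightness_delta_range: tuple[float, float] = (-0.2, 0.2)
    saturation_factor_range: tuple[float, float] = (0.6, 1.6)
    contrast_factor_range: tuple[float, float] = (0.7, 1.3)
    hue_delta_range: tuple[float, float] = (-0.08, 0.08)

    def __post_init__(self) -> None:
        if not 0 < self.crop_fraction <= 1:
            raise ValueError("crop_fraction must be in (0, 1]")
        for name in (
            "brightness_delta_range", "saturation_factor_range",
            "contrast_factor_range", "hue_delta_range",
        ):
            lo, hi = getattr(self, name)
            if lo > hi:
                raise ValueError(f"{name} must be ordered (lo <= hi)")
        for name in ("hflip_prob", "vflip_prob"):
            p = getattr(self, name)
            if not 0 <= p <= 1:
                raise ValueError(f"{name} must be in [0, 1]")
        if any(r % 90 != 0 for r in self.rotations):
            raise ValueError("rotations must be multiples of 90 degrees")


def identity_policy() -> AugmentationPolicy:
    """Policy whose every draw is a pixel-level no-op (useful for testing)."""
    return AugmentationPolicy(
        crop_fraction=1.0,
        rotations=(0,),
        hflip_prob=0.0,
        vflip_prob=0.0,
        brightness_delta_range=(0.0, 0.0),
        saturation_factor_range=(1.0, 1.0),
        contrast_factor_range=(1.0, 1.0),
        hue_delta_range=(0.0, 0.0),
    )


def crop_size(height_px: int, width_px: int, crop_fraction: float) -> tuple[int, int]:
    """Crop dimensions: floor(fraction * dim) per axis, at least 1 px.

    E.g. a 2160 x 2560 image at fraction 0.7 crops to 1512 x 1792.
    """
    if height_px <= 0 or width_px <= 0:
        raise ValueError("dimensions must be positive")
    return (
        max(1, int(np.floor(crop_fraction * height_px))),
        max(1, int(np.floor(crop_fraction * width_px))),
    )


try:  # single-pass hue rotation; the numpy HSV round-trip is the fallback
    from numba import njit

    @njit(cache=True)
    def _hue_shift_jit(px: np.ndarray, delta: float) -> np.ndarray:  # pragma: no cover
        out = np.empty_like(px)
        for i in range(px.shape[0]):
            for j in range(px.shape[1]):
                r, g, b = px[i, j, 0], px[i, j, 1], px[i, j, 2]
                mx = max(r, g, b)
                mn = min(r, g, b)
                d = mx - mn
                if d == 0.0:
                    h = 0.0
                elif mx == r:
                    h = ((g - b) / d) % 6.0
                elif mx == g:
                    h = (b - r) / d + 2.0
                else:
                    h = (r - g) / d + 4.0
                s = 0.0 if mx == 0.0 else d / mx
                h6 = ((h / 6.0 + delta) % 1.0) * 6.0
                for ch in range(3):
                    n = 5.0 if ch == 0 else (3.0 if ch == 1 else 1.0)
                    k = (n + h6) % 6.0
                    k = min(k, 4.0 - k)
                    k = min(max(k, 0.0), 1.0)
                    out[i, j, ch] = mx - mx * s * k
        return out

except ImportError:  # pragma: no cover
    _hue_shift_jit = None


def _rgb_to_hsv(px: np.ndarray) -> np.ndarray:
    """Vectorized RGB -> HSV on [0,1] floats (hue in [0,1))."""
    r, g, b = px[..., 0], px[..., 1], px[..., 2]
    maxc = px.max(axis=-1)
    minc = px.min(axis=-1)
    delta = maxc - minc
    safe = np.where(delta == 0, 1.0, delta)
    h = np.zeros_like(maxc)
    rmax = (maxc == r)
    gmax = (maxc == g) & ~rmax
    bmax = ~(rmax | gmax)
    h[rmax] = ((g - b)[rmax] / safe[rmax]) % 6.0
    h[gmax] = (b - r)[gmax] / safe[gmax] + 2.0
    h[bmax] = (r - g)[bmax] / safe[bmax] + 4.0
    h = np.where(delta == 0, 0.0, h / 6.0)
    s = np.where(maxc == 0, 0.0, delta / np.where(maxc == 0, 1.0, maxc))
    return np.stack([h, s, maxc], axis=-1)


def _hsv_to_rgb(hsv: np.ndarray) -> np.ndarray:
    # branch-free form: channel n is v - v*s*clip(min(k, 4-k), 0, 1),
    # k = (n + 6h) mod 6 with n = 5, 3, 1 for R, G, B
    h, s, v = hsv[..., 0] * 6.0, hsv[..., 1], hsv[..., 2]
    vs = v * s
    out = np.empty(hsv.shape)
    for ch, n in ((0, 5.0), (1, 3.0), (2, 1.0)):
        k = np.mod(n + h, 6.0)
        out[..., ch] = v - vs * np.clip(np.minimum(k, 4.0 - k), 0.0, 1.0)
    return out


def _apply_photometrics(
    px: np.ndarray, brightness: float, saturation: float,
    contrast: float, hue: float,
) -> np.ndarray:
    if brightness == 0.0 and saturation == 1.0 and contrast == 1.0 and hue == 0.0:
        return np.clip(px, 0.0, 1.0)  # identity draw: bit-exact no-op
    # brightness, saturation, and contrast compose into one affine pass:
    #   x1 = s*(px + b) + (1-s)*(gray + b);  out = m1 + c*(x1 - m1)
    gray = px @ _LUMA
    m1 = saturation * (px.mean() + brightness) + (1 - saturation) * (
        gray.mean() + brightness
    )
    out = (
        contrast * saturation * px
        + (contrast * (1.0 - saturation)) * gray[..., None]
        + (contrast * brightness + (1.0 - contrast) * m1)
    )
    # HSV math needs [0,1] inputs, so clip before the hue rotation
    out = np.clip(out, 0.0, 1.0)
    if hue != 0.0:
        if _hue_shift_jit is not None:
            out = _hue_shift_jit(np.ascontiguousarray(out), hue)
        else:
            hsv = _rgb_to_hsv(out)
            hsv[..., 0] = np.mod(hsv[..., 0] + hue, 1.0)
            out = _hsv_to_rgb(hsv)
    return np.clip(out, 0.0, 1.0)


def augment_image(
    image: PlateImage,
    policy: AugmentationPolicy,
    rng: np.random.Generator,
) -> PlateImage:
    """One stochastic augmented view; a fixed rng stream fixes the view.

    Order: rotation -> crop at a uniform valid offset -> flips ->
    brightness/saturation/contrast/hue jitter with parameters drawn
    uniformly from the policy ranges.
    """
    px = image.pixels
    k = int(rng.choice(len(policy.rotations)))
    px = np.rot90(px, k=policy.rotations[k] // 90, axes=(0, 1))

    h, w = px.shape[:2]
    ch, cw = crop_size(h, w, policy.crop_fraction)
    if ch > h or cw > w:
        raise ValueError("crop larger than image")
    oy = int(rng.integers(0, h - ch + 1))
    ox = int(rng.integers(0, w - cw + 1))
    px = px[oy:oy + ch, ox:ox + cw]

    if rng.random() < policy.hflip_prob:
        px = px[:, ::-1]
    if rng.random() < policy.vflip_prob:
        px = px[::-1, :]

    brightness = float(rng.uniform(*policy.brightness_delta_range))
    saturation = float(rng.uniform(*policy.saturation_factor_range))
    contrast = float(rng.uniform(*policy.contrast_factor_range))
    hue = float(rng.uniform(*policy.hue_delta_range))
    out = _apply_photometrics(np.ascontiguousarray(px, dtype=float),
                              brightness, saturation, contrast, hue)
    return PlateImage(out)


def center_crop(image: PlateImage, crop_fraction: float) -> PlateImage:
    """Deterministic center crop used for validation/test views."""
    h, w = image.pixels.shape[:2]
    ch, cw = crop_size(h, w, crop_fraction)
    oy = (h - ch) // 2
    ox = (w - cw) // 2
    return PlateImage(np.ascontiguousarray(image.pixels[oy:oy + ch, ox:ox + cw]))
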