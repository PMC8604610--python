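"""Per-frame geometric corrections: undistortion, rotation, crop.

The trackway camera is a wide-angle action camera, so frames carry mild
barrel distortion.  A single-coefficient radial (Brown-Conrady with only k1)
model is used: an output pixel at normalised radius rho samples the source at
radius rho * (1 + k1 * rho**2), with bilinear interpolation and black fill.
Rotation levels the trackway; cropping keeps only the glass band.
"""

from __future__ import annotations

import math

import numpy as np
from scipy import ndimage

from .config import ConfigError, PreprocessConfig
from .frames import FrameImage

__all__ = [
    "correct_distortion",
    "apply_barrel_distortion",
    "rotate_frame",
    "crop_band",
    "preprocess_frame",
    "preview_stages",
]


def _radius_norm(height: int, width: int) -> tuple[float, float, float]:
    cy = (height - 1) / 2.0
    cx = (width - 1) / 2.0
    rn = math.hypot(cx, cy) or 1.0  # half-diagonal, so rho in [0, 1]
    return cy, cx, rn


def _sample(pixels: np.ndarray, ys: np.ndarray, xs: np.ndarray) -> np.ndarray:
    out = np.empty_like(pixels)
    for c in range(pixels.shape[2]):
        ch = ndimage.map_coordinates(
            pixels[:, :, c].astype(np.float64), [ys, xs], order=1, mode="constant", cval=0.0
        )
        out[:, :, c] = np.clip(np.round(ch), 0, 255).astype(np.uint8)
    return out


def correct_distortion(img: FrameImage, k1: float) -> FrameImage:
    """Remove barrel distortion with radial coefficient ``k1``.

    The image centre is a fixed point for any k1, and k1 = 0 is a bit-exact
    identity.  Output pixels whose source falls outside the frame are black.
    """
    if not math.isfinite(k1):
        raise ConfigError("distortion coefficient k1 must be finite")
    if k1 == 0:
        return img.with_pixels(img.pixels.copy())
    h, w = img.height, img.width
    cy, cx, rn = _radius_norm(h, w)
    yy, xx = np.mgrid[0:h, 0:w].astype(np.float64)
    dy, dx = yy - cy, xx - cx
    rho2 = (dx * dx + dy * dy) / (rn * rn)
    f = 1.0 + k1 * rho2
    return img.with_pixels(_sample(img.pixels, cy + dy * f, cx + dx * f))


def apply_barrel_distortion(img: FrameImage, k1: float) -> FrameImage:
    """Synthesise barrel distortion: the exact inverse warp of
    :func:`correct_distortion`, so warp-then-correct round-trips a test
    pattern.  Used by calibration previews and tests; the per-pixel inverse
    radius is found by Newton iteration on r * (1 + k1 * (r/rn)**2) = r_out.
    """
    if not math.isfinite(k1):
        raise ConfigError("distortion coefficient k1 must be finite")
    if k1 == 0:
        return img.with_pixels(img.pixels.copy())
    h, w = img.height, img.width
    cy, cx, rn = _radius_norm(h, w)
    yy, xx = np.mgrid[0:h, 0:w].astype(np.float64)
    dy, dx = yy - cy, xx - cx
    r_out = np.hypot(dx, dy)
    r = r_out.copy()
    for _ in range(30):
        g = r * (1.0 + k1 * (r * r) / (rn * rn)) - r_out
        gp = 1.0 + 3.0 * k1 * (r * r) / (rn * rn)
        step = g / gp
        r = r - step
        if np.max(np.abs(step)) < 1e-10:
            break
    with np.errstate(invalid="ignore", divide="ignore"):
        scale = np.where(r_out > 0, r / r_out, 1.0)
    return img.with_pixels(_sample(img.pixels, cy + dy * scale, cx + dx * scale))


def rotate_frame(img: FrameImage, degrees: float) -> FrameImage:
    """Rotate counter-clockwise (as displayed) by ``degrees``; black fill.

    Output dimensions equal the input's; bilinear interpolation.
    """
    if not math.isfinite(degrees):
        raise ConfigError("rotation angle must be finite")
    if degrees % 360 == 0:
        return img.with_pixels(img.pixels.copy())
    rot = ndimage.rotate(
        img.pixels.astype(np.float64),
        degrees,
        axes=(1, 0),
        reshape=False,
        order=1,
        mode="constant",
        cval=0.0,
        prefilter=False,
    )
    return img.with_pixels(np.clip(np.round(rot), 0, 255).astype(np.uint8))


def crop_band(img: FrameImage, y_top: int, y_bottom: int) -> FrameImage:
    """Crop to rows [y_top, y_bottom) — the glass trackway band."""
    if not (0 <= y_top < y_bottom <= img.height):
        raise ConfigError(
            f"crop band [{y_top}, {y_bottom}) outside image of height {img.height}"
        )
    return img.with_pixels(img.pixels[y_top:y_bottom].copy())


def preprocess_frame(img: FrameImage, cfg: PreprocessConfig) -> FrameImage:
    """Apply, in order: undistortion, rotation, crop to the trackway band.

    Output height is crop_y_bottom - crop_y_top regardless of pixel content.
    """
    cfg.validate(height=img.height)
    out = correct_distortion(img, cfg.distortion_k1)
    out = rotate_frame(out, cfg.rotation_deg)
    bottom = cfg.crop_y_bottom if cfg.crop_y_bottom is not None else img.height
    return crop_band(out, cfg.crop_y_top, bottom)


def preview_stages(img: FrameImage, cfg: PreprocessConfig) -> dict[str, FrameImage]:
    """Every intermediate stage of :func:`preprocess_frame`, for calibration.

    Replaces the interactive parameter-picking step of the original system:
    adjust the config, re-render the previews, repeat.
    """
    cfg.validate(height=img.height)
    undist = correct_distortion(img, cfg.distortion_k1)
    rotated = rotate_frame(undist, cfg.rotation_deg)
    bottom = cfg.crop_y_bottom if cfg.crop_y_bottom is not None else img.height
    cropped = crop_band(rotated, cfg.crop_y_top, bottom)
    return {
        "original": img,
        "undistorted": undist,
        "rotated": rotated,
        "cropped": cropped,
    }
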