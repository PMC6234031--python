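"""Background removal and vignetting (flat-field) correction.

The correction follows the two-step recipe used for the reporter time-lapse data:

1. subtract a per-channel *minimum intensity image* (the pixel-wise minimum over all
   frames of that channel, smoothed to suppress the noise bias of a pixel-wise
   minimum), flooring at zero;
2. divide by a *flat-field* image obtained by normalizing the (smoothed) minimum
   image to mean 1, which removes the intensity drop-off at the image border
   without altering the average image intensity.

Single-frame (endpoint) images have no minimum image; a tiled low-percentile
background estimate is used instead and flagged in the returned metadata.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .core import ImageStack

__all__ = [
    "CorrectionField",
    "minimum_projection",
    "smooth_min_image",
    "subtract_background",
    "flatfield_from_minimum",
    "apply_flatfield",
    "percentile_background",
    "derive_correction",
    "correct_stack",
]

FLATFIELD_MIN_GAIN = 0.05


@dataclass
class CorrectionField:
    """Per-channel background image and mean-1 flat-field gain."""

    background: np.ndarray
    flatfield: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.background = np.asarray(self.background, dtype=float)
        self.flatfield = np.asarray(self.flatfield, dtype=float)
        if self.background.shape != self.flatfield.shape:
            raise ValueError("background and flatfield shapes differ")
        if np.any(self.flatfield <= 0):
            raise ValueError("flatfield must be strictly positive")
        if abs(self.flatfield.mean() - 1.0) > 1e-6:
            raise ValueError("flatfield mean must be 1")


def _channel_frames(stack, channel):
    """(n, y, x) frames of one channel from an ImageStack, array, or list thereof."""
    if isinstance(stack, (list, tuple)):
        parts = [_channel_frames(s, channel) for s in stack]
        return np.concatenate(parts, axis=0)
    if isinstance(stack, ImageStack):
        return stack.channel(channel) if isinstance(channel, str) else stack.data[:, channel]
    arr = np.asarray(stack, dtype=float)
    if arr.ndim == 4:
        return arr[:, channel]
    if arr.ndim == 3:
        return arr
    raise ValueError("expected frames with shape (t, y, x) or (t, c, y, x)")


def minimum_projection(stack, channel=0) -> np.ndarray:
    """Pixel-wise minimum over all frames of one channel.

    ``stack`` may be an :class:`ImageStack`, a ``(t, y, x)``/``(t, c, y, x)`` array, or
    a list of stacks (frames pooled across fields, as when the minimum is taken over
    every image acquired in a channel). At least two frames are required — for a
    single frame use :func:`percentile_background` instead.
    """
    frames = _channel_frames(stack, channel)
    if frames.shape[0] < 2:
        raise ValueError(
            "minimum projection needs >= 2 frames; use percentile_background "
            "for single-frame (endpoint) images"
        )
    return frames.min(axis=0)


def smooth_min_image(min_image: np.ndarray, sigma: float) -> np.ndarray:
    """Gaussian-smooth a raw minimum image (pixel-wise minima are noise-biased)."""
    if sigma <= 0:
        return np.asarray(min_image, dtype=float)
    return ndimage.gaussian_filter(np.asarray(min_image, dtype=float), sigma=sigma)


def subtract_background(stack, background: np.ndarray):
    """Subtract a background image from every frame, flooring at zero.

    Accepts and returns the same container type (ImageStack in -> ImageStack out).
    """
    background = np.asarray(background, dtype=float)
    if isinstance(stack, ImageStack):
        if background.shape != stack.data.shape[-2:]:
            raise ValueError("background shape does not match frames")
        return stack.copy_with(np.maximum(stack.data - background, 0.0))
    arr = np.asarray(stack, dtype=float)
    if background.shape != arr.shape[-2:]:
        raise ValueError("background shape does not match frames")
    return np.maximum(arr - background, 0.0)


def flatfield_from_minimum(min_image: np.ndarray, smooth_sigma: float = 0.0) -> np.ndarray:
    """Flat-field gain: the (smoothed) minimum image normalized to mean 1.

    The gain is clamped from below at 0.05 before renormalization, so the returned
    field is strictly positive with mean exactly 1.
    """
    m = smooth_min_image(min_image, smooth_sigma)
    mean = m.mean()
    if mean <= 0:
        raise ValueError("minimum image has no intensity; cannot derive a flat-field")
    ff = np.maximum(m / mean, FLATFIELD_MIN_GAIN)
    return ff / ff.mean()


def apply_flatfield(stack, flatfield: np.ndarray):
    """Divide every frame by the flat-field gain."""
    flatfield = np.asarray(flatfield, dtype=float)
    if np.any(flatfield <= 0):
        raise ValueError("flatfield must be strictly positive")
    if isinstance(stack, ImageStack):
        if flatfield.shape != stack.data.shape[-2:]:
            raise ValueError("flatfield shape does not match frames")
        return stack.copy_with(stack.data / flatfield)
    arr = np.asarray(stack, dtype=float)
    if flatfield.shape != arr.shape[-2:]:
        raise ValueError("flatfield shape does not match frames")
    return arr / flatfield


def percentile_background(
    image: np.ndarray,
    tile_px: int,
    percentile: float = 1.0,
    smooth: bool = True,
) -> np.ndarray:
    """Tiled low-percentile background estimate for single-frame images.

    The image is divided into ``tile_px`` x ``tile_px`` tiles (choose several times
    the nucleus radius so every tile contains background pixels); the per-tile
    ``percentile`` is smoothed and resampled to full resolution.
    """
    img = np.asarray(image, dtype=float)
    if tile_px < 2:
        raise ValueError("tile_px must be >= 2")
    h, w = img.shape
    nrow = max(h // tile_px, 1)
    ncol = max(w // tile_px, 1)
    coarse = np.empty((nrow, ncol))
    for i in range(nrow):
        r1 = (i + 1) * tile_px if i < nrow - 1 else h
        for j in range(ncol):
            c1 = (j + 1) * tile_px if j < ncol - 1 else w
            coarse[i, j] = np.percentile(img[i * tile_px:r1, j * tile_px:c1], percentile)
    if smooth and min(nrow, ncol) > 2:
        coarse = ndimage.gaussian_filter(coarse, sigma=1.0, mode="nearest")
    out = ndimage.zoom(coarse, (h / nrow, w / ncol), order=1, mode="nearest",
                       grid_mode=True)
    return np.maximum(out, 0.0)  # heavy noise can push a low percentile negative


def derive_correction(
    stacks,
    channel,
    nucleus_radius_px: float,
    percentile: float = 1.0,
) -> CorrectionField:
    """Background + flat-field for one channel, using the minimum image when possible.

    ``stacks`` may be one ImageStack/array or a list (frames pooled across fields).
    The raw minimum image is Gaussian-smoothed with sigma = 2 x nucleus radius before
    both uses. When only a single frame is available the tiled percentile fallback is
    used and ``meta['background_method']`` is set to ``"percentile"``; the flat-field
    is then derived from the same estimate.
    """
    frames = _channel_frames(stacks, channel)
    sigma = 2.0 * nucleus_radius_px
    if frames.shape[0] >= 2:
        raw_min = frames.min(axis=0)
        method = "minimum"
        background = smooth_min_image(raw_min, sigma)
    else:
        background = percentile_background(
            frames[0], tile_px=max(int(round(4 * nucleus_radius_px)), 4),
            percentile=percentile,
        )
        method = "percentile"
    try:
        flatfield = flatfield_from_minimum(background, smooth_sigma=0.0)
    except ValueError:
        warnings.warn("background carries no intensity; flat-field set to 1")
        flatfield = np.ones_like(background)
    return CorrectionField(
        background=background,
        flatfield=flatfield,
        meta={"background_method": method, "smooth_sigma_px": sigma},
    )


def correct_stack(stack: ImageStack, fields: dict) -> ImageStack:
    """Subtract-then-divide correction of every channel of a stack.

    ``fields`` maps channel name -> CorrectionField (see :func:`derive_correction`);
    channels without an entry pass through unchanged.
    """
    out = stack.data.copy()
    for name, fld in fields.items():
        ci = stack.channel_index(name)
        out[:, ci] = np.maximum(out[:, ci] - fld.background, 0.0) / fld.flatfield
    corrected = stack.copy_with(out)
    corrected.meta["corrected"] = {
        name: fld.meta.get("background_method", "minimum") for name, fld in fields.items()
    }
    return corrected
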