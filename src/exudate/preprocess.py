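"""Colour normalisation, contrast enhancement and shade correction.

The preprocessing chain turns a raw fundus photograph into the working
green-channel image used by all later stages:

1. resize to the working grid (512x512 by default);
2. colour normalisation in YIQ space — the luminance plane is replaced by
   ``Y_mod = a*Y - b*I - c*Q`` with gains (1.8, 0.9, 0.9) and the image is
   converted back to RGB;
3. the green channel is contrast-enhanced with CLAHE;
4. a grayscale morphological opening with a 3-px-diameter disc removes the
   bright central light reflex of vessels;
5. shade correction ``I_ie = I - I_bg + u`` subtracts a 51x51 windowed
   mean background and restores the field-of-view mean.

All window means are restricted to the field of view (outside-FOV pixels
are held at 0 and never enter a window average).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage import exposure, morphology, transform

from ._util import box_mean
from .io import FundusImage

__all__ = [
    "PreprocessResult",
    "resize_to_working",
    "normalize_yiq",
    "apply_clahe",
    "open_with_disc",
    "illumination_equalize",
    "preprocess",
]

# NTSC YIQ primaries; the inverse is computed numerically so the round
# trip is the identity to machine precision.
RGB2YIQ = np.array(
    [
        [0.299, 0.587, 0.114],
        [0.595716, -0.274453, -0.321263],
        [0.211456, -0.522591, 0.311135],
    ]
)
YIQ2RGB = np.linalg.inv(RGB2YIQ)


@dataclass
class PreprocessResult:
    """All intermediates of the preprocessing chain, on the working grid."""

    normalized_rgb: FundusImage
    green: np.ndarray
    green_clahe: np.ndarray
    green_opened: np.ndarray
    green_equalized: np.ndarray


def resize_to_working(img: FundusImage, size: tuple[int, int]) -> FundusImage:
    """Resample image and FOV mask to ``size`` (anisotropic; mask re-binarised).

    A same-size request returns an exact copy so the operation is a strict
    identity there.
    """
    rows, cols = int(size[0]), int(size[1])
    if rows <= 0 or cols <= 0:
        raise ValueError("target size must be positive")
    if (rows, cols) == img.shape:
        return FundusImage(img.rgb.copy(), img.fov_mask.copy(), img.source_id)
    rgb = transform.resize(
        img.rgb, (rows, cols, 3), order=1, mode="reflect",
        anti_aliasing=True, preserve_range=True,
    )
    fov = transform.resize(
        img.fov_mask.astype(np.float64), (rows, cols), order=1,
        mode="constant", cval=0.0, anti_aliasing=False, preserve_range=True,
    )
    return FundusImage(np.clip(rgb, 0.0, 1.0), fov > 0.5, img.source_id)


def normalize_yiq(
    img: FundusImage, a: float = 1.8, b: float = 0.9, c: float = 0.9
) -> FundusImage:
    """Enhance the YIQ luminance plane: ``Y_mod = a*Y - b*I - c*Q``.

    Channels are clipped to [0, 1] after the YIQ->RGB back-conversion; with
    (a, b, c) = (1, 0, 0) the transform is the identity up to round-trip
    floating-point error.
    """
    if not all(np.isfinite(v) for v in (a, b, c)):
        raise ValueError("gains must be finite")
    yiq = img.rgb @ RGB2YIQ.T
    yiq[:, :, 0] = a * yiq[:, :, 0] - b * yiq[:, :, 1] - c * yiq[:, :, 2]
    rgb = np.clip(yiq @ YIQ2RGB.T, 0.0, 1.0)
    rgb[~img.fov_mask] = 0.0
    return FundusImage(rgb, img.fov_mask.copy(), img.source_id)


def apply_clahe(
    img: np.ndarray,
    clip: float = 0.01,
    tiles: tuple[int, int] = (8, 8),
    fov: np.ndarray | None = None,
) -> np.ndarray:
    """Contrast-limited adaptive histogram equalisation on a [0, 1] raster.

    A constant image is returned unchanged (its histogram mapping is
    degenerate); outside-FOV pixels are reset to 0 after enhancement.
    """
    img = np.asarray(img, dtype=np.float64)
    if img.min() < -1e-9 or img.max() > 1 + 1e-9:
        raise ValueError("CLAHE input must lie in [0, 1]")
    if np.ptp(img) < 1e-12:
        return img.copy()
    kernel = (max(1, img.shape[0] // tiles[0]), max(1, img.shape[1] // tiles[1]))
    out = exposure.equalize_adapthist(
        np.clip(img, 0.0, 1.0), kernel_size=kernel, clip_limit=clip
    )
    if fov is not None:
        out = np.where(fov, out, 0.0)
    return out


def open_with_disc(img: np.ndarray, diameter_px: int = 3) -> np.ndarray:
    """Grayscale morphological opening with a disc structuring element.

    Anti-extensive (output <= input) and idempotent; removes bright
    structures thinner than the disc, e.g. 1-px vessel light reflexes.
    """
    if diameter_px < 1:
        raise ValueError("disc diameter must be >= 1")
    if diameter_px == 1:
        return np.asarray(img, dtype=np.float64).copy()
    footprint = morphology.disk(diameter_px // 2)
    return morphology.opening(np.asarray(img, dtype=np.float64), footprint)


def illumination_equalize(
    img: np.ndarray, window: int = 51, fov: np.ndarray | None = None
) -> np.ndarray:
    """Shade correction ``I_ie = I - I_bg + u``.

    ``I_bg`` is the ``window``-sized FOV-restricted mean-filtered image and
    ``u`` is the FOV mean of ``I_bg`` (numerically the average image
    intensity), a choice that makes the correction conserve the FOV mean
    exactly. The result is *not* clipped here; the pipeline clips after
    this step.
    """
    img = np.asarray(img, dtype=np.float64)
    if window % 2 == 0 or window < 3:
        raise ValueError("window must be odd and >= 3")
    if window > min(img.shape):
        raise ValueError("window larger than the image")
    if fov is None:
        fov = np.ones(img.shape, dtype=bool)
    if not fov.any():
        raise ValueError("empty field of view")
    bg = box_mean(img, (window, window), mask=fov)
    u = bg[fov].mean()
    out = np.where(fov, img - bg + u, 0.0)
    return out


def preprocess(img: FundusImage, cfg=None) -> PreprocessResult:
    """Run the full preprocessing chain on a working-grid image."""
    from .io import PipelineConfig

    cfg = cfg or PipelineConfig()
    work = resize_to_working(img, cfg.working_size)
    a, b, c = cfg.yiq_gain
    normalized = normalize_yiq(work, a, b, c)
    green = normalized.green.copy()
    green[~normalized.fov_mask] = 0.0
    green_clahe = apply_clahe(
        green, cfg.clahe_clip, cfg.clahe_tiles, fov=normalized.fov_mask
    )
    green_opened = open_with_disc(green_clahe, cfg.opening_diameter)
    green_opened[~normalized.fov_mask] = 0.0
    equalized = illumination_equalize(
        green_opened, cfg.illum_window, fov=normalized.fov_mask
    )
    equalized = np.clip(equalized, 0.0, 1.0)
    return PreprocessResult(
        normalized_rgb=normalized,
        green=green,
        green_clahe=green_clahe,
        green_opened=green_opened,
        green_equalized=equalized,
    )
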