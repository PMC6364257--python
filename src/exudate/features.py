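"""Per-pixel descriptors for exudate classification.

Eight features are computed as full-image planes so any candidate pixel
can be sampled in O(1):

f1  3x3 mean of the (normalised) green channel
f2  gray-scale luminance of the normalised RGB image
f3  3x3 mean hue        (HSV)
f4  3x3 mean saturation (HSV)
f5  3x3 mean value      (HSV)
f6  energy: sum of squared green intensities over the 8-neighbourhood
    (9 pixels including the centre; configurable)
f7  standard deviation, in a 3x3 window, of the morphologically opened
    green channel
f8  3x3 mean of the Sobel gradient magnitude of the green channel

f8 is the edge-sharpness cue that separates hard exudates (crisp margins)
from cotton-wool-like bright lesions (blurry margins).
"""

from __future__ import annotations

import numpy as np
from scipy.ndimage import uniform_filter
from skimage import filters
from skimage.color import rgb2gray, rgb2hsv

from .preprocess import PreprocessResult

__all__ = ["FEATURE_NAMES", "compute_feature_stack", "sample_features"]

FEATURE_NAMES = (
    "f1_mean_green",
    "f2_gray",
    "f3_mean_hue",
    "f4_mean_saturation",
    "f5_mean_value",
    "f6_energy",
    "f7_sd_opened_green",
    "f8_mean_gradient",
)


def _mean3(img: np.ndarray) -> np.ndarray:
    return uniform_filter(np.asarray(img, dtype=np.float64), size=3,
                          mode="reflect")


def compute_feature_stack(
    pre: PreprocessResult,
    rgb_image=None,
    include_center: bool = True,
    energy_plane: str = "green",
) -> np.ndarray:
    """Compute all eight feature planes; returns an (H, W, 8) array.

    ``rgb_image`` is the colour fundus image used for the gray (f2) and
    HSV (f3-f5) planes — by default the photograph itself (before colour
    normalisation), because the luminance gain saturates bright lesions
    and flattens exactly the hue/saturation contrast between yellow hard
    exudates and whiter cotton-wool-like lesions that f3/f4 carry. The
    green-channel features (f1, f6-f8) use the normalised working green.

    ``include_center``/``energy_plane`` control the energy stencil (f6):
    whether the centre pixel enters the 8-neighbourhood sum and whether it
    is taken on the green or the gray plane.
    """
    if rgb_image is None:
        rgb_image = pre.normalized_rgb
    rgb = rgb_image.rgb if hasattr(rgb_image, "rgb") else np.asarray(rgb_image)
    green = np.asarray(pre.green, dtype=np.float64)
    if rgb.shape[:2] != green.shape:
        raise ValueError("rgb image grid does not match the working grid")
    h, w = green.shape

    f1 = _mean3(green)
    f2 = rgb2gray(rgb)
    hsv = rgb2hsv(rgb)
    f3 = _mean3(hsv[:, :, 0])
    f4 = _mean3(hsv[:, :, 1])
    f5 = _mean3(hsv[:, :, 2])

    if energy_plane == "green":
        e_src = green
    elif energy_plane == "gray":
        e_src = np.asarray(f2, dtype=np.float64)
    else:
        raise ValueError("energy_plane must be 'green' or 'gray'")
    sq = e_src ** 2
    f6 = 9.0 * _mean3(sq)
    if not include_center:
        f6 = f6 - sq

    opened = np.asarray(pre.green_opened, dtype=np.float64)
    var = _mean3(opened ** 2) - _mean3(opened) ** 2
    f7 = np.sqrt(np.clip(var, 0.0, None))

    f8 = _mean3(filters.sobel(green))

    stack = np.stack([f1, f2, f3, f4, f5, f6, f7, f8], axis=-1)
    if not np.isfinite(stack).all():
        raise ValueError("non-finite feature values")
    return stack


def sample_features(stack: np.ndarray, pixels) -> np.ndarray:
    """Sample rows of the feature stack at ``pixels`` (sequence of (row, col)).

    Order is preserved; duplicate pixels yield identical rows. Raises on
    out-of-bounds coordinates.
    """
    stack = np.asarray(stack)
    pixels = np.asarray(pixels, dtype=int)
    if pixels.size == 0:
        return np.empty((0, stack.shape[-1]))
    if pixels.ndim != 2 or pixels.shape[1] != 2:
        raise ValueError("pixels must be an (n, 2) sequence of (row, col)")
    h, w = stack.shape[:2]
    if (
        (pixels[:, 0] < 0).any() or (pixels[:, 0] >= h).any()
        or (pixels[:, 1] < 0).any() or (pixels[:, 1] >= w).any()
    ):
        raise IndexError("pixel coordinates out of bounds")
    return stack[pixels[:, 0], pixels[:, 1], :]
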