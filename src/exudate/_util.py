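"""Shared raster helpers.

All windowed means in this package use one convention: the window of size
``s`` centred at pixel ``x`` covers the half-open index range
``[x - s//2, x - s//2 + s)``. For odd ``s`` this is symmetric; for even
``s`` the extra row/column sits on the low (top/left) side. Means are
normalised by the number of *valid* pixels in the window (inside the image
and, when a mask is given, inside the mask), so borders and the field of
view are handled uniformly.
"""

from __future__ import annotations

import numpy as np

__all__ = ["box_sum", "box_mean", "window_bounds"]


def window_bounds(x: int, size: int) -> tuple[int, int]:
    """Half-open [lo, hi) covered by a size-``size`` window centred at ``x``."""
    lo = x - size // 2
    return lo, lo + size


def box_sum(arr: np.ndarray, window: tuple[int, int]) -> np.ndarray:
    """Sliding-window sum with zeros assumed outside the image.

    Exact (integral-image) computation; no approximation or padding artifact.
    """
    arr = np.asarray(arr, dtype=np.float64)
    if arr.ndim != 2:
        raise ValueError("box_sum expects a 2-D array")
    wr, wc = int(window[0]), int(window[1])
    if wr < 1 or wc < 1:
        raise ValueError("window dimensions must be >= 1")
    h, w = arr.shape
    cum = np.zeros((h + 1, w + 1), dtype=np.float64)
    np.cumsum(arr, axis=0, out=cum[1:, 1:])
    np.cumsum(cum[1:, 1:], axis=1, out=cum[1:, 1:])

    r0 = np.clip(np.arange(h) - wr // 2, 0, h)
    r1 = np.clip(np.arange(h) - wr // 2 + wr, 0, h)
    c0 = np.clip(np.arange(w) - wc // 2, 0, w)
    c1 = np.clip(np.arange(w) - wc // 2 + wc, 0, w)
    return (
        cum[np.ix_(r1, c1)]
        - cum[np.ix_(r0, c1)]
        - cum[np.ix_(r1, c0)]
        + cum[np.ix_(r0, c0)]
    )


def box_mean(
    values: np.ndarray,
    window: tuple[int, int],
    mask: np.ndarray | None = None,
) -> np.ndarray:
    """Windowed mean over the valid (in-image, in-mask) part of each window.

    With ``mask`` given, pixels outside it contribute neither to the sum nor
    to the normalisation, so the result at an in-mask pixel is the plain mean
    of its in-mask neighbours. Pixels whose window contains no valid
    neighbour get 0.
    """
    values = np.asarray(values, dtype=np.float64)
    if mask is not None:
        mask = np.asarray(mask, dtype=bool)
        if mask.shape != values.shape:
            raise ValueError("mask and values shapes differ")
        num = box_sum(np.where(mask, values, 0.0), window)
        den = box_sum(mask.astype(np.float64), window)
    else:
        num = box_sum(values, window)
        den = box_sum(np.ones_like(values), window)
    out = np.zeros_like(num)
    np.divide(num, den, out=out, where=den > 0)
    return out
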