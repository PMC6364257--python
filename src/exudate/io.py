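"""Core raster types, image I/O and pipeline configuration.

Images are held internally as floating-point arrays in [0, 1]; conversion
to and from 8-bit happens only at the file boundary. Coordinates are
0-based ``(row, col)`` and every window/tile extent is half-open.

Grayscale rasters and binary masks are plain numpy arrays (``float64``
H×W and ``bool`` H×W respectively); composite results use the dataclasses
defined here and in the stage modules.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import yaml
from PIL import Image
from scipy import ndimage
from skimage import morphology

__all__ = [
    "FundusImage",
    "PipelineConfig",
    "FundusIOError",
    "load_fundus",
    "compute_fov_mask",
    "save_mask",
    "load_mask",
    "save_gray",
]


class FundusIOError(ValueError):
    """Unreadable, unwritable or wrongly formatted image file."""


@dataclass
class FundusImage:
    """An RGB fundus photograph with its circular field-of-view mask.

    Attributes
    ----------
    rgb : (H, W, 3) float array in [0, 1]
    fov_mask : (H, W) bool array, True inside the illuminated field of view
    source_id : provenance string (file stem or phantom seed tag)
    """

    rgb: np.ndarray
    fov_mask: np.ndarray
    source_id: str = ""

    def __post_init__(self) -> None:
        self.rgb = np.asarray(self.rgb, dtype=np.float64)
        self.fov_mask = np.asarray(self.fov_mask, dtype=bool)
        if self.rgb.ndim != 3 or self.rgb.shape[2] != 3:
            raise ValueError("rgb must be H x W x 3")
        if self.fov_mask.shape != self.rgb.shape[:2]:
            raise ValueError("fov_mask grid does not match rgb")
        if self.rgb.min() < -1e-9 or self.rgb.max() > 1 + 1e-9:
            raise ValueError("rgb values must lie in [0, 1]")

    @property
    def shape(self) -> tuple[int, int]:
        return self.rgb.shape[:2]

    @property
    def green(self) -> np.ndarray:
        return self.rgb[:, :, 1]


@dataclass
class PipelineConfig:
    """Every tunable of the detection pipeline, with its default.

    The defaults encode the published operating point: 512x512 working
    grid, YIQ luminance gains (1.8, 0.9, 0.9), a 51x51 shade-correction
    mean filter, a 9x9 vessel blur, a 55x22 vessel-density window, the
    1.2 brightness weight of the optic-disc score, 30x40 threshold tiles
    smoothed 10x10, global/dynamic blend k = 0.1 and overlap ratio
    sigma = 0.2.
    """

    working_size: tuple[int, int] = (512, 512)
    # color normalisation (YIQ luminance gains a, b, c)
    yiq_gain: tuple[float, float, float] = (1.8, 0.9, 0.9)
    # FOV extraction
    fov_threshold: float = 0.06
    fov_close_radius: int = 5
    # contrast enhancement
    clahe_clip: float = 0.01
    clahe_tiles: tuple[int, int] = (8, 8)
    opening_diameter: int = 3
    illum_window: int = 51
    # vessel extraction / optic disc
    vessel_blur: int = 9
    density_window: tuple[int, int] = (55, 22)
    od_mean_window: int = 61
    od_brightness_weight: float = 1.2
    eq3_literal: bool = False
    od_roi_fraction: float = 1.0 / 3.0
    hough_radii: tuple[int, int] = (15, 50)
    hough_radius_step: int = 2
    hough_accum_threshold: float = 0.25
    od_fallback_radius: int = 35
    od_dilate: int = 5
    # candidate segmentation
    tile_shape: tuple[int, int] = (30, 40)
    threshold_smooth: int = 10
    k_global: float = 0.1
    min_area: int = 5
    min_tile_pixels: int = 10
    fcm_m: float = 2.0
    fcm_tol: float = 1.0e-6
    fcm_max_iter: int = 100
    # features
    energy_include_center: bool = True
    # classification
    svm_c_grid: tuple[float, ...] = tuple(float(2.0 ** p) for p in range(-3, 10))
    svm_gamma_grid: tuple[float, ...] = tuple(float(2.0 ** p) for p in range(-9, 4))
    svm_cv_folds: int = 3
    # evaluation
    sigma_overlap: float = 0.2
    eval_restrict_fov: bool = False
    # randomness
    seed: int = 0

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if not 0.0 <= self.k_global <= 1.0:
            raise ValueError("k_global must lie in [0, 1]")
        if not 0.0 <= self.sigma_overlap <= 1.0:
            raise ValueError("sigma_overlap must lie in [0, 1]")
        th, tw = self.tile_shape
        if th < 2 or tw < 2:
            raise ValueError("tile dimensions must be >= 2")
        if self.illum_window % 2 == 0 or self.illum_window < 3:
            raise ValueError("illum_window must be odd and >= 3")
        n, m = self.density_window
        if not n > m >= 1:
            raise ValueError("density window must have N > M >= 1")
        if self.fcm_m <= 1:
            raise ValueError("fcm fuzziness exponent must be > 1")

    def as_dict(self) -> dict:
        d = dataclasses.asdict(self)
        for key, val in d.items():
            if isinstance(val, tuple):
                d[key] = list(val)
        return d

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.as_dict(), sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        return cls.from_dict(data)

    @classmethod
    def from_dict(cls, data: dict) -> "PipelineConfig":
        names = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - names
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        kwargs = {}
        for f in dataclasses.fields(cls):
            if f.name not in data:
                continue
            val = data[f.name]
            if isinstance(val, list):
                val = tuple(val)
            kwargs[f.name] = val
        return cls(**kwargs)


def compute_fov_mask(
    rgb: np.ndarray, threshold: float = 0.06, close_radius: int = 5
) -> np.ndarray:
    """Estimate the circular field of view from pixel luminance.

    A pixel is inside the FOV when its brightest channel exceeds
    ``threshold``; the raw mask is morphologically closed and reduced to
    its largest connected component with holes filled, yielding one disc
    region (or an empty mask for an all-dark frame).
    """
    bright = rgb.max(axis=2) > threshold
    if not bright.any():
        return np.zeros(rgb.shape[:2], dtype=bool)
    closed = morphology.closing(bright, morphology.disk(close_radius))
    labels, n = ndimage.label(closed)
    if n == 0:
        return np.zeros(rgb.shape[:2], dtype=bool)
    sizes = np.bincount(labels.ravel())
    sizes[0] = 0
    keep = labels == np.argmax(sizes)
    return ndimage.binary_fill_holes(keep)


def load_fundus(
    path: str | Path,
    fov_threshold: float = 0.06,
    fov_close_radius: int = 5,
) -> FundusImage:
    """Read a colour fundus photograph and compute its FOV mask.

    Accepts PNG/JPEG/TIFF; integer images are rescaled so the full dtype
    range maps onto [0, 1].
    """
    path = Path(path)
    try:
        with Image.open(path) as im:
            arr = np.asarray(im)
    except (OSError, ValueError) as exc:
        raise FundusIOError(f"cannot read image file {path}: {exc}") from exc
    if arr.ndim == 2:
        raise FundusIOError(f"{path} is single-channel; a colour image is required")
    if arr.shape[2] == 4:  # drop alpha
        arr = arr[:, :, :3]
    if arr.shape[2] != 3:
        raise FundusIOError(f"{path} has {arr.shape[2]} channels; expected 3")
    if np.issubdtype(arr.dtype, np.integer):
        rgb = arr.astype(np.float64) / np.iinfo(arr.dtype).max
    else:
        rgb = np.clip(arr.astype(np.float64), 0.0, 1.0)
    fov = compute_fov_mask(rgb, fov_threshold, fov_close_radius)
    return FundusImage(rgb=rgb, fov_mask=fov, source_id=path.stem)


def save_mask(mask: np.ndarray, path: str | Path) -> None:
    """Write a binary mask as an 8-bit {0, 255} PNG (lossless round-trip)."""
    mask = np.asarray(mask)
    if mask.ndim != 2:
        raise ValueError("mask must be 2-D")
    uniq = np.unique(mask)
    if not np.all(np.isin(uniq, (0, 1, True, False))):
        raise ValueError("mask must be binary")
    arr = (mask.astype(np.uint8) * 255)
    try:
        Image.fromarray(arr, mode="L").save(Path(path))
    except OSError as exc:
        raise FundusIOError(f"cannot write mask to {path}: {exc}") from exc


def load_mask(path: str | Path) -> np.ndarray:
    """Read a mask PNG back to a bool array (any nonzero pixel is True)."""
    try:
        with Image.open(Path(path)) as im:
            arr = np.asarray(im.convert("L"))
    except OSError as exc:
        raise FundusIOError(f"cannot read mask from {path}: {exc}") from exc
    return arr > 127


def save_gray(img: np.ndarray, path: str | Path, bits: int = 16) -> None:
    """Write a [0, 1] grayscale raster as an 8- or 16-bit PNG."""
    img = np.clip(np.asarray(img, dtype=np.float64), 0.0, 1.0)
    if bits == 16:
        arr = np.round(img * 65535).astype(np.uint16)
        Image.fromarray(arr, mode="I;16").save(Path(path))
    elif bits == 8:
        arr = np.round(img * 255).astype(np.uint8)
        Image.fromarray(arr, mode="L").save(Path(path))
    else:
        raise ValueError("bits must be 8 or 16")
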