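"""Candidate exudate extraction by fuzzy-C-means thresholding.

The working image is divided into tiles (30x40 px by default). In each
tile, two-cluster fuzzy C-means (FCM) on the pixel intensities yields two
cluster centres whose midpoint is the tile's local threshold. The tile
thresholds are bilinearly interpolated into a dynamic threshold matrix D
and smoothed with a 10x10 mean filter. The same clustering applied to the
whole field of view gives a single global threshold S, and the decision
surface is the convex blend ``T = k*S + (1-k)*D`` with k = 0.1. Pixels
brighter than T (inside the FOV, outside the masked optic disc) form the
candidate mask.

FCM minimises ``J(U, V) = sum_i sum_k u_ki^m * (x_i - v_k)^2`` by
alternating the closed-form membership and centre updates; with
intensities as the only feature this is a 1-D problem and the iteration is
fully vectorised.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from scipy.interpolate import RegularGridInterpolator
from scipy.spatial import cKDTree
from skimage import measure

from ._util import box_mean

__all__ = [
    "FCMResult",
    "ThresholdMatrix",
    "CandidateMask",
    "fcm_1d",
    "tile_threshold",
    "build_dynamic_matrix",
    "global_threshold",
    "combine_thresholds",
    "segment_candidates",
]


@dataclass
class FCMResult:
    """Converged state of a 1-D fuzzy C-means run.

    ``centers`` are reported sorted ascending; each row of ``memberships``
    sums to 1; ``cost_history`` holds J(U, V) after every iteration and is
    non-increasing.
    """

    centers: np.ndarray
    memberships: np.ndarray
    iterations: int
    converged: bool
    degenerate: bool = False
    cost_history: list = field(default_factory=list)

    @property
    def threshold(self) -> float:
        """Midpoint of the (two) cluster centres."""
        return float(self.centers.mean())


def fcm_1d(
    data: np.ndarray,
    c: int = 2,
    m: float = 2.0,
    tol: float = 1.0e-6,
    max_iter: int = 100,
    seed: int | None = None,
    jitter: float = 0.0,
) -> FCMResult:
    """Fuzzy C-means on a 1-D sample.

    Centres are initialised at evenly spaced data quantiles, which makes
    the run deterministic; ``seed`` is consumed only when ``jitter`` > 0
    adds random perturbation to that initialisation. All-identical data is
    flagged degenerate with every centre at the common value.
    """
    data = np.asarray(data, dtype=np.float64).ravel()
    if data.size == 0:
        raise ValueError("empty data")
    if c < 2:
        raise ValueError("need at least 2 clusters")
    if m <= 1:
        raise ValueError("fuzziness exponent m must be > 1")

    span = np.ptp(data)
    if span < 1e-12:
        centers = np.full(c, data[0])
        memberships = np.full((data.size, c), 1.0 / c)
        return FCMResult(centers, memberships, 0, True, degenerate=True,
                         cost_history=[0.0])

    centers = np.quantile(data, (np.arange(c) + 0.5) / c)
    if np.unique(centers).size < c:
        centers = np.linspace(data.min(), data.max(), c)
    if jitter > 0:
        rng = np.random.default_rng(seed)
        centers = centers + rng.normal(0.0, jitter * span, c)

    exponent = -1.0 / (m - 1.0)
    costs: list[float] = []
    converged = False
    iterations = 0
    u = np.full((data.size, c), 1.0 / c)
    for iterations in range(1, max_iter + 1):
        d2 = (data[:, None] - centers[None, :]) ** 2
        hit = d2 < 1e-30
        any_hit = hit.any(axis=1)
        with np.errstate(divide="ignore", invalid="ignore"):
            inv = d2 ** exponent
            u = inv / inv.sum(axis=1, keepdims=True)
        if any_hit.any():
            rows = hit[any_hit]
            u[any_hit] = rows / rows.sum(axis=1, keepdims=True)
        w = u ** m
        denom = w.sum(axis=0)
        new_centers = np.where(
            denom > 0, (w * data[:, None]).sum(axis=0) / np.maximum(denom, 1e-300),
            centers,
        )
        costs.append(float((w * (data[:, None] - new_centers[None, :]) ** 2).sum()))
        shift = np.abs(new_centers - centers).max()
        centers = new_centers
        if shift < tol:
            converged = True
            break

    order = np.argsort(centers)
    return FCMResult(centers[order], u[:, order], iterations, converged,
                     cost_history=costs)


def tile_threshold(tile_pixels: np.ndarray, **fcm_kwargs) -> float:
    """Local threshold of a tile: midpoint of its two FCM cluster centres."""
    res = fcm_1d(tile_pixels, c=2, **fcm_kwargs)
    return res.threshold


def global_threshold(
    img: np.ndarray, fov: np.ndarray, **fcm_kwargs
) -> tuple[float, bool]:
    """Whole-FOV FCM threshold. Returns ``(value, degenerate_flag)``."""
    fov = np.asarray(fov, dtype=bool)
    if not fov.any():
        raise ValueError("empty field of view")
    res = fcm_1d(np.asarray(img, dtype=np.float64)[fov], c=2, **fcm_kwargs)
    return res.threshold, res.degenerate


def _tile_edges(n: int, t: int) -> list[tuple[int, int]]:
    """Half-open tile extents; the last tile absorbs the remainder."""
    n_tiles = max(1, n // t)
    edges = [(i * t, (i + 1) * t) for i in range(n_tiles)]
    edges[-1] = (edges[-1][0], n)
    return edges


def build_dynamic_matrix(
    img: np.ndarray,
    fov: np.ndarray,
    tile_shape: tuple[int, int] = (30, 40),
    smooth: int = 10,
    min_tile_pixels: int = 10,
    **fcm_kwargs,
) -> np.ndarray:
    """Dynamic threshold matrix D from per-tile FCM thresholds.

    Tile thresholds are anchored at tile centres, bilinearly interpolated
    to the full grid (constant extension beyond the outermost centres),
    and box-smoothed with a ``smooth`` x ``smooth`` window. Tiles with
    fewer than ``min_tile_pixels`` FOV pixels are imputed from the nearest
    valid tile.
    """
    img = np.asarray(img, dtype=np.float64)
    fov = np.asarray(fov, dtype=bool)
    h, w = img.shape
    th, tw = int(tile_shape[0]), int(tile_shape[1])
    if th > h or tw > w:
        raise ValueError("tile does not fit in the image")
    row_edges = _tile_edges(h, th)
    col_edges = _tile_edges(w, tw)

    thresholds = np.full((len(row_edges), len(col_edges)), np.nan)
    for i, (ra, rb) in enumerate(row_edges):
        for j, (ca, cb) in enumerate(col_edges):
            vals = img[ra:rb, ca:cb][fov[ra:rb, ca:cb]]
            if vals.size >= min_tile_pixels:
                thresholds[i, j] = tile_threshold(vals, **fcm_kwargs)
    if np.isnan(thresholds).all():
        raise ValueError("no tile has enough field-of-view pixels")

    row_centers = np.array([(a + b - 1) / 2.0 for a, b in row_edges])
    col_centers = np.array([(a + b - 1) / 2.0 for a, b in col_edges])

    # impute skipped tiles from the nearest valid tile centre
    nan_mask = np.isnan(thresholds)
    if nan_mask.any():
        valid_idx = np.argwhere(~nan_mask)
        pts = np.column_stack(
            [row_centers[valid_idx[:, 0]], col_centers[valid_idx[:, 1]]]
        )
        tree = cKDTree(pts)
        need = np.argwhere(nan_mask)
        query = np.column_stack([row_centers[need[:, 0]], col_centers[need[:, 1]]])
        _, nearest = tree.query(query)
        thresholds[need[:, 0], need[:, 1]] = thresholds[
            valid_idx[nearest, 0], valid_idx[nearest, 1]
        ]

    # bilinear interpolation to full resolution (clamped => convex)
    rc, cc = row_centers, col_centers
    grid = thresholds
    if len(rc) == 1:
        rc = np.array([rc[0] - 0.5, rc[0] + 0.5])
        grid = np.vstack([grid, grid])
    if len(cc) == 1:
        cc = np.array([cc[0] - 0.5, cc[0] + 0.5])
        grid = np.hstack([grid, grid])
    interp = RegularGridInterpolator((rc, cc), grid, method="linear")
    rr = np.clip(np.arange(h, dtype=np.float64), rc[0], rc[-1])
    ww = np.clip(np.arange(w, dtype=np.float64), cc[0], cc[-1])
    mesh = np.stack(np.meshgrid(rr, ww, indexing="ij"), axis=-1)
    dynamic = interp(mesh)

    if smooth and smooth > 1:
        dynamic = box_mean(dynamic, (smooth, smooth))
    return dynamic


def combine_thresholds(S, D: np.ndarray, k: float) -> np.ndarray:
    """Final decision surface ``T = k*S + (1-k)*D``, exact elementwise."""
    if not 0.0 <= k <= 1.0:
        raise ValueError("k must lie in [0, 1]")
    D = np.asarray(D, dtype=np.float64)
    S = np.asarray(S, dtype=np.float64)
    if S.ndim == 0:
        S = np.full_like(D, float(S))
    if S.shape != D.shape:
        raise ValueError("S and D shapes differ")
    return k * S + (1.0 - k) * D


@dataclass
class ThresholdMatrix:
    """Global (S), dynamic (D) and combined (T) threshold surfaces."""

    global_S: np.ndarray
    dynamic_D: np.ndarray
    combined_T: np.ndarray
    k: float
    tile_shape: tuple[int, int]
    global_degenerate: bool = False

    @classmethod
    def build(
        cls,
        img: np.ndarray,
        fov: np.ndarray,
        tile_shape: tuple[int, int] = (30, 40),
        smooth: int = 10,
        k: float = 0.1,
        min_tile_pixels: int = 10,
        **fcm_kwargs,
    ) -> "ThresholdMatrix":
        s_value, degenerate = global_threshold(img, fov, **fcm_kwargs)
        S = np.full(np.asarray(img).shape, s_value)
        D = build_dynamic_matrix(
            img, fov, tile_shape, smooth, min_tile_pixels, **fcm_kwargs
        )
        T = combine_thresholds(S, D, k)
        return cls(S, D, T, k, tuple(tile_shape), degenerate)


@dataclass
class CandidateMask:
    """Connected candidate regions above the threshold surface."""

    mask: np.ndarray
    labels: np.ndarray
    n_components: int
    areas: np.ndarray
    bboxes: list

    def component_pixels(self, index: int) -> np.ndarray:
        """(n, 2) pixel coordinates of component ``index`` (1-based label)."""
        return np.argwhere(self.labels == index)


def segment_candidates(
    img: np.ndarray,
    T: np.ndarray,
    fov: np.ndarray,
    exclude: np.ndarray | None = None,
    min_area: int = 5,
) -> CandidateMask:
    """Candidate mask: ``img > T`` inside the FOV, minus the excluded
    (optic-disc) region, with 8-connected components below ``min_area``
    removed."""
    img = np.asarray(img, dtype=np.float64)
    T = np.asarray(T, dtype=np.float64)
    if img.shape != T.shape:
        raise ValueError("image and threshold shapes differ")
    fg = (img > T) & np.asarray(fov, dtype=bool)
    if exclude is not None:
        fg &= ~np.asarray(exclude, dtype=bool)
    labels = measure.label(fg, connectivity=2)
    if labels.max() and min_area > 1:
        areas = np.bincount(labels.ravel())
        small = np.flatnonzero(areas < min_area)
        kill = np.isin(labels, small[small > 0])
        fg[kill] = False
        labels = measure.label(fg, connectivity=2)
    n = int(labels.max())
    areas = np.bincount(labels.ravel(), minlength=n + 1)[1:]
    slices = ndimage.find_objects(labels)
    bboxes = [
        (sl[0].start, sl[1].start, sl[0].stop, sl[1].stop) for sl in slices
    ]
    return CandidateMask(fg, labels, n, areas, bboxes)
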