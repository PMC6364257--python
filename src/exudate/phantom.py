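"""Seeded synthetic fundus phantoms with exact ground truth.

A phantom emulates the aspects of a colour fundus photograph that the
detection pipeline actually exploits: a circular illuminated field of
view on a black frame, smooth uneven illumination (radial falloff plus a
linear gradient), a bright optic disc with dark curvilinear vessels
radiating from it (vertically aligned near the disc), sharp-edged bright
exudate blobs in clusters of a few to thousands of pixels, and bright
Gaussian-blurred distractor blobs mimicking cotton-wool spots. It does
not attempt photorealism — no microaneurysms, haemorrhages, texture or
camera artefacts.

Every phantom is a pure function of its :class:`PhantomSpec` (seed
included), so repeated generation is bit-identical and truth masks are
exact by construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter
from skimage.draw import disk as draw_disk
from skimage.draw import ellipse as draw_ellipse
from skimage.morphology import dilation, disk as disk_footprint

from .io import FundusImage

__all__ = ["PhantomSpec", "PhantomTruth", "generate_phantom", "generate_dataset"]


@dataclass
class PhantomSpec:
    """Geometry, photometry and noise of one synthetic fundus image.

    Brightness values are additive green-channel amplitudes on a [0, 1]
    scale; areas are in pixels. Defaults render a 512x512 phantom with
    contrast comfortably above the noise floor (exudates +0.22..0.30 over
    a 0.45 background, noise SD 0.015).
    """

    size: tuple[int, int] = (512, 512)
    fov_radius: float | None = None  # default 0.48 * min(size)
    # optic disc
    od_radius_range: tuple[float, float] = (28.0, 40.0)
    od_offset_range: tuple[float, float] = (0.45, 0.62)  # fraction of FOV radius
    od_brightness: float = 0.32
    # vessels
    n_vessels: int = 8
    vessel_width_range: tuple[float, float] = (2.0, 4.0)
    vessel_darkness: float = 0.45  # fraction of green light absorbed
    vessel_waviness: float = 0.25
    # hard exudates
    n_exudates: int = 6
    exudate_area_range: tuple[float, float] = (10.0, 2000.0)
    exudate_brightness_range: tuple[float, float] = (0.22, 0.30)
    # soft (cotton-wool-like) distractors
    n_soft_distractors: int = 3
    soft_radius_range: tuple[float, float] = (5.0, 12.0)
    soft_blur: float = 4.0
    # illumination and noise
    illumination_radial: float = 0.18
    illumination_linear: float = 0.08
    noise_sd: float = 0.015
    seed: int = 0


@dataclass
class PhantomTruth:
    """Exact ground truth recorded while rendering."""

    exudate_mask: np.ndarray
    soft_mask: np.ndarray
    vessel_mask: np.ndarray
    od_mask: np.ndarray
    od_center: tuple[int, int]
    od_radius: float
    fov_mask: np.ndarray
    vessel_centerlines: np.ndarray = field(default=None)


_BASE_COLOR = np.array([0.62, 0.45, 0.18])       # retinal background RGB
_OD_COLOR = np.array([0.90, 1.00, 0.80])         # additive OD tint
_EXUDATE_COLOR = np.array([1.00, 1.00, 0.30])    # additive exudate tint
_SOFT_COLOR = np.array([0.95, 1.00, 0.50])       # additive distractor tint
# multiplicative absorption per channel: blood absorbs green/blue strongly,
# so vessels stay visible even on the bright disc
_VESSEL_ABSORB = np.array([0.30, 1.00, 0.65])


def _render_vessels(rng, spec, od_center, od_radius, fov_center, fov_radius, shape):
    """Trace arcade-like vessel paths from the disc outward.

    Vessels leave the disc vertically (up or down) and, as in real retinal
    arcades, bend toward the horizontal — toward the macular side — as
    they move away from it, so vertical vessel runs concentrate in the
    disc's vicinity.
    """
    h, w = shape
    vessel = np.zeros(shape, dtype=bool)
    centerline = np.zeros(shape, dtype=bool)
    # arcades arc toward the retina centre (macular side of the disc)
    toward = 0.0 if fov_center[1] >= od_center[1] else np.pi
    for i in range(spec.n_vessels):
        upward = i % 2 == 0
        ang = (-np.pi / 2 if upward else np.pi / 2) + rng.uniform(-0.45, 0.45)
        target = toward + rng.uniform(-0.25, 0.25)
        # vessels emerge around the disc centre with a little spread
        pos = np.asarray(od_center, dtype=np.float64) + np.array(
            [rng.normal(0.0, 3.0), rng.uniform(-0.35, 0.35) * od_radius]
        )
        width = rng.uniform(*spec.vessel_width_range)
        n_steps = 400
        for step in range(n_steps):
            r, c = int(round(pos[0])), int(round(pos[1]))
            if 0 <= r < h and 0 <= c < w:
                centerline[r, c] = True
                taper = 1.0 - 0.6 * min(1.0, step / 250.0)
                rr, cc = draw_disk((pos[0], pos[1]),
                                   max(1.0, width * taper / 2.0) + 0.5,
                                   shape=shape)
                vessel[rr, cc] = True
            dist_od = np.hypot(pos[0] - od_center[0], pos[1] - od_center[1])
            # bend toward the horizontal target once clear of the disc
            pull = 0.030 * np.clip((dist_od - 45.0) / 80.0, 0.0, 1.0)
            diff = np.angle(np.exp(1j * (target - ang)))
            ang += pull * diff + rng.normal(0.0, spec.vessel_waviness * 0.15)
            pos = pos + 2.0 * np.array([np.sin(ang), np.cos(ang)])
            if np.hypot(pos[0] - fov_center[0], pos[1] - fov_center[1]) > fov_radius - 3:
                break
    return vessel, centerline


def _place_blob(rng, area, allowed, fov_center, fov_radius, od_center,
                od_radius, shape, anchor=None, max_tries=60):
    """One sharp elliptical blob of roughly ``area`` px inside ``allowed``."""
    h, w = shape
    for _ in range(max_tries):
        if anchor is None:
            ang = rng.uniform(0, 2 * np.pi)
            rad = rng.uniform(0.2, 0.8) * fov_radius
            center = (fov_center[0] + rad * np.sin(ang),
                      fov_center[1] + rad * np.cos(ang))
        else:
            center = (anchor[0] + rng.normal(0, 25),
                      anchor[1] + rng.normal(0, 25))
        if np.hypot(center[0] - fov_center[0], center[1] - fov_center[1]) > fov_radius - 14:
            continue
        if np.hypot(center[0] - od_center[0], center[1] - od_center[1]) < od_radius + 12:
            continue
        q = rng.uniform(0.5, 1.0)
        a = np.sqrt(area / (np.pi * q))
        b = a * q
        rot = rng.uniform(0, np.pi)
        blob = np.zeros(shape, dtype=bool)
        rr, cc = draw_ellipse(center[0], center[1], a, b,
                              shape=shape, rotation=rot)
        blob[rr, cc] = True
        if rng.uniform() < 0.5:  # irregular outline: add an offset lobe
            rr, cc = draw_ellipse(
                center[0] + rng.normal(0, a / 2),
                center[1] + rng.normal(0, a / 2),
                a * 0.6, b * 0.6, shape=shape, rotation=rot,
            )
            blob[rr, cc] = True
        blob &= allowed
        if blob.sum() >= max(3, 0.4 * area):
            return blob, center
    return None, None


def generate_phantom(spec: PhantomSpec) -> tuple[FundusImage, PhantomTruth]:
    """Render one phantom. Deterministic given ``spec`` (seed included)."""
    h, w = spec.size
    if h < 64 or w < 64:
        raise ValueError("phantom must be at least 64 x 64")
    rng = np.random.default_rng(spec.seed)
    fov_radius = spec.fov_radius or 0.48 * min(h, w)
    fov_center = ((h - 1) / 2.0, (w - 1) / 2.0)
    if fov_radius > min(h, w) / 2.0:
        raise ValueError("field of view does not fit in the frame")

    rows, cols = np.mgrid[0:h, 0:w].astype(np.float64)
    d_fov = np.hypot(rows - fov_center[0], cols - fov_center[1])
    fov_mask = d_fov <= fov_radius
    fov_soft = np.clip((fov_radius - d_fov) / 1.5 + 0.5, 0.0, 1.0)

    # illumination: radial falloff + linear gradient of random direction
    theta = rng.uniform(0, 2 * np.pi)
    lin = ((rows - fov_center[0]) * np.sin(theta)
           + (cols - fov_center[1]) * np.cos(theta)) / fov_radius
    light = (1.0 - spec.illumination_radial * (d_fov / fov_radius) ** 2
             + spec.illumination_linear * lin)
    light = np.clip(light, 0.5, 1.2)

    img = _BASE_COLOR[None, None, :] * light[:, :, None]

    # optic disc
    od_radius = rng.uniform(*spec.od_radius_range)
    side = rng.choice((-1.0, 1.0))
    od_ang = rng.uniform(-0.35, 0.35)
    od_offset = rng.uniform(*spec.od_offset_range) * fov_radius
    od_center_f = (fov_center[0] + od_offset * np.sin(od_ang),
                   fov_center[1] + side * od_offset * np.cos(od_ang))
    d_od = np.hypot(rows - od_center_f[0], cols - od_center_f[1])
    od_mask = d_od <= od_radius
    od_soft = np.clip((od_radius - d_od) / 2.0 + 0.5, 0.0, 1.0)
    img = img + od_soft[:, :, None] * spec.od_brightness * _OD_COLOR

    od_center = (int(round(od_center_f[0])), int(round(od_center_f[1])))

    # vessels radiating from the disc
    vessel_mask, centerlines = _render_vessels(
        rng, spec, od_center_f, od_radius, fov_center, fov_radius, (h, w)
    )
    v_soft = gaussian_filter(vessel_mask.astype(np.float64), 0.7)
    absorb = 1.0 - (spec.vessel_darkness * v_soft)[:, :, None] * _VESSEL_ABSORB
    img = img * absorb

    # keep lesions off the disc and the FOV rim
    od_keepout = dilation(od_mask, disk_footprint(8))
    allowed = fov_mask & (d_fov <= fov_radius - 12) & ~od_keepout

    # hard exudates, in clusters as they appear clinically
    exudate_mask = np.zeros((h, w), dtype=bool)
    n_clusters = max(1, spec.n_exudates // 3)
    cluster_anchors = []
    for _ in range(n_clusters):
        blob_probe, center = _place_blob(
            rng, 50.0, allowed, fov_center, fov_radius,
            od_center_f, od_radius, (h, w)
        )
        if center is not None:
            cluster_anchors.append(center)
    lo, hi = np.log(spec.exudate_area_range[0]), np.log(spec.exudate_area_range[1])
    for i in range(spec.n_exudates):
        area = float(np.exp(rng.uniform(lo, hi)))
        anchor = cluster_anchors[i % len(cluster_anchors)] if cluster_anchors else None
        blob, _ = _place_blob(rng, area, allowed, fov_center, fov_radius,
                              od_center_f, od_radius, (h, w), anchor=anchor)
        if blob is None:
            continue
        amp = rng.uniform(*spec.exudate_brightness_range)
        img = img + (amp * blob.astype(np.float64))[:, :, None] * _EXUDATE_COLOR
        exudate_mask |= blob

    # soft distractors: same brightness, blurred edges
    soft_mask = np.zeros((h, w), dtype=bool)
    soft_allowed = allowed & ~dilation(exudate_mask, disk_footprint(5))
    for _ in range(spec.n_soft_distractors):
        radius = rng.uniform(*spec.soft_radius_range)
        area = np.pi * radius ** 2
        blob, _ = _place_blob(rng, area, soft_allowed, fov_center, fov_radius,
                              od_center_f, od_radius, (h, w))
        if blob is None:
            continue
        amp = rng.uniform(*spec.exudate_brightness_range)
        bump = gaussian_filter(blob.astype(np.float64), spec.soft_blur)
        peak = bump.max()
        if peak > 0:
            bump = bump / peak
        img = img + (amp * bump)[:, :, None] * _SOFT_COLOR
        soft_mask |= blob

    if spec.noise_sd > 0:
        img = img + rng.normal(0.0, spec.noise_sd, img.shape)

    img = np.clip(img * fov_soft[:, :, None], 0.0, 1.0)

    fundus = FundusImage(rgb=img, fov_mask=fov_mask,
                         source_id=f"phantom-seed{spec.seed}")
    truth = PhantomTruth(
        exudate_mask=exudate_mask, soft_mask=soft_mask,
        vessel_mask=vessel_mask, od_mask=od_mask,
        od_center=od_center, od_radius=float(od_radius),
        fov_mask=fov_mask, vessel_centerlines=centerlines,
    )
    return fundus, truth


def generate_dataset(
    n: int,
    seed: int = 0,
    exudate_free_fraction: float = 0.0,
    base_spec: PhantomSpec | None = None,
    vary: bool = True,
):
    """A seeded list of phantoms plus a parameter manifest.

    Exactly ``round(n * exudate_free_fraction)`` images are rendered
    without exudates (normal retinas for image-level screening); their
    positions in the list are drawn once from the dataset seed. With
    ``vary`` the lesion counts, optic-disc geometry and illumination are
    perturbed per image so the set spans realistic acquisition variation.
    """
    if n < 1:
        raise ValueError("need n >= 1")
    base = base_spec or PhantomSpec()
    rng = np.random.default_rng(seed)
    n_free = int(round(n * exudate_free_fraction))
    free = np.zeros(n, dtype=bool)
    if n_free:
        free[rng.choice(n, size=n_free, replace=False)] = True

    phantoms = []
    records = []
    for i in range(n):
        child_seed = int((seed * 1_000_003 + 7919 * i + 1) % (2**31 - 1))
        overrides: dict = {"seed": child_seed}
        if vary:
            overrides.update(
                n_exudates=int(rng.integers(4, 9)),
                n_soft_distractors=int(rng.integers(1, 4)),
                n_vessels=int(rng.integers(6, 11)),
                illumination_radial=float(rng.uniform(0.10, 0.25)),
                illumination_linear=float(rng.uniform(0.02, 0.12)),
                od_brightness=float(rng.uniform(0.26, 0.38)),
            )
        if free[i]:
            overrides["n_exudates"] = 0
        spec = replace(base, **overrides)
        image, truth = generate_phantom(spec)
        phantoms.append((image, truth))
        records.append(
            {
                "index": i,
                "seed": child_seed,
                "exudate_free": bool(free[i]),
                "n_exudates": spec.n_exudates,
                "n_soft_distractors": spec.n_soft_distractors,
                "n_vessels": spec.n_vessels,
                "od_row": truth.od_center[0],
                "od_col": truth.od_center[1],
                "od_radius": truth.od_radius,
                "exudate_pixels": int(truth.exudate_mask.sum()),
            }
        )
    manifest = pd.DataFrame.from_records(records)
    return phantoms, manifest
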