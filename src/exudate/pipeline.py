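"""End-to-end orchestration of the four detection stages.

``prepare_image`` runs preprocessing, optic-disc masking, candidate
segmentation and feature extraction — everything that does not need a
trained classifier — and caches the products in a :class:`PreparedImage`
so cross-validation can reuse them across folds. ``run_pipeline`` adds
the SVM stage and returns the final exudate mask with a reproducibility
manifest. Stages communicate only through the declared result types.
"""

from __future__ import annotations

import hashlib
import time
from dataclasses import dataclass, field

import numpy as np

from . import __version__
from .classify import TrainedClassifier, classify_pixels
from .features import compute_feature_stack
from .io import FundusImage, PipelineConfig
from .od import (
    ODModel,
    extract_vessels,
    locate_od_center,
    mask_od,
    od_exclusion_mask,
    segment_od,
)
from .preprocess import PreprocessResult, preprocess, resize_to_working
from .segmentation import CandidateMask, ThresholdMatrix, segment_candidates

__all__ = ["PreparedImage", "RunManifest", "PipelineResult",
           "prepare_image", "run_pipeline"]


@dataclass
class PreparedImage:
    """All classifier-independent products for one image."""

    image: FundusImage
    pre: PreprocessResult
    vessels: np.ndarray
    od: ODModel
    equalized_masked: np.ndarray
    thresholds: ThresholdMatrix
    candidates: CandidateMask
    stack: np.ndarray
    timings: dict = field(default_factory=dict)

    @property
    def fov(self) -> np.ndarray:
        return self.image.fov_mask


@dataclass
class RunManifest:
    """Reproducibility record of one pipeline run."""

    source_id: str
    input_sha256: str
    config: dict
    stage_seconds: dict
    counts: dict
    version: str = __version__


@dataclass
class PipelineResult:
    he_mask: np.ndarray
    prepared: PreparedImage
    manifest: RunManifest
    classified: bool


def prepare_image(img: FundusImage, cfg: PipelineConfig | None = None) -> PreparedImage:
    """Preprocess -> vessels/OD -> thresholds -> candidates -> features."""
    cfg = cfg or PipelineConfig()
    timings: dict = {}

    t0 = time.perf_counter()
    work = resize_to_working(img, cfg.working_size)
    pre = preprocess(work, cfg)
    fov = pre.normalized_rgb.fov_mask
    timings["preprocess"] = time.perf_counter() - t0

    t0 = time.perf_counter()
    vessels = extract_vessels(pre.green_clahe, fov, blur=cfg.vessel_blur,
                              already_enhanced=True)
    center, score = locate_od_center(
        pre.green, vessels, fov,
        brightness_weight=cfg.od_brightness_weight,
        mean_window=cfg.od_mean_window,
        density_window=cfg.density_window,
        literal=cfg.eq3_literal,
    )
    od = segment_od(
        pre.green, center, fov,
        roi_fraction=cfg.od_roi_fraction,
        radii=cfg.hough_radii,
        radius_step=cfg.hough_radius_step,
        accum_threshold=cfg.hough_accum_threshold,
        fallback_radius=cfg.od_fallback_radius,
    )
    od.score_map = score
    timings["od"] = time.perf_counter() - t0

    t0 = time.perf_counter()
    masked = mask_od(pre.green_equalized, od, fov, dilate_px=cfg.od_dilate)
    thresholds = ThresholdMatrix.build(
        masked, fov,
        tile_shape=cfg.tile_shape, smooth=cfg.threshold_smooth,
        k=cfg.k_global, min_tile_pixels=cfg.min_tile_pixels,
        m=cfg.fcm_m, tol=cfg.fcm_tol, max_iter=cfg.fcm_max_iter,
    )
    exclude = od_exclusion_mask(od, cfg.od_dilate)
    candidates = segment_candidates(
        masked, thresholds.combined_T, fov, exclude=exclude,
        min_area=cfg.min_area,
    )
    timings["segment"] = time.perf_counter() - t0

    t0 = time.perf_counter()
    stack = compute_feature_stack(pre, rgb_image=work,
                                  include_center=cfg.energy_include_center)
    timings["features"] = time.perf_counter() - t0

    return PreparedImage(
        image=work, pre=pre, vessels=vessels, od=od,
        equalized_masked=masked, thresholds=thresholds,
        candidates=candidates, stack=stack, timings=timings,
    )


def run_pipeline(
    img: FundusImage,
    cfg: PipelineConfig | None = None,
    clf: TrainedClassifier | None = None,
) -> PipelineResult:
    """Full detection run. Without a classifier the candidate mask is
    returned and flagged unclassified."""
    cfg = cfg or PipelineConfig()
    prepared = prepare_image(img, cfg)

    t0 = time.perf_counter()
    if clf is not None:
        he = classify_pixels(clf, prepared.stack, prepared.candidates,
                             min_area=cfg.min_area)
        classified = True
    else:
        he = prepared.candidates.mask.copy()
        classified = False
    prepared.timings["classify"] = time.perf_counter() - t0

    digest = hashlib.sha256(
        np.ascontiguousarray(img.rgb).tobytes()
    ).hexdigest()
    manifest = RunManifest(
        source_id=img.source_id,
        input_sha256=digest,
        config=cfg.as_dict(),
        stage_seconds=dict(prepared.timings),
        counts={
            "candidate_pixels": int(prepared.candidates.mask.sum()),
            "candidate_components": prepared.candidates.n_components,
            "he_pixels": int(he.sum()),
            "od_fallback": bool(prepared.od.fallback),
        },
    )
    return PipelineResult(he_mask=he, prepared=prepared,
                          manifest=manifest, classified=classified)
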