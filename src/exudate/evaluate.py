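"""Pixel-level overlap-ratio evaluation and image-level screening metrics.

Exudate contours drawn by different annotators rarely agree pixel for
pixel, so straight pixel counting understates performance. The pixel-level
protocol therefore works on connected components with a minimum overlap
ratio sigma (default 0.2): a pixel is a true positive if it lies in

    (D ∩ G)
  ∪ { D_i : |D_i ∩ G| / |D_i| > sigma }      (whole detected component)
  ∪ { G_j : |G_j ∩ D| / |G_j| > sigma }      (whole ground-truth component)

where {D_i} / {G_j} are the 8-connected components of the detection and
ground-truth masks. False positives are detected components disjoint from
G plus the outside-G part of under-sigma components; false negatives
symmetrically; everything else is a true negative. The comparison at the
boundary is strict: ratio == sigma does not promote a component.

Image-level evaluation reduces each image to a present/absent flag and
reports accuracy, specificity and sensitivity of the 2x2 table.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage import measure

__all__ = [
    "OverlapEvalResult",
    "PixelMetrics",
    "ImageMetrics",
    "pixel_level_eval",
    "pixel_metrics",
    "image_level_eval",
    "consensus_ground_truth",
]


@dataclass
class OverlapEvalResult:
    """Pixel partition of one image under the sigma-overlap rules."""

    tp: int
    fp: int
    fn: int
    tn: int
    sigma: float
    detected_promoted: np.ndarray  # per D_i: whole component counted TP
    truth_promoted: np.ndarray     # per G_j
    domain_size: int

    def counts(self) -> tuple[int, int, int, int]:
        return self.tp, self.fp, self.fn, self.tn


@dataclass
class PixelMetrics:
    sensitivity: float
    ppv: float
    fscore: float


@dataclass
class ImageMetrics:
    accuracy: float
    specificity: float
    sensitivity: float
    tp: int
    fp: int
    fn: int
    tn: int


def _component_overlap(mask: np.ndarray, other: np.ndarray):
    """Per-component size and overlap with ``other`` for ``mask``'s
    8-connected components. Returns (labels, sizes, overlaps)."""
    labels = measure.label(mask, connectivity=2)
    n = int(labels.max())
    sizes = np.bincount(labels.ravel(), minlength=n + 1)
    overlaps = np.bincount(labels[other].ravel(), minlength=n + 1)
    return labels, sizes, overlaps


def pixel_level_eval(
    detected: np.ndarray,
    truth: np.ndarray,
    sigma: float = 0.2,
    domain: np.ndarray | None = None,
) -> OverlapEvalResult:
    """Evaluate a detection mask against ground truth under the
    sigma-overlap protocol.

    ``domain`` optionally restricts the pixel universe (e.g. to the FOV);
    by default the full grid is scored, where true negatives dominate.
    """
    detected = np.asarray(detected, dtype=bool)
    truth = np.asarray(truth, dtype=bool)
    if detected.shape != truth.shape:
        raise ValueError("mask shapes differ")
    if not 0.0 <= sigma <= 1.0:
        raise ValueError("sigma must lie in [0, 1]")
    if domain is None:
        domain = np.ones_like(detected)
    else:
        domain = np.asarray(domain, dtype=bool)
        if domain.shape != detected.shape:
            raise ValueError("domain shape differs")

    d_labels, d_sizes, d_over = _component_overlap(detected, truth)
    g_labels, g_sizes, g_over = _component_overlap(truth, detected)

    with np.errstate(invalid="ignore", divide="ignore"):
        d_ratio = np.where(d_sizes > 0, d_over / np.maximum(d_sizes, 1), 0.0)
        g_ratio = np.where(g_sizes > 0, g_over / np.maximum(g_sizes, 1), 0.0)
    d_promoted = d_ratio > sigma
    g_promoted = g_ratio > sigma
    d_promoted[0] = g_promoted[0] = False

    tp_mask = (detected & truth) | d_promoted[d_labels] | g_promoted[g_labels]
    fp_mask = detected & ~tp_mask
    fn_mask = truth & ~tp_mask

    tp = int((tp_mask & domain).sum())
    fp = int((fp_mask & domain).sum())
    fn = int((fn_mask & domain).sum())
    size = int(domain.sum())
    tn = size - tp - fp - fn
    return OverlapEvalResult(
        tp=tp, fp=fp, fn=fn, tn=tn, sigma=sigma,
        detected_promoted=d_promoted[1:], truth_promoted=g_promoted[1:],
        domain_size=size,
    )


def pixel_metrics(res: OverlapEvalResult) -> PixelMetrics:
    """Sensitivity, PPV and F-score with the 0/0 -> 0 convention."""
    s = res.tp / (res.tp + res.fn) if res.tp + res.fn else 0.0
    ppv = res.tp / (res.tp + res.fp) if res.tp + res.fp else 0.0
    f = 2 * s * ppv / (s + ppv) if s + ppv else 0.0
    return PixelMetrics(sensitivity=s, ppv=ppv, fscore=f)


def image_level_eval(predictions, labels) -> ImageMetrics:
    """Screening metrics from per-image exudate-present flags."""
    predictions = [bool(p) for p in predictions]
    labels = [bool(l) for l in labels]
    if not predictions:
        raise ValueError("empty prediction list")
    if len(predictions) != len(labels):
        raise ValueError("prediction/label lengths differ")
    tp = sum(p and l for p, l in zip(predictions, labels))
    tn = sum(not p and not l for p, l in zip(predictions, labels))
    fp = sum(p and not l for p, l in zip(predictions, labels))
    fn = sum(not p and l for p, l in zip(predictions, labels))
    total = tp + fp + tn + fn
    acc = (tp + tn) / total
    spec = tn / (tn + fp) if tn + fp else 0.0
    sens = tp / (tp + fn) if tp + fn else 0.0
    return ImageMetrics(accuracy=acc, specificity=spec, sensitivity=sens,
                        tp=tp, fp=fp, fn=fn, tn=tn)


def consensus_ground_truth(annotations, level: float = 0.75) -> np.ndarray:
    """Consensus mask: pixels whose mean annotator confidence >= ``level``.

    ``annotations`` is a sequence of per-annotator confidence maps in
    [0, 1] (binary marks are the usual case); with four annotators and
    level 0.75, three marks are required.
    """
    if not 0.0 < level <= 1.0:
        raise ValueError("level must lie in (0, 1]")
    maps = [np.asarray(a, dtype=np.float64) for a in annotations]
    if not maps:
        raise ValueError("empty annotation list")
    shape = maps[0].shape
    if any(m.shape != shape for m in maps):
        raise ValueError("annotation maps must share a grid")
    mean = np.mean(maps, axis=0)
    return mean >= level
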