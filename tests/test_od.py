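"""Vessel extraction, optic-disc localisation, Hough segmentation, masking."""

import numpy as np
import pytest
from skimage.draw import circle_perimeter, disk as draw_disk

from exudate import (
    ODModel,
    extract_vessels,
    locate_od_center,
    mask_od,
    segment_od,
    vessel_density_map,
)
from exudate.od import od_exclusion_mask
from oracles import box_mean_oracle


class TestExtractVessels:
    def test_constant_image_yields_empty_mask(self):
        fov = np.ones((64, 64), dtype=bool)
        assert not extract_vessels(np.full((64, 64), 0.5), fov).any()

    def test_empty_fov_yields_empty_mask(self):
        assert not extract_vessels(np.random.rand(32, 32),
                                   np.zeros((32, 32), bool)).any()

    def test_dark_line_recovered(self, rng):
        img = np.full((96, 96), 0.6) + rng.normal(0, 0.01, (96, 96))
        img = np.clip(img, 0, 1)
        img[:, 46:49] -= 0.25  # 3-px dark line
        fov = np.ones((96, 96), dtype=bool)
        mask = extract_vessels(img, fov, already_enhanced=True)
        line = np.zeros_like(fov)
        line[:, 46:49] = True
        from skimage.morphology import dilation, disk

        line_d = dilation(line, disk(1))
        inter = (mask & line_d).sum()
        dice = 2 * inter / (mask.sum() + line_d.sum())
        assert dice >= 0.7

    def test_phantom_centerlines_covered_sparsely(self, phantom_default,
                                                  prepared_default):
        _, truth = phantom_default
        prep = prepared_default
        cov = (prep.vessels & truth.vessel_centerlines).sum()
        cov /= truth.vessel_centerlines.sum()
        assert cov >= 0.8
        assert prep.vessels.sum() / prep.fov.sum() < 0.15


class TestVesselDensityMap:
    def test_all_ones_mask_gives_all_ones_density(self):
        assert np.allclose(vessel_density_map(np.ones((60, 60), bool)), 1.0)

    def test_single_column_profile(self):
        mask = np.zeros((80, 80), dtype=bool)
        mask[:, 40] = True
        dens = vessel_density_map(mask, (55, 22))
        mid = dens[40]
        assert mid.argmax() in range(30, 51)
        assert mid[40] == mid.max()
        # the half-open window [c - 11, c + 11) sees the column for
        # offsets -10..+11 and nothing beyond
        assert mid[40 + 11] > 0 and mid[40 - 10] > 0
        assert mid[40 + 12] == 0 and mid[40 - 11] == 0

    def test_matches_double_loop_oracle(self, rng):
        mask = rng.random((32, 32)) > 0.7
        dens = vessel_density_map(mask, (7, 4))
        assert np.allclose(dens, box_mean_oracle(mask.astype(float), (7, 4)),
                           atol=1e-12)

    def test_window_must_be_tall(self):
        with pytest.raises(ValueError):
            vessel_density_map(np.ones((10, 10), bool), (4, 6))

    def test_density_argmax_tracks_disc_column(self):
        """The tall-window density peaks on the vertical vessel bundle
        through the disc: the argmax column stays close to the disc
        column even when the row drifts along the bundle."""
        from exudate import PhantomSpec, generate_phantom, preprocess

        hits = 0
        n = 10
        for seed in range(n):
            image, truth = generate_phantom(PhantomSpec(seed=seed))
            pre = preprocess(image)
            fov = pre.normalized_rgb.fov_mask
            vessels = extract_vessels(pre.green_clahe, fov,
                                      already_enhanced=True)
            dens = vessel_density_map(vessels)
            peak = np.unravel_index(np.argmax(np.where(fov, dens, -1.0)),
                                    dens.shape)
            hits += abs(peak[1] - truth.od_center[1]) <= 30
        assert hits >= 0.8 * n


class TestLocateCenter:
    def test_brightness_term_alone_finds_gaussian_blob(self):
        rr, cc = np.mgrid[0:128, 0:128]
        img = 0.2 + 0.6 * np.exp(-((rr - 70) ** 2 + (cc - 50) ** 2) / 200.0)
        fov = np.ones((128, 128), dtype=bool)
        center, _ = locate_od_center(img, np.zeros_like(fov), fov)
        assert np.hypot(center[0] - 70, center[1] - 50) <= 2

    def test_density_term_alone_finds_vertical_bundle(self):
        img = np.full((128, 128), 0.5)
        vessels = np.zeros((128, 128), dtype=bool)
        vessels[20:108, 62:66] = True
        fov = np.ones((128, 128), dtype=bool)
        center, _ = locate_od_center(img, vessels, fov)
        # the returned point's density window must contain the bundle
        # (the score is flat wherever the whole bundle is inside the
        # window, and ties resolve to the first such pixel)
        assert abs(center[1] - 63.5) <= 11
        assert 20 <= center[0] <= 108

    def test_literal_mode_repels_vessels(self):
        img = np.full((128, 128), 0.5)
        vessels = np.zeros((128, 128), dtype=bool)
        vessels[:, 60:68] = True
        fov = np.ones((128, 128), dtype=bool)
        center, _ = locate_od_center(img, vessels, fov, literal=True)
        assert abs(center[1] - 63) > 10

    def test_empty_fov_rejected(self):
        with pytest.raises(ValueError):
            locate_od_center(np.zeros((8, 8)), np.zeros((8, 8), bool),
                             np.zeros((8, 8), bool))

    def test_tie_breaks_to_smallest_row_then_column(self):
        img = np.zeros((64, 64))
        fov = np.ones((64, 64), dtype=bool)
        center, _ = locate_od_center(img, np.zeros_like(fov), fov)
        assert center == (0, 0)


class TestSegmentOD:
    def test_crisp_circle_recovered(self):
        img = np.full((180, 180), 0.3)
        rr, cc = draw_disk((90, 90), 30)
        img[rr, cc] = 0.8
        fov = np.ones((180, 180), dtype=bool)
        od = segment_od(img, (90, 90), fov)
        assert not od.fallback
        assert abs(od.radius - 30) <= 1
        assert np.hypot(od.center[0] - 90, od.center[1] - 90) <= 1.5

    def test_flat_roi_falls_back_flagged(self):
        img = np.full((180, 180), 0.3)
        fov = np.ones((180, 180), dtype=bool)
        od = segment_od(img, (90, 90), fov, fallback_radius=35)
        assert od.fallback
        assert od.radius == 35
        assert od.center == (90, 90)


class TestMaskOD:
    def _od(self, shape, center, radius):
        disc = np.zeros(shape, dtype=bool)
        if radius > 0:
            rr, cc = draw_disk(center, radius, shape=shape)
            disc[rr, cc] = True
        return ODModel(center=center, radius=float(radius), disc_mask=disc)

    def test_zero_radius_changes_nothing(self, rng):
        img = rng.random((64, 64))
        fov = np.ones((64, 64), dtype=bool)
        od = self._od((64, 64), (32, 32), 0)
        assert np.array_equal(mask_od(img, od, fov, dilate_px=0), img)

    def test_full_image_disc_yields_constant_median(self, rng):
        img = rng.random((64, 64))
        fov = np.ones((64, 64), dtype=bool)
        od = self._od((64, 64), (32, 32), 100)
        out = mask_od(img, od, fov)
        assert np.allclose(out, np.median(img))

    def test_masking_is_idempotent(self, rng):
        img = rng.random((64, 64))
        fov = np.ones((64, 64), dtype=bool)
        od = self._od((64, 64), (20, 40), 10)
        once = mask_od(img, od, fov)
        assert np.array_equal(mask_od(once, od, fov), once)

    def test_exclusion_mask_grows_with_dilation(self):
        od = self._od((64, 64), (32, 32), 8)
        grown = od_exclusion_mask(od, 5)
        assert grown.sum() > od.disc_mask.sum()
        assert (od.disc_mask & ~grown).sum() == 0


class TestPhantomODRecovery:
    def test_no_candidates_inside_true_disc(self, phantom_default,
                                            prepared_default):
        _, truth = phantom_default
        assert not (prepared_default.candidates.mask & truth.od_mask).any()

    def test_center_and_radius_close_to_truth(self, phantom_default,
                                              prepared_default):
        _, truth = phantom_default
        od = prepared_default.od
        dist = np.hypot(od.center[0] - truth.od_center[0],
                        od.center[1] - truth.od_center[1])
        assert dist <= truth.od_radius
        assert abs(od.radius - truth.od_radius) <= 0.25 * truth.od_radius
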