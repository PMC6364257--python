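"""Fuzzy C-means thresholding and candidate extraction."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from exudate import (
    build_dynamic_matrix,
    combine_thresholds,
    fcm_1d,
    global_threshold,
    segment_candidates,
    tile_threshold,
)
from oracles import fcm_two_center_oracle


class TestFCM:
    def test_two_well_separated_groups(self):
        data = np.array([0.0, 0.0, 0.0, 10.0, 10.0, 10.0])
        res = fcm_1d(data, c=2, m=2.0)
        assert np.allclose(res.centers, [0.0, 10.0], atol=1e-6)
        assert res.converged and not res.degenerate

    def test_constant_data_flagged_degenerate(self):
        res = fcm_1d(np.full(50, 3.3), c=2)
        assert res.degenerate
        assert np.allclose(res.centers, 3.3)

    def test_two_gaussian_modes_recovered(self, rng):
        data = np.concatenate([rng.normal(0.3, 0.02, 250),
                               rng.normal(0.7, 0.02, 250)])
        res = fcm_1d(data, c=2)
        assert abs(res.centers[0] - 0.3) < 0.01
        assert abs(res.centers[1] - 0.7) < 0.01

    def test_cost_non_increasing(self, rng):
        data = rng.random(300)
        res = fcm_1d(data, c=2)
        costs = np.array(res.cost_history)
        assert np.all(np.diff(costs) <= 1e-10)

    def test_membership_rows_sum_to_one(self, rng):
        data = rng.random(100)
        res = fcm_1d(data, c=3)
        assert np.allclose(res.memberships.sum(axis=1), 1.0, atol=1e-9)
        assert res.centers.min() >= data.min() - 1e-12
        assert res.centers.max() <= data.max() + 1e-12
        assert np.all(np.diff(res.centers) >= 0)

    def test_matches_exhaustive_grid_oracle(self, rng):
        for _ in range(5):
            data = np.concatenate([
                rng.normal(rng.uniform(0.1, 0.4), 0.05, 50),
                rng.normal(rng.uniform(0.6, 0.9), 0.05, 50),
            ])
            res = fcm_1d(data, c=2)
            oracle = fcm_two_center_oracle(data)
            assert np.allclose(res.centers, oracle, atol=5e-3)

    def test_point_equal_to_center_handled(self):
        res = fcm_1d(np.array([0.0, 0.0, 1.0]), c=2)
        assert np.isfinite(res.memberships).all()
        assert np.allclose(res.memberships.sum(axis=1), 1.0)


class TestTileAndGlobalThreshold:
    def test_midpoint_of_separated_groups(self):
        data = np.array([0.0] * 10 + [10.0] * 10)
        assert tile_threshold(data) == pytest.approx(5.0, abs=1e-6)

    def test_threshold_brackets_blob_and_background(self, rng):
        tile = np.full(600, 0.2) + rng.normal(0, 0.01, 600)
        tile[:80] = 0.8 + rng.normal(0, 0.01, 80)
        thr = tile_threshold(tile)
        assert 0.2 < thr < 0.8

    def test_global_equals_full_population_fcm(self, rng):
        img = rng.random((40, 40))
        fov = np.ones((40, 40), dtype=bool)
        value, degenerate = global_threshold(img, fov)
        assert not degenerate
        oracle = fcm_two_center_oracle(img.ravel())
        assert value == pytest.approx(oracle.mean(), abs=5e-3)

    def test_constant_image_flagged(self):
        value, degenerate = global_threshold(np.full((20, 20), 0.5),
                                             np.ones((20, 20), bool))
        assert degenerate and value == 0.5


class TestDynamicMatrix:
    def test_identical_tiles_give_constant_matrix(self, rng):
        tile = rng.random((16, 16))
        img = np.tile(tile, (4, 4))
        fov = np.ones(img.shape, dtype=bool)
        D = build_dynamic_matrix(img, fov, tile_shape=(16, 16), smooth=0)
        assert np.ptp(D) < 1e-9

    def test_two_half_image_orders_thresholds(self, rng):
        h, w = 60, 120
        img = np.full((h, w), 0.2) + rng.normal(0, 0.005, (h, w))
        img[:, :60] += (rng.random((h, 60)) > 0.9) * 0.2   # dim blobs
        img[:, 60:] += 0.4 + (rng.random((h, 60)) > 0.9) * 0.3
        fov = np.ones((h, w), dtype=bool)
        D = build_dynamic_matrix(img, fov, tile_shape=(30, 30), smooth=0)
        assert D[:, :40].max() < D[:, 80:].min()

    def test_values_bounded_by_tile_thresholds(self, rng):
        img = rng.random((90, 120))
        fov = np.ones(img.shape, dtype=bool)
        thrs = []
        for r in range(0, 90, 30):
            for c in range(0, 120, 40):
                thrs.append(tile_threshold(img[r:r + 30, c:c + 40].ravel()))
        D = build_dynamic_matrix(img, fov, tile_shape=(30, 40), smooth=10)
        assert D.min() >= min(thrs) - 1e-9
        assert D.max() <= max(thrs) + 1e-9

    def test_fov_starved_tiles_imputed(self, rng):
        img = rng.random((60, 60))
        fov = np.zeros((60, 60), dtype=bool)
        fov[:30] = True  # bottom tiles have no FOV pixels
        D = build_dynamic_matrix(img, fov, tile_shape=(30, 30), smooth=0)
        assert np.isfinite(D).all()

    def test_no_valid_tile_rejected(self):
        with pytest.raises(ValueError):
            build_dynamic_matrix(np.zeros((40, 40)),
                                 np.zeros((40, 40), dtype=bool),
                                 tile_shape=(20, 20))


class TestCombineThresholds:
    def test_blend_arithmetic(self):
        S = np.full((4, 4), 0.5)
        D = np.full((4, 4), 0.7)
        assert np.allclose(combine_thresholds(S, D, 0.1), 0.68)

    def test_endpoints_reduce_to_inputs(self, rng):
        S, D = rng.random((8, 8)), rng.random((8, 8))
        assert np.array_equal(combine_thresholds(S, D, 1.0), S)
        assert np.array_equal(combine_thresholds(S, D, 0.0), D)

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(k=st.floats(0.0, 1.0), seed=st.integers(0, 1000))
    def test_convex_combination_bounded(self, k, seed):
        r = np.random.default_rng(seed)
        S, D = r.random((6, 6)), r.random((6, 6))
        T = combine_thresholds(S, D, k)
        assert (T >= np.minimum(S, D) - 1e-12).all()
        assert (T <= np.maximum(S, D) + 1e-12).all()

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            combine_thresholds(np.zeros((3, 3)), np.zeros((4, 4)), 0.5)


class TestSegmentCandidates:
    def test_image_below_threshold_gives_empty_mask(self):
        img = np.full((32, 32), 0.2)
        T = np.full((32, 32), 0.5)
        out = segment_candidates(img, T, np.ones((32, 32), bool))
        assert not out.mask.any() and out.n_components == 0

    def test_blob_inside_od_region_excluded(self):
        img = np.full((64, 64), 0.2)
        img[20:30, 20:30] = 0.9
        T = np.full((64, 64), 0.5)
        exclude = np.zeros((64, 64), dtype=bool)
        exclude[15:35, 15:35] = True
        out = segment_candidates(img, T, np.ones((64, 64), bool),
                                 exclude=exclude)
        assert not out.mask.any()

    def test_speck_filter_removes_small_components(self):
        img = np.full((64, 64), 0.2)
        img[10, 10] = 0.9                # 1-px speck
        img[30:34, 30:34] = 0.9          # 16-px blob
        T = np.full((64, 64), 0.5)
        out = segment_candidates(img, T, np.ones((64, 64), bool), min_area=5)
        assert out.n_components == 1
        assert out.areas.tolist() == [16]
        assert not out.mask[10, 10]

    def test_outside_fov_values_ignored(self, rng):
        img = rng.random((48, 48))
        T = np.full((48, 48), 0.5)
        fov = np.zeros((48, 48), dtype=bool)
        fov[8:40, 8:40] = True
        out1 = segment_candidates(img, T, fov)
        img2 = img.copy()
        img2[~fov] = rng.random((48, 48))[~fov]
        out2 = segment_candidates(img2, T, fov)
        assert np.array_equal(out1.mask, out2.mask)

    def test_phantom_blobs_recovered_as_components(self, phantom_default,
                                                   prepared_default):
        """Most generated exudate components of >= 10 px overlap a
        candidate component by at least half their area."""
        from skimage import measure

        _, truth = phantom_default
        cand = prepared_default.candidates.mask
        labels = measure.label(truth.exudate_mask, connectivity=2)
        sizes = np.bincount(labels.ravel())
        found = total = 0
        for lab in range(1, labels.max() + 1):
            if sizes[lab] < 10:
                continue
            total += 1
            comp = labels == lab
            found += (cand & comp).sum() >= 0.5 * sizes[lab]
        assert total > 0
        assert found >= max(1, round(total * 5 / 6))
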