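import numpy as np
import pytest

import celltrax as ct
from celltrax.detection import DetectionParams, detector_names

from conftest import disk_mask, gaussian_blob


class TestLogResponse:
    def test_constant_image_gives_zero(self):
        resp = ct.log_response(np.full((30, 30), 57.0), sigma=3.0)
        assert np.all(np.abs(resp) < 1e-9 * 57.0)

    def test_peak_at_gaussian_blob_center(self):
        img = gaussian_blob((61, 61), (30, 30), sigma=3.0, amplitude=100.0)
        resp = ct.log_response(img, sigma=3.0)
        peak = np.unravel_index(np.argmax(resp), resp.shape)
        assert abs(peak[0] - 30) <= 1 and abs(peak[1] - 30) <= 1
        # closed form: max response of a matched blob is 2*A*s^2*t^2/(s^2+t^2)^2
        expected = 2 * 100.0 * 9.0 * 9.0 / (9.0 + 9.0) ** 2
        assert resp[peak] == pytest.approx(expected, rel=0.05)

    def test_linearity(self):
        rng = np.random.default_rng(0)
        img = rng.uniform(0, 50, (40, 40))
        np.testing.assert_allclose(
            ct.log_response(3 * img, 2.0), 3 * ct.log_response(img, 2.0), rtol=1e-10
        )

    def test_rejects_non_finite(self):
        img = np.zeros((10, 10))
        img[3, 3] = np.nan
        with pytest.raises(ValueError, match="non-finite"):
            ct.log_response(img, 2.0)


def brute_force_maxima(resp, threshold, min_distance):
    """Exhaustive local-maximum scan + greedy suppression oracle."""
    h, w = resp.shape
    cands = []
    for r in range(h):
        for c in range(w):
            v = resp[r, c]
            if v <= threshold:
                continue
            neigh = resp[max(0, r - 1) : r + 2, max(0, c - 1) : c + 2]
            if v >= neigh.max():
                cands.append((r, c, v))
    cands.sort(key=lambda x: (-x[2], x[0], x[1]))
    kept = []
    for r, c, v in cands:
        if all((r - kr) ** 2 + (c - kc) ** 2 >= min_distance**2 for kr, kc, _ in kept):
            kept.append((r, c, v))
    return kept


class TestDetectSpots:
    def test_blank_frame(self):
        assert ct.detect_spots(np.zeros((50, 50)), DetectionParams()) == []

    def test_three_well_separated_blobs(self):
        centers = [(15, 15), (15, 48), (48, 30)]
        img = sum(gaussian_blob((64, 64), c, 3.0, 100.0) for c in centers)
        params = DetectionParams(sigma=3.0, threshold=10.0, min_distance=5)
        spots = ct.detect_spots(img, params)
        assert len(spots) == 3
        found = sorted(tuple(map(round, s.centroid)) for s in spots)
        for (fr, fc), (tr, tc) in zip(found, sorted(centers)):
            assert abs(fr - tr) <= 1 and abs(fc - tc) <= 1
        # oracle parity: exhaustive scan of the response array
        resp = ct.log_response(img, 3.0)
        oracle = brute_force_maxima(resp, 10.0, 5)
        assert sorted((r, c) for r, c, _ in oracle) == sorted(
            (int(s.centroid[0]), int(s.centroid[1])) for s in spots
        )

    def test_close_pair_suppressed_to_one(self):
        img = gaussian_blob((40, 40), (20, 18), 2.0, 100.0) + gaussian_blob(
            (40, 40), (20, 22), 2.0, 100.0
        )
        params = DetectionParams(sigma=2.0, threshold=5.0, min_distance=10)
        spots = ct.detect_spots(img, params)
        resp = ct.log_response(img, 2.0)
        oracle = brute_force_maxima(resp, 5.0, 10)
        assert len(spots) == len(oracle) == 1

    def test_sorted_by_descending_response(self):
        img = gaussian_blob((60, 60), (15, 15), 3.0, 100.0) + gaussian_blob(
            (60, 60), (45, 45), 3.0, 50.0
        )
        spots = ct.detect_spots(img, DetectionParams(sigma=3.0, threshold=5.0))
        responses = [s.features["log_response"] for s in spots]
        assert responses == sorted(responses, reverse=True)

    @pytest.mark.parametrize("shift", [(3, 0), (0, 4), (2, 5)])
    def test_translation_equivariance(self, shift):
        rng = np.random.default_rng(1)
        img = np.zeros((80, 80))
        for c in [(25, 25), (25, 55), (55, 40)]:
            img += gaussian_blob((80, 80), c, 3.0, 100.0)
        img += rng.normal(0, 1.0, img.shape) * 0  # noiseless; shift must be exact
        shifted = np.roll(np.roll(img, shift[0], axis=0), shift[1], axis=1)
        params = DetectionParams(sigma=3.0, threshold=10.0)
        a = sorted(s.centroid for s in ct.detect_spots(img, params))
        b = sorted(s.centroid for s in ct.detect_spots(shifted, params))
        for (ra, ca), (rb, cb) in zip(a, b):
            assert (rb - ra, cb - ca) == shift


class TestSegmentRegions:
    def test_two_disjoint_disks_recovered(self):
        img = np.full((60, 60), 5.0)
        img[disk_mask((60, 60), (18, 18), 7) > 0] = 100.0
        img[disk_mask((60, 60), (42, 42), 7) > 0] = 100.0
        params = DetectionParams(sigma=5.0, smoothing_sigma=0.5, region_level=None)
        spots = [
            ct.Roi(1, 0, (18.0, 18.0), (14, 14, 23, 23)),
            ct.Roi(2, 0, (42.0, 42.0), (38, 38, 47, 47)),
        ]
        masks, rois, empty = ct.segment_regions(img, spots, params)
        assert empty == []
        for roi, center in zip(rois, [(18, 18), (42, 42)]):
            truth = disk_mask((60, 60), center, 7) > 0
            got = np.zeros((60, 60), dtype=bool)
            got[roi.region[:, 0], roi.region[:, 1]] = True
            # agreement up to a 1-px boundary band
            from scipy import ndimage as ndi

            band = ndi.binary_dilation(truth) & ~ndi.binary_erosion(truth)
            assert not np.any((got ^ truth) & ~band)

    def test_overlapping_blobs_partition_foreground(self):
        img = gaussian_blob((40, 40), (20, 14), 4.0, 100.0) + gaussian_blob(
            (40, 40), (20, 26), 4.0, 100.0
        )
        params = DetectionParams(sigma=4.0, fg_method="fixed", fg_value=20.0,
                                 region_level=None)
        spots = [
            ct.Roi(1, 0, (20.0, 14.0), (16, 10, 25, 19)),
            ct.Roi(2, 0, (20.0, 26.0), (16, 22, 25, 31)),
        ]
        masks, rois, empty = ct.segment_regions(img, spots, params)
        lab = masks.frames[0]
        smoothed_fg = None
        # regions are disjoint, inside foreground, and each contains its marker
        assert lab[20, 14] == 1 and lab[20, 26] == 2
        from scipy import ndimage as ndi

        sm = ndi.gaussian_filter(img, params.smoothing_sigma)
        assert np.all(sm[lab > 0] > 20.0)
        # nearest-marker-by-descent oracle: the ridge is the equidistant column
        left, right = lab == 1, lab == 2
        assert np.sum(left) == pytest.approx(np.sum(right), rel=0.1)

    def test_marker_on_background_reported_empty(self):
        img = np.full((30, 30), 5.0)
        img[disk_mask((30, 30), (15, 15), 5) > 0] = 100.0
        params = DetectionParams(fg_method="fixed", fg_value=50.0)
        spots = [
            ct.Roi(1, 0, (15.0, 15.0), (11, 11, 20, 20)),
            ct.Roi(2, 0, (3.0, 3.0), (1, 1, 6, 6)),
        ]
        _, rois, empty = ct.segment_regions(img, spots, params)
        assert empty == [2]

    def test_spot_out_of_bounds_rejected(self):
        with pytest.raises(ValueError, match="outside"):
            ct.segment_regions(
                np.zeros((20, 20)),
                [ct.Roi(1, 0, (25.0, 5.0), (23, 3, 28, 8))],
                DetectionParams(),
            )


class TestComputeFeatures:
    def test_constant_disk_intensities(self):
        mask = disk_mask((40, 40), (20, 20), 6)
        stack = ct.FrameStack(np.full((1, 40, 40), 10.0))
        roi = ct.rois_from_masks(ct.LabeledMasks([mask]), stack)[0][0]
        area = int(np.sum(mask > 0))
        assert roi.features["area"] == area
        assert roi.features["mean_intensity"] == pytest.approx(10.0)
        assert roi.features["sum_intensity"] == pytest.approx(10.0 * area)

    def test_square_area(self):
        mask = np.zeros((20, 20), dtype=np.int32)
        mask[5:10, 5:10] = 1
        roi = ct.rois_from_masks(ct.LabeledMasks([mask]))[0][0]
        stack = ct.FrameStack(np.zeros((1, 20, 20)))
        feats = ct.compute_features(roi, stack)
        assert feats["area"] == 25

    def test_circularity_of_large_disk(self):
        mask = disk_mask((60, 60), (30, 30), 20)
        stack = ct.FrameStack(np.zeros((1, 60, 60)))
        roi = ct.rois_from_masks(ct.LabeledMasks([mask]), stack)[0][0]
        assert 0.85 <= roi.features["circularity"] <= 1.05

    def test_multichannel_features(self):
        mask = disk_mask((30, 30), (15, 15), 4)
        pixels = np.stack([np.full((30, 30), 3.0), np.full((30, 30), 7.0)])[None]
        stack = ct.FrameStack(pixels)
        roi = ct.rois_from_masks(ct.LabeledMasks([mask]), stack)[0][0]
        assert roi.features["mean_intensity_c0"] == pytest.approx(3.0)
        assert roi.features["mean_intensity_c1"] == pytest.approx(7.0)

    def test_empty_region_rejected(self):
        roi = ct.Roi(1, 0, (5.0, 5.0), (5, 5, 6, 6), region=np.empty((0, 2), dtype=int))
        with pytest.raises(ValueError, match="empty"):
            ct.compute_features(roi, ct.FrameStack(np.zeros((1, 10, 10))))


class TestPluginRegistry:
    def test_builtin_names_registered(self):
        assert {"log_spots", "log_watershed", "masks"} <= set(detector_names())

    def test_log_spots_dispatch_identity(self):
        img = gaussian_blob((40, 40), (20, 20), 3.0, 100.0)
        params = DetectionParams(sigma=3.0, threshold=5.0)
        direct = ct.detect_spots(img, params)
        via = ct.run_detector_plugin("log_spots", img, params)
        assert [(s.centroid, s.bbox) for s in direct] == [(s.centroid, s.bbox) for s in via]

    def test_unknown_name(self):
        with pytest.raises(KeyError, match="no detector"):
            ct.run_detector_plugin("nope", np.zeros((5, 5)), DetectionParams())

    def test_masks_plugin_matches_rois_from_masks(self):
        lab = disk_mask((30, 30), (10, 10), 3, label=1) + disk_mask(
            (30, 30), (22, 22), 4, label=2
        )
        via = ct.run_detector_plugin("masks", lab, None)
        oracle = ct.rois_from_masks(ct.LabeledMasks([lab]))[0]
        assert len(via) == len(oracle) == 2
        assert [len(r.region) for r in via] == [len(r.region) for r in oracle]

    def test_contract_violation_names_plugin(self):
        def bad(frame, params):
            return [ct.Roi(1, 0, (100.0, 100.0), (0, 0, 2, 2))]

        ct.register_detector("bad_test_plugin", bad)
        with pytest.raises(ValueError, match="bad_test_plugin"):
            ct.run_detector_plugin("bad_test_plugin", np.zeros((5, 5)), None)


def test_detection_recall_precision_on_default_movie(default_movie, default_pipeline):
    """On the well-separated regime, detection finds essentially every cell."""
    _, _, gt_masks, _ = default_movie
    rois, _ = default_pipeline
    tp = fp = fn = 0
    for t, frame_rois in enumerate(rois):
        gt = gt_masks.frames[t]
        gt_labels = set(np.unique(gt)) - {0}
        hit = set()
        for r in frame_rois:
            lab = gt[int(round(r.centroid[0])), int(round(r.centroid[1]))]
            if lab > 0 and lab not in hit:
                hit.add(lab)
                tp += 1
            else:
                fp += 1
        fn += len(gt_labels - hit)
    recall = tp / (tp + fn)
    precision = tp / (tp + fp)
    assert recall >= 0.95 and precision >= 0.95
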