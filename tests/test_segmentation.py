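"""Wavelet detection, watershed splitting, stitching."""

import numpy as np
import pytest

from emtscreen import (
    SegmentationParams,
    atrous_b3,
    segment_field,
    segment_well,
    stitch_masks,
    watershed_split,
    wavelet_detect,
)

from .conftest import one_to_one_matches


def gaussian_blob(shape, cy, cx, sigma, amp, offset=0.0):
    yy, xx = np.mgrid[0 : shape[0], 0 : shape[1]]
    return offset + amp * np.exp(-((xx - cx) ** 2 + (yy - cy) ** 2) / (2 * sigma**2))


class TestAtrous:
    def test_reconstruction_is_exact(self):
        rng = np.random.default_rng(0)
        img = rng.uniform(0, 100, size=(64, 64))
        details, residual = atrous_b3(img, 3)
        np.testing.assert_allclose(sum(details) + residual, img, atol=1e-9)

    def test_constant_has_no_detail(self):
        details, residual = atrous_b3(np.full((64, 64), 42.0), 3)
        for d in details:
            np.testing.assert_allclose(d, 0.0, atol=1e-10)

    def test_linear_ramp_has_no_detail(self):
        img = np.tile(np.linspace(0, 500, 128), (128, 1))
        details, _ = atrous_b3(img, 3)
        for d in details:
            np.testing.assert_allclose(d, 0.0, atol=1e-8)


class TestWaveletDetect:
    def test_constant_image_empty_mask(self):
        assert wavelet_detect(np.full((128, 128), 100.0)).sum() == 0

    def test_ramp_background_yields_no_nuclei(self):
        img = np.tile(np.linspace(0, 500, 512), (512, 1))
        seg = segment_field(img)
        assert len(seg.centroids) == 0

    def test_single_blob_single_component(self):
        img = gaussian_blob((256, 256), 131, 128, sigma=4, amp=1000, offset=100)
        mask = wavelet_detect(img)
        from skimage.measure import label

        assert label(mask, connectivity=2).max() == 1
        seg = segment_field(img)
        assert len(seg.centroids) == 1
        assert seg.centroids.loc[0, "x_px"] == pytest.approx(128, abs=1.0)
        assert seg.centroids.loc[0, "y_px"] == pytest.approx(131, abs=1.0)

    def test_offset_invariance(self):
        img = gaussian_blob((128, 128), 60, 70, sigma=3, amp=800, offset=50)
        a = segment_field(img)
        b = segment_field(img + 123.0)
        assert np.array_equal(a.labels, b.labels)

    def test_nonfinite_rejected(self):
        img = np.ones((32, 32))
        img[3, 3] = np.nan
        with pytest.raises(ValueError):
            wavelet_detect(img)


class TestWatershedSplit:
    def test_isolated_blob_one_label(self):
        img = gaussian_blob((128, 128), 64, 64, sigma=3, amp=1000)
        mask = wavelet_detect(img)
        labels, oversized = watershed_split(mask, img)
        assert labels.max() == 1
        assert not oversized

    def test_touching_blobs_split_in_two(self):
        img = (
            gaussian_blob((128, 128), 64, 58, sigma=3, amp=1000)
            + gaussian_blob((128, 128), 64, 67, sigma=3, amp=1000)  # 3 sigma apart
        )
        seg = segment_field(img)
        assert seg.labels.max() == 2
        xs = np.sort(seg.centroids["x_px"].to_numpy())
        assert xs[0] == pytest.approx(58, abs=2.0)
        assert xs[1] == pytest.approx(67, abs=2.0)

    def test_component_below_min_area_removed(self):
        # a 3x3 foreground component (9 px < 20 px min) yields no label
        mask = np.zeros((64, 64), bool)
        mask[30:33, 30:33] = True
        img = np.where(mask, 1000.0, 0.0)
        labels, _ = watershed_split(mask, img)
        assert labels.max() == 0

    def test_shape_mismatch_raises(self):
        with pytest.raises(ValueError):
            watershed_split(np.zeros((10, 10), bool), np.zeros((12, 10)))

    def test_area_filter_idempotent(self):
        from emtscreen.segmentation import _filter_areas

        img = (
            gaussian_blob((128, 128), 40, 40, sigma=3, amp=900)
            + gaussian_blob((128, 128), 90, 80, sigma=3, amp=900)
        )
        params = SegmentationParams()
        mask = wavelet_detect(img, params)
        labels, _ = watershed_split(mask, img, params)
        again, _ = _filter_areas(labels, params)
        assert np.array_equal(labels, again)


class TestSegmentFieldCounts:
    def test_well_separated_noiseless_exact_count(self):
        rng = np.random.default_rng(1)
        # 10x10 grid of nuclei, 24 px apart, slight jitter
        img = np.full((256, 256), 50.0)
        truth = []
        for i in range(10):
            for j in range(10):
                cy = 10 + 24 * i + rng.uniform(-2, 2)
                cx = 10 + 24 * j + rng.uniform(-2, 2)
                img += gaussian_blob((256, 256), cy, cx, sigma=2, amp=3000)
                truth.append((cx, cy))
        seg = segment_field(img)
        assert len(seg.centroids) == 100
        det = seg.centroids[["x_px", "y_px"]].to_numpy()
        assert one_to_one_matches(det, np.array(truth), tol_um=3.0) == 100

    def test_noisy_count_within_five_percent(self):
        rng = np.random.default_rng(2)
        img = np.full((256, 256), 50.0)
        for i in range(10):
            for j in range(10):
                img += gaussian_blob(
                    (256, 256), 10 + 24 * i, 10 + 24 * j, sigma=2, amp=3000
                )
        img = img + rng.normal(0, 300, img.shape)  # 10% of peak
        seg = segment_field(img)
        assert abs(len(seg.centroids) - 100) <= 5


class TestStitching:
    def _blob_fields(self, cx, cy):
        yy, xx = np.mgrid[0:512, 0:512]
        mont = 50 + 2000 * np.exp(-((xx - cx) ** 2 + (yy - cy) ** 2) / (2 * 9.0))
        return [
            mont[(i // 2) * 256 : (i // 2 + 1) * 256, (i % 2) * 256 : (i % 2 + 1) * 256]
            for i in range(4)
        ]

    def test_interior_nucleus_centroid_preserved(self):
        fields = self._blob_fields(80, 300)  # interior of field 2
        well, cent = segment_well(fields)
        assert well.labels.max() == 1
        assert cent.loc[0, "x_px"] == pytest.approx(80, abs=1.0)
        assert cent.loc[0, "y_px"] == pytest.approx(300, abs=1.0)
        assert well.provenance[1] == (2,)

    def test_seam_straddling_nucleus_merged_once(self):
        fields = self._blob_fields(256, 100)  # on the vertical seam
        well, cent = segment_well(fields)
        assert well.labels.max() == 1
        assert well.n_seam_merges >= 1
        assert well.provenance[1] == (0, 1)
        assert cent.loc[0, "x_px"] == pytest.approx(256, abs=2.0)
        assert cent.loc[0, "y_px"] == pytest.approx(100, abs=2.0)

    def test_four_empty_fields(self):
        fields = [np.full((64, 64), 10.0)] * 4
        well, cent = segment_well(fields)
        assert well.labels.max() == 0
        assert len(cent) == 0

    def test_missing_field_raises_with_index(self):
        with pytest.raises(ValueError, match="3"):
            stitch_masks([np.zeros((8, 8), int)] * 3)

    def test_count_conservation(self):
        # labels after stitching = sum of per-field labels - seam merges
        fields = self._blob_fields(256, 100)
        segs = [segment_field(f) for f in fields]
        per_field = sum(s.labels.max() for s in segs)
        well, _ = segment_well(fields)
        assert well.labels.max() == per_field - well.n_seam_merges


class TestRecoveryOnSyntheticWell:
    def test_recall_and_precision(self, simulated_well):
        f1, f2, truth = simulated_well
        for flds, true in ((f1, truth.centers_t1), (f2, truth.centers_t2)):
            well, cent = segment_well([f.pixels for f in flds])
            det = cent[["x_px", "y_px"]].to_numpy() * 1.6
            matched = one_to_one_matches(det, true, tol_um=8.0)
            assert matched / len(true) >= 0.95
            assert 1 - matched / len(det) <= 0.05
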