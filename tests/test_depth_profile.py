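"""Depth binning, image-dependent thresholding, area-fraction profiles."""

import numpy as np
import pytest

from cervimage import (
    ChannelImage,
    DepthMap,
    EpitheliumMask,
    MarkerMask,
    SegmentScheme,
    assign_depth_bins,
    double_positive,
    profile_segments,
    threshold_marker,
)


def _depth_map(values, reference="apical", px=1.0):
    return DepthMap(depth_um=np.asarray(values, float), reference=reference, pixel_size_um=px)


class TestSegmentScheme:
    def test_default_intervals_match_published_scheme(self):
        scheme = SegmentScheme()
        assert scheme.intervals() == [
            (10.0, 50.0), (50.0, 100.0), (100.0, 150.0), (150.0, 200.0),
            (200.0, 250.0), (250.0, 300.0), (300.0, None),
        ]

    @pytest.mark.parametrize(
        "kw", [dict(apical_exclusion_um=60), dict(bin_width_um=0),
               dict(cap_um=320), dict(bin_width_um=400)],
    )
    def test_invalid_schemes_rejected(self, kw):
        with pytest.raises(ValueError):
            SegmentScheme(**kw)


class TestAssignDepthBins:
    def test_edge_values_get_documented_labels(self):
        depth = _depth_map([[5, 10, 49.999, 50, 299, 300, 512]])
        labels = assign_depth_bins(depth, SegmentScheme())
        assert labels.tolist() == [[0, 1, 1, 2, 6, 7, 7]]

    def test_everything_inside_excluded_margin(self):
        depth = _depth_map(np.full((5, 5), 7.0))
        labels = assign_depth_bins(depth, SegmentScheme())
        assert np.all(labels == 0)

    def test_outside_mask_labelled_minus_one(self):
        depth = _depth_map([[np.nan, 20.0]])
        labels = assign_depth_bins(depth, SegmentScheme())
        assert labels.tolist() == [[-1, 1]]

    def test_random_depths_match_interval_membership_oracle(self, rng):
        scheme = SegmentScheme(bin_width_um=40, apical_exclusion_um=8, cap_um=240)
        depth = _depth_map(rng.uniform(0, 500, size=(40, 40)))
        labels = assign_depth_bins(depth, scheme)
        intervals = scheme.intervals()
        for d, lab in zip(depth.depth_um.ravel(), labels.ravel()):
            if d < scheme.apical_exclusion_um:
                expect = 0
            else:
                expect = None
                for k, (lo, hi) in enumerate(intervals, start=1):
                    if d >= lo and (hi is None or d < hi):
                        expect = k
                        break
            assert lab == expect

    def test_non_apical_reference_is_a_misuse_error(self):
        depth = _depth_map([[1.0]], reference="basal")
        with pytest.raises(ValueError, match="apical"):
            assign_depth_bins(depth, SegmentScheme())


class TestThresholdMarker:
    def test_separable_bimodal_recovers_planted_fraction(self, rng):
        img = np.full((100, 100), 10.0)
        pos = rng.random((100, 100)) < 0.07
        img[pos] = 200.0
        ch = ChannelImage(img, "CD4", 1.0)
        mask = EpitheliumMask(np.ones((100, 100), bool), 1.0)
        res = threshold_marker(ch, mask, "otsu")
        assert res.positive_pixels == pos.sum()
        assert 10.0 < res.threshold_value < 200.0

    def test_fixed_zero_threshold_marks_everything(self):
        ch = ChannelImage(np.full((10, 10), 5.0), "CD4", 1.0)
        mask = EpitheliumMask(np.ones((10, 10), bool), 1.0)
        res = threshold_marker(ch, mask, "fixed", threshold=0.0)
        assert res.positive_pixels == 100

    def test_otsu_equals_exhaustive_between_class_variance_search(self, rng):
        """Otsu on a two-component mixture agrees with brute-force
        maximization over all 256 candidate 8-bit levels."""
        vals = np.concatenate([
            np.clip(rng.normal(60, 12, 4000), 0, 255),
            np.clip(rng.normal(190, 15, 1200), 0, 255),
        ]).astype(np.uint8)
        img = vals.reshape(80, 65).astype(float)
        ch = ChannelImage(img, "CD4", 1.0)
        mask = EpitheliumMask(np.ones(img.shape, bool), 1.0)
        res = threshold_marker(ch, mask, "otsu")

        hist = np.bincount(vals, minlength=256).astype(float)
        best, best_t = -1.0, 0
        for t in range(255):
            w0, w1 = hist[: t + 1].sum(), hist[t + 1:].sum()
            if w0 == 0 or w1 == 0:
                continue
            m0 = (np.arange(t + 1) * hist[: t + 1]).sum() / w0
            m1 = (np.arange(t + 1, 256) * hist[t + 1:]).sum() / w1
            v = w0 * w1 * (m0 - m1) ** 2
            if v > best:
                best, best_t = v, t
        # same positive set: pixels strictly above the optimal level
        assert res.positive_pixels == int((vals > best_t).sum())

    def test_constant_image_otsu_falls_back_to_all_negative(self, caplog):
        ch = ChannelImage(np.full((10, 10), 3.0), "CD4", 1.0)
        mask = EpitheliumMask(np.ones((10, 10), bool), 1.0)
        with caplog.at_level("WARNING"):
            res = threshold_marker(ch, mask, "otsu")
        assert res.positive_pixels == 0
        assert any("constant" in r.message for r in caplog.records)

    def test_empty_mask_is_an_error(self):
        ch = ChannelImage(np.ones((10, 10)), "CD4", 1.0)
        mask = EpitheliumMask(np.zeros((10, 10), bool), 1.0)
        with pytest.raises(ValueError):
            threshold_marker(ch, mask, "otsu")

    def test_threshold_computed_from_epithelium_pixels_only(self):
        """A bright artefact outside the ROI must not move the threshold."""
        img = np.full((20, 20), 10.0)
        img[:5, :] = 1000.0  # outside mask
        img[10:12, 10:12] = 200.0
        mask = EpitheliumMask(np.zeros((20, 20), bool), 1.0)
        mask.mask[5:, :] = True
        res = threshold_marker(ChannelImage(img, "CD4", 1.0), mask, "otsu")
        assert res.threshold_value < 200.0
        assert res.positive_pixels == 4


class TestDoublePositive:
    def test_disjoint_masks_empty(self):
        a = MarkerMask(np.eye(5, dtype=bool), "A", 1.0)
        b = MarkerMask(np.flipud(np.eye(5)).astype(bool) & ~np.eye(5, dtype=bool), "B", 1.0)
        assert double_positive(a, b).positive_pixels == 0

    def test_subset_absorption(self, rng):
        big = rng.random((30, 30)) < 0.4
        small = big & (rng.random((30, 30)) < 0.5)
        res = double_positive(MarkerMask(big, "A", 1), MarkerMask(small, "B", 1))
        assert np.array_equal(res.mask, small)
        assert res.marker_name == "A+B+"

    def test_random_overlap_equals_pixel_count(self, rng):
        a = rng.random((50, 50)) < 0.3
        b = rng.random((50, 50)) < 0.2
        res = double_positive(MarkerMask(a, "A", 1), MarkerMask(b, "B", 1))
        assert res.positive_pixels == int((a & b).sum())

    def test_dimension_mismatch(self):
        with pytest.raises(ValueError):
            double_positive(
                MarkerMask(np.ones((5, 5), bool), "A", 1),
                MarkerMask(np.ones((5, 6), bool), "B", 1),
            )


def _layered_setup(px=1.0):
    """Flat epithelium, 60 rows deep, apical at row 0."""
    H, W = 60, 100
    mask = EpitheliumMask(np.ones((H, W), bool), px)
    depth = DepthMap(np.arange(H, dtype=float)[:, None] * np.ones((1, W)) * px,
                     "apical", px)
    scheme = SegmentScheme(bin_width_um=20 * px, apical_exclusion_um=5 * px,
                           cap_um=40 * px)
    labels = assign_depth_bins(depth, scheme)
    return mask, depth, scheme, labels


class TestProfileSegments:
    def test_indicator_marker_fills_one_bin(self):
        mask, depth, scheme, labels = _layered_setup()
        m = np.zeros(mask.shape, bool)
        m[labels == 2] = True
        prof = profile_segments([MarkerMask(m, "CD4", 1)], labels, mask, scheme)
        fr = prof.per_bin_pct["CD4"]
        assert fr[1] == pytest.approx(100.0)
        assert fr[0] == 0.0 and fr[2] == 0.0
        bin2_share = (labels == 2).sum() / mask.mask.sum()
        assert prof.overall_pct["CD4"] == pytest.approx(100.0 * bin2_share)

    def test_no_positive_pixels_gives_all_zero(self):
        mask, depth, scheme, labels = _layered_setup()
        prof = profile_segments(
            [MarkerMask(np.zeros(mask.shape, bool), "CD4", 1)], labels, mask, scheme
        )
        assert np.nansum(prof.per_bin_pct["CD4"]) == 0.0
        assert prof.overall_pct["CD4"] == 0.0

    def test_empty_bin_reported_missing_not_zero(self):
        mask, depth, scheme, labels = _layered_setup()
        # epithelium only 60 px deep -> terminal bin beyond 40 px exists, but
        # restrict mask so no pixel falls in bin 2
        mask.mask[(labels == 2)] = False
        labels = np.where(mask.mask, labels, -1)
        prof = profile_segments(
            [MarkerMask(np.zeros(mask.shape, bool), "CD4", 1)], labels, mask, scheme
        )
        assert np.isnan(prof.per_bin_pct["CD4"][1])

    def test_bin_area_times_fraction_conserves_positive_area(self, rng):
        mask, depth, scheme, labels = _layered_setup(px=2.0)
        m = mask.mask & (rng.random(mask.shape) < 0.1)
        prof = profile_segments([MarkerMask(m, "CD4", 1)], labels, mask, scheme)
        px_to_mm2 = (mask.pixel_size_um / 1000.0) ** 2
        recovered = np.nansum(prof.bin_area_mm2 * prof.per_bin_pct["CD4"] / 100.0)
        included_pos = int((m & (labels >= 1)).sum())
        assert recovered == pytest.approx(included_pos * px_to_mm2, rel=1e-12)

    def test_overall_fraction_independent_of_bin_width(self, small_phantom):
        _, channels, _, truth = small_phantom
        mask = truth.mask
        m = threshold_marker(channels["CD4"], mask, "otsu")
        for width in (25.0, 50.0):
            scheme = SegmentScheme(bin_width_um=width, apical_exclusion_um=10, cap_um=300)
            labels = assign_depth_bins(truth.depth, scheme)
            prof = profile_segments([m], labels, mask, scheme)
            assert prof.overall_pct["CD4"] == pytest.approx(
                100.0 * m.positive_pixels / mask.mask.sum()
            )

    def test_double_positive_bounded_by_min_of_parents(self, small_phantom):
        _, channels, _, truth = small_phantom
        mask, scheme = truth.mask, truth.scheme
        labels = truth.bin_labels
        a = threshold_marker(channels["CD4"], mask)
        b = threshold_marker(channels["CCR5"], mask)
        prof = profile_segments([a, b, double_positive(a, b)], labels, mask, scheme)
        dp = prof.overall_pct["CD4+CCR5+"]
        assert dp <= min(prof.overall_pct["CD4"], prof.overall_pct["CCR5"]) + 1e-12

    def test_rot90_leaves_fractions_unchanged(self):
        mask, depth, scheme, labels = _layered_setup()
        rng = np.random.default_rng(3)
        m = mask.mask & (rng.random(mask.shape) < 0.2)
        prof = profile_segments([MarkerMask(m, "CD4", 1)], labels, mask, scheme)
        rmask = EpitheliumMask(np.rot90(mask.mask).copy(), mask.pixel_size_um)
        rprof = profile_segments(
            [MarkerMask(np.rot90(m).copy(), "CD4", 1)],
            np.rot90(labels).copy(), rmask, scheme,
        )
        np.testing.assert_allclose(
            prof.per_bin_pct["CD4"], rprof.per_bin_pct["CD4"], equal_nan=True
        )

    def test_positive_outside_epithelium_rejected(self):
        mask, depth, scheme, labels = _layered_setup()
        m = np.zeros(mask.shape, bool)
        mask.mask[0, 0] = False
        labels[0, 0] = -1
        m[0, 0] = True
        with pytest.raises(ValueError, match="outside"):
            profile_segments([MarkerMask(m, "CD4", 1)], labels, mask, scheme)

    def test_long_format_export(self):
        mask, depth, scheme, labels = _layered_setup()
        prof = profile_segments(
            [MarkerMask(np.zeros(mask.shape, bool), "CD4", 1)], labels, mask, scheme
        )
        df = prof.to_frame(sample_id="s1", image_id="i1")
        # one row per bin plus one overall row
        assert len(df) == scheme.n_labels + 1
        assert set(df.columns) >= {
            "sample_id", "image_id", "marker", "bin_lower_um",
            "bin_upper_um", "area_mm2", "positive_fraction_pct", "threshold_value",
        }
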