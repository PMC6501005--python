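import numpy as np
import pytest

from conftest import nucleus_record
from _oracles import radial_binning_profile
from periscope.radial import (
    NucleusRecord,
    aggregate_profiles,
    compare_conditions,
    mfi_summary,
    radial_scan,
    segment_nuclei,
)
from periscope.simulate import NucleusSimParams, make_nucleus_cohort
from periscope.radial import records_from_labels


def disk_image(size=128, center=(64, 64), radius=30, value=200.0):
    rr, cc = np.mgrid[0:size, 0:size]
    mask = (rr - center[0]) ** 2 + (cc - center[1]) ** 2 <= radius**2
    return np.where(mask, value, 0.0), mask


class TestSegmentNuclei:
    def test_two_disks_found(self):
        img1, _ = disk_image(center=(40, 40), radius=20)
        img2, _ = disk_image(center=(90, 90), radius=15)
        records = segment_nuclei(img1 + img2, min_area=100)
        assert len(records) == 2
        areas = sorted(r.mask.sum() for r in records)
        assert areas[0] < areas[1]

    def test_border_touching_component_excluded(self):
        img, _ = disk_image(center=(10, 64), radius=20)
        assert segment_nuclei(img, min_area=10) == []
        assert len(segment_nuclei(img, min_area=10, border_policy="include")) == 1

    def test_small_speck_filtered_by_min_area(self):
        img = np.zeros((64, 64))
        img[30:32, 30:33] = 100.0  # 6-px speck
        assert segment_nuclei(img, min_area=50) == []

    def test_non_2d_input_rejected(self):
        with pytest.raises(ValueError, match="2-D"):
            segment_nuclei(np.zeros((4, 4, 3)))

    def test_centroid_inside_mask(self):
        img, mask = disk_image()
        (rec,) = segment_nuclei(img, min_area=100)
        cr, cc = rec.centroid
        assert rec.mask[int(round(cr)), int(round(cc))]


class TestRadialScan:
    def test_uniform_disk_gives_constant_profile(self):
        img, mask = disk_image(value=200.0)
        (rec,) = segment_nuclei(img, min_area=100)
        prof = radial_scan(rec)
        dev = np.abs(prof.mean_intensity[:-2] - 200.0) / 200.0
        assert dev.max() <= 0.02

    def test_planted_ring_recovered_inside_and_outside_transition(self, ring_nucleus):
        rec, _ = ring_nucleus
        prof = radial_scan(rec)
        f = prof.radius_fractions
        inner = prof.mean_intensity[f < 0.7]
        outer = prof.mean_intensity[(f > 0.8) & (f <= 0.98)]
        assert np.allclose(inner, 100.0, rtol=0.03)
        assert np.allclose(outer, 400.0, rtol=0.05)

    def test_agrees_with_per_pixel_binning_oracle(self, smooth_ring_nucleus):
        rec, truth = smooth_ring_nucleus
        prof = radial_scan(rec)
        f, oracle = radial_binning_profile(rec.intensity, truth)
        sel = (f >= 0.05) & (f <= 0.95) & np.isfinite(oracle)
        rms = np.sqrt(np.mean((prof.mean_intensity[sel] - oracle[sel]) ** 2))
        assert rms / oracle[sel].mean() <= 0.05

    def test_rotation_by_90_degrees_leaves_profile_unchanged(self):
        params = NucleusSimParams(
            noise_sd=0.0, ring_contrast=4.0, rotation=0.4, semi_axes=(55.0, 40.0)
        )
        rec, _ = nucleus_record(params)
        prof = radial_scan(rec)
        from scipy import ndimage

        img90 = np.rot90(rec.intensity)
        mask90 = np.rot90(rec.mask)
        c90 = ndimage.center_of_mass(mask90)
        prof90 = radial_scan(NucleusRecord(1, img90, mask90, c90))
        rms = np.sqrt(np.mean((prof.mean_intensity - prof90.mean_intensity) ** 2))
        assert rms / prof.mean_intensity.mean() <= 0.01

    def test_integer_translation_leaves_profile_unchanged(self, flat_nucleus):
        rec, _ = flat_nucleus
        prof = radial_scan(rec)
        shifted = NucleusRecord(
            2,
            np.pad(rec.intensity, ((7, 0), (3, 0)))[: rec.intensity.shape[0], : rec.intensity.shape[1]],
            np.pad(rec.mask, ((7, 0), (3, 0)))[: rec.mask.shape[0], : rec.mask.shape[1]],
            (rec.centroid[0] + 7, rec.centroid[1] + 3),
        )
        prof_shift = radial_scan(shifted)
        rms = np.sqrt(np.mean((prof.mean_intensity - prof_shift.mean_intensity) ** 2))
        assert rms / prof.mean_intensity.mean() <= 0.01

    def test_mean_is_exact_mean_of_lines(self, ring_nucleus):
        rec, _ = ring_nucleus
        prof = radial_scan(rec)
        np.testing.assert_array_equal(
            prof.mean_intensity, prof.per_line_intensity.mean(axis=0)
        )

    def test_degenerate_mask_rejected(self):
        img = np.zeros((16, 16))
        mask = np.zeros((16, 16), bool)
        mask[8, 8] = True
        with pytest.raises(ValueError, match="degenerate nucleus"):
            radial_scan(NucleusRecord(1, img, mask, (8.0, 8.0)))

    def test_centroid_outside_mask_rejected(self):
        img, mask = disk_image()
        with pytest.raises(ValueError, match="degenerate nucleus"):
            radial_scan(NucleusRecord(1, img, mask, (2.0, 2.0)))


class TestAggregateAndMfi:
    def _constant_profile(self, value, n_points=50):
        img, mask = disk_image(value=value)
        (rec,) = segment_nuclei(img, min_area=100)
        return radial_scan(rec, n_lines=64, n_points=n_points)

    def test_mean_and_population_sd(self):
        p10 = self._constant_profile(10.0)
        p20 = self._constant_profile(20.0)
        agg = aggregate_profiles([p10, p20])
        assert np.allclose(agg.mean, 15.0, rtol=0.02)
        assert np.allclose(agg.sd, 5.0, rtol=0.05)

    def test_single_profile_sd_zero(self):
        p = self._constant_profile(10.0)
        agg = aggregate_profiles([p])
        np.testing.assert_array_equal(agg.mean, p.mean_intensity)
        assert np.all(agg.sd == 0.0)

    def test_empty_list_rejected(self):
        with pytest.raises(ValueError):
            aggregate_profiles([])

    def test_mixed_n_points_rejected(self):
        with pytest.raises(ValueError, match="mixed"):
            aggregate_profiles(
                [self._constant_profile(10.0, 50), self._constant_profile(10.0, 60)]
            )

    def test_constant_profile_enrichment_is_one(self):
        s = mfi_summary(self._constant_profile(42.0))
        assert s.center_mfi == pytest.approx(42.0, rel=1e-6)
        assert s.peripheral_enrichment == pytest.approx(1.0, rel=1e-6)
        assert not s.undefined

    def test_zero_center_flags_undefined(self):
        from periscope.radial import RadialProfile

        f = np.linspace(0, 1, 200)
        prof = RadialProfile(1, 200, 200, f, np.where(f >= 0.75, 1.0, 0.0))
        s = mfi_summary(prof)
        assert s.center_mfi == 0.0
        assert s.periphery_mfi == 1.0
        assert s.undefined and np.isnan(s.peripheral_enrichment)

    def test_ring_fixture_enrichment_within_15_percent(self, ring_nucleus):
        rec, truth = ring_nucleus
        s = mfi_summary(radial_scan(rec))
        assert abs(s.peripheral_enrichment - truth["ring_contrast"]) <= 0.15 * truth[
            "ring_contrast"
        ]

    def test_invalid_band_bounds_rejected(self, ring_nucleus):
        rec, _ = ring_nucleus
        prof = radial_scan(rec)
        with pytest.raises(ValueError):
            mfi_summary(prof, center_frac=0.8, periphery_frac=0.75)


class TestCompareConditions:
    def _cohort_aggregate(self, contrast, seed):
        image, labels, _ = make_nucleus_cohort(
            6, image_size=(640, 640), ring_contrast=contrast, noise_sd=10.0, seed=seed
        )
        records = records_from_labels(image, labels)
        return aggregate_profiles([radial_scan(r, n_lines=100, n_points=100) for r in records])

    def test_planted_contrast_ordering_recovered(self):
        agg1 = self._cohort_aggregate(1.0, seed=1)
        agg4 = self._cohort_aggregate(4.0, seed=2)
        curves, summaries = compare_conditions([("flat", agg1), ("ring", agg4)])
        by_label = summaries.set_index("condition")["peripheral_enrichment"]
        assert by_label["ring"] > by_label["flat"]
        assert set(curves["condition"]) == {"flat", "ring"}
        assert len(curves) == 2 * 100

    def test_identical_cohorts_identical_rows(self):
        agg = self._cohort_aggregate(2.0, seed=3)
        curves, summaries = compare_conditions([("a", agg), ("b", agg)])
        a_rows = curves[curves["condition"] == "a"].drop(columns="condition")
        b_rows = curves[curves["condition"] == "b"].drop(columns="condition")
        np.testing.assert_array_equal(a_rows.to_numpy(), b_rows.to_numpy())
        assert summaries["peripheral_enrichment"].nunique() == 1

    def test_single_condition_rejected(self):
        agg = self._cohort_aggregate(1.0, seed=4)
        with pytest.raises(ValueError, match="two conditions"):
            compare_conditions([("only", agg)])

    def test_duplicate_labels_rejected(self):
        agg = self._cohort_aggregate(1.0, seed=5)
        with pytest.raises(ValueError, match="duplicate"):
            compare_conditions([("x", agg), ("x", agg)])
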