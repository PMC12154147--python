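"""Vessel, leakage and tight-junction morphometry."""

import json

import numpy as np
import pytest

from fusquant.microscopy import (
    GAP_CUTOFF_UM,
    TJStrand,
    ZStack,
    bin_gaps_and_fractions,
    classify_caliber,
    corrected_intensity,
    detect_leaky_vessels,
    fraction_leaky,
    if_area_mask,
    leakage_mask,
    max_intensity_projection,
    measure_gaps,
    normalized_optical_density,
    segment_vessels,
    trace_tj_strands,
)
from fusquant.synthetic import StrandSpec, VesselScene, VesselSpec, gen_vessel_image


class TestProjection:
    def test_single_plane_identity(self):
        data = np.random.default_rng(0).random((1, 3, 8, 8))
        stack = ZStack(data=data, pixel_size_um=0.2)
        np.testing.assert_array_equal(max_intensity_projection(stack).data, data[0])

    def test_matches_bruteforce_loop(self):
        rng = np.random.default_rng(1)
        data = rng.random((5, 3, 12, 10))
        mip = max_intensity_projection(ZStack(data=data, pixel_size_um=0.2)).data
        for c in range(3):
            for y in range(12):
                for x in range(10):
                    assert mip[c, y, x] == max(data[z, c, y, x] for z in range(5))

    def test_disjoint_bright_pixels_union(self):
        data = np.zeros((2, 1, 4, 4))
        data[0, 0, 0, 0] = 5.0
        data[1, 0, 3, 3] = 7.0
        stack = ZStack(data=data, pixel_size_um=1.0, channels={"vessel": 0})
        mip = max_intensity_projection(stack).data
        assert mip[0, 0, 0] == 5.0 and mip[0, 3, 3] == 7.0


class TestCorrectedIntensity:
    def test_arithmetic_example(self):
        image = np.zeros((10, 10))
        roi = np.zeros((10, 10), bool)
        roi[:2, :5] = True  # 10 px
        image[roi] = 50.0
        bg = np.zeros((10, 10), bool)
        bg[5:, :] = True
        image[bg] = 20.0
        result = corrected_intensity(image, roi, bg)
        assert result.corrected == pytest.approx(500.0 - 10 * 20.0)

    def test_matched_statistics_near_zero(self):
        image = np.full((8, 8), 13.0)
        roi = np.zeros((8, 8), bool)
        roi[:4] = True
        result = corrected_intensity(image, roi, ~roi)
        assert result.corrected == 0.0

    def test_zero_image(self):
        image = np.zeros((6, 6))
        roi = np.zeros((6, 6), bool)
        roi[0] = True
        assert corrected_intensity(image, roi, ~roi).corrected == 0.0

    def test_overlap_rejected(self):
        image = np.ones((4, 4))
        roi = np.ones((4, 4), bool)
        with pytest.raises(ValueError, match="overlap"):
            corrected_intensity(image, roi, roi)

    def test_normalized_optical_density_ratio(self):
        image = np.zeros((10, 10))
        ipsi = np.zeros((10, 10), bool)
        ipsi[:2, :2] = True
        contra = np.zeros((10, 10), bool)
        contra[8:, 8:] = True
        bg = np.zeros((10, 10), bool)
        bg[4:6, :] = True
        image[ipsi] = 30.0
        image[contra] = 10.0
        ratio = normalized_optical_density(
            corrected_intensity(image, ipsi, bg), corrected_intensity(image, contra, bg)
        )
        assert ratio == pytest.approx(3.0)


class TestIfAreaMask:
    def test_constant_image_empty_mask(self):
        image = np.full((20, 20), 7.0)
        noise = np.zeros((20, 20), bool)
        noise[:5] = True
        mask, area = if_area_mask(image, noise, pixel_size_um=0.5)
        assert area == 0.0 and mask.sum() == 0  # nothing exceeds c + 0

    def test_bright_blob_recovered(self):
        rng = np.random.default_rng(4)
        image = rng.normal(10.0, 2.0, size=(64, 64))
        blob = np.zeros((64, 64), bool)
        blob[20:40, 20:40] = True
        image[blob] += 20.0  # 10 sd above noise
        noise = np.zeros((64, 64), bool)
        noise[:10] = True
        mask, _ = if_area_mask(image, noise, pixel_size_um=0.2)
        assert (mask & blob).sum() / blob.sum() >= 0.99

    def test_threshold_above_max_zero_area(self):
        image = np.zeros((10, 10))
        image[:5] = 1.0  # noise ROI stats dominate
        noise = np.zeros((10, 10), bool)
        noise[:5] = True
        _, area = if_area_mask(image, noise, pixel_size_um=1.0)
        assert area == 0.0


class TestVesselSegmentation:
    def test_single_tube_diameter(self):
        scene = VesselScene(vessels=(VesselSpec((15.0, 50.0), (85.0, 50.0), 8.0),))
        mip = max_intensity_projection(gen_vessel_image(scene).stack)
        segs = segment_vessels(mip.channel("vessel"), 0.2, threshold=scene.vessel_amplitude / 2)
        assert len(segs) == 1
        assert abs(segs[0].diameter_um - 8.0) <= 0.2  # within 1 px

    def test_two_tubes_two_segments(self):
        scene = VesselScene(
            vessels=(
                VesselSpec((15.0, 30.0), (85.0, 30.0), 6.0),
                VesselSpec((15.0, 70.0), (85.0, 70.0), 12.0),
            )
        )
        mip = max_intensity_projection(gen_vessel_image(scene).stack)
        segs = segment_vessels(mip.channel("vessel"), 0.2, threshold=scene.vessel_amplitude / 2)
        assert len(segs) == 2

    def test_blank_image_no_segments(self):
        assert segment_vessels(np.zeros((64, 64)), 0.2, threshold=10.0) == []


class TestCaliber:
    @pytest.mark.parametrize(
        "diameter,expected", [(4.0, "small"), (9.99, "small"), (10.0, "large"), (12.0, "large")]
    )
    def test_boundary(self, diameter, expected):
        assert classify_caliber(diameter) == expected

    def test_invalid_diameter(self):
        with pytest.raises(ValueError):
            classify_caliber(0.0)


class TestLeakage:
    def test_mask_threshold_semantics(self):
        image = np.ones((5, 5))
        assert leakage_mask(image, 0.0).all()
        assert not leakage_mask(image, 2.0).any()
        with pytest.raises(ValueError, match="explicit"):
            leakage_mask(image, None)

    def test_fixture_flags_exactly_the_leaky_vessels(self, fixture_scene, fixture_mip, fixture_vessels, fixture_render):
        leak = leakage_mask(fixture_mip.channel("tracer"), 75.0)
        records = detect_leaky_vessels(
            fixture_vessels, leak, fixture_mip.channel("tracer"), fixture_mip.pixel_size_um
        )
        flags = [r.is_leaky for r in records]
        assert flags == fixture_render.vessel_truth["is_leaky"].tolist()

    def test_empty_leak_mask_all_negative(self, fixture_mip, fixture_vessels):
        leak = np.zeros(fixture_mip.channel("tracer").shape, bool)
        records = detect_leaky_vessels(
            fixture_vessels, leak, fixture_mip.channel("tracer"), fixture_mip.pixel_size_um
        )
        assert all(not r.is_leaky for r in records)
        assert all(r.leakage_area_um2 == 0 for r in records)

    def test_leakage_everywhere_fills_roi(self, fixture_mip, fixture_vessels):
        shape = fixture_mip.channel("tracer").shape
        leak = np.ones(shape, bool)
        ps = fixture_mip.pixel_size_um
        records = detect_leaky_vessels(
            fixture_vessels, leak, fixture_mip.channel("tracer"), ps, roi_halfwidth_um=10.0
        )
        half_px = round(10.0 / ps)
        roi_px = (2 * half_px + 1) ** 2
        for r in records:
            assert r.is_leaky
            if not r.roi_clipped:
                assert r.leakage_area_um2 == pytest.approx(roi_px * ps**2)


class TestFractionLeaky:
    def _records(self, vessels, leaky_labels):
        from fusquant.microscopy import LeakyVesselRecord

        return [
            LeakyVesselRecord(v.label, v.label in leaky_labels, 0.0, 0.0, 0)
            for v in vessels
        ]

    def test_fraction_arithmetic(self, fixture_vessels):
        small = [v for v in fixture_vessels if v.caliber == "small"]
        records = self._records(fixture_vessels, {small[0].label})
        out = fraction_leaky(records, fixture_vessels)
        assert out["small"]["fraction"] == pytest.approx(1 / 3)  # 1 of 3 small
        assert out["large"]["fraction"] == 0.0

    def test_no_vessels_of_class_flagged(self, fixture_vessels):
        small_only = [v for v in fixture_vessels if v.caliber == "small"]
        out = fraction_leaky(self._records(small_only, set()), small_only)
        assert not out["large"]["defined"]
        assert np.isnan(out["large"]["fraction"])

    def test_unknown_record_rejected(self, fixture_vessels):
        from fusquant.microscopy import LeakyVesselRecord

        with pytest.raises(ValueError, match="unknown"):
            fraction_leaky([LeakyVesselRecord(999, True, 0, 0, 0)], fixture_vessels)


class TestTJStrands:
    def test_two_edges_two_strands(self, fixture_scene, fixture_mip, fixture_vessels):
        junction = fixture_mip.channel("junction")
        thr = fixture_scene.tj_amplitude / 2
        strands = trace_tj_strands(junction, fixture_vessels[0], 0.2, threshold=thr)
        assert len(strands) == 2 and not any(s.absent for s in strands)

    def test_vessel_without_junction_flagged_absent(self, fixture_scene, fixture_mip, fixture_vessels):
        junction = fixture_mip.channel("junction")
        thr = fixture_scene.tj_amplitude / 2
        strands = trace_tj_strands(junction, fixture_vessels[4], 0.2, threshold=thr)
        assert len(strands) == 1 and strands[0].absent

    def test_continuous_strand_has_no_gaps(self, fixture_scene, fixture_mip, fixture_vessels):
        junction = fixture_mip.channel("junction")
        thr = fixture_scene.tj_amplitude / 2
        strands = trace_tj_strands(junction, fixture_vessels[2], 0.2, threshold=thr)
        for strand in strands:
            assert measure_gaps(strand, junction, 0.2, threshold=thr) == ()

    def test_programmed_gaps_recovered(self, fixture_scene, fixture_mip, fixture_vessels, fixture_render):
        """Programmed gap lengths recovered within +-0.4 um (2 px)."""
        junction = fixture_mip.channel("junction")
        thr = fixture_scene.tj_amplitude / 2
        truth = fixture_render.strand_truth
        for vessel_id in (0, 1, 3):
            vessel = fixture_vessels[vessel_id]
            expected = sorted(
                g
                for gaps in truth[truth.vessel_id == vessel_id]["gaps_um"]
                for g in json.loads(gaps)
            )
            measured = []
            for strand in trace_tj_strands(junction, vessel, 0.2, threshold=thr):
                measured.extend(measure_gaps(strand, junction, 0.2, threshold=thr))
            measured.sort()
            assert len(measured) == len(expected)
            for m, e in zip(measured, expected):
                assert abs(m - e) <= 0.4

    def test_subresolution_gap_discarded(self):
        """A 0.2 um interruption sits below the 0.4 um detection floor."""
        scene = VesselScene(
            vessels=(VesselSpec((15.0, 50.0), (85.0, 50.0), 8.0),),
            strands=(StrandSpec(0, +1, gaps=((40.0, 0.2),)), StrandSpec(0, -1)),
        )
        render = gen_vessel_image(scene)
        mip = max_intensity_projection(render.stack)
        segs = segment_vessels(mip.channel("vessel"), 0.2, threshold=scene.vessel_amplitude / 2)
        junction = mip.channel("junction")
        thr = scene.tj_amplitude / 2
        for strand in trace_tj_strands(junction, segs[0], 0.2, threshold=thr):
            assert measure_gaps(strand, junction, 0.2, threshold=thr) == ()

    def test_gap_rescaling_idempotence(self, fixture_scene, fixture_mip, fixture_vessels):
        """Scaling image and threshold together leaves measured gaps unchanged."""
        junction = fixture_mip.channel("junction")
        thr = fixture_scene.tj_amplitude / 2
        vessel = fixture_vessels[1]
        gaps_ref, gaps_scaled = [], []
        for strand in trace_tj_strands(junction, vessel, 0.2, threshold=thr):
            gaps_ref.extend(measure_gaps(strand, junction, 0.2, threshold=thr))
        for strand in trace_tj_strands(junction * 3.0, vessel, 0.2, threshold=thr * 3.0):
            gaps_scaled.extend(measure_gaps(strand, junction * 3.0, 0.2, threshold=thr * 3.0))
        assert gaps_ref == gaps_scaled


class TestGapBinning:
    def _strand(self, gaps, absent=False):
        return TJStrand(0, 0, np.empty((0, 2)), np.empty(0), 0.0, tuple(gaps), absent)

    def test_one_of_four_in_each_bin(self):
        strands = [self._strand((1.0, 3.0))] + [self._strand(()) for _ in range(3)]
        summary = bin_gaps_and_fractions(strands)
        assert summary.fraction_small == pytest.approx(0.25)
        assert summary.fraction_big == pytest.approx(0.25)

    def test_all_continuous(self):
        summary = bin_gaps_and_fractions([self._strand(()) for _ in range(4)])
        assert summary.fraction_small == 0.0 and summary.fraction_big == 0.0

    def test_cutoff_is_closed_on_small_side(self):
        summary = bin_gaps_and_fractions([self._strand((GAP_CUTOFF_UM,))])
        assert summary.n_with_small_gap == 1 and summary.n_with_big_gap == 0

    def test_absent_counted_separately(self):
        strands = [self._strand((), absent=True), self._strand((1.0,))]
        summary = bin_gaps_and_fractions(strands)
        assert summary.n_absent == 1 and summary.n_strands == 1
        assert summary.fraction_small == 1.0

    def test_zero_strands_undefined(self):
        summary = bin_gaps_and_fractions([])
        assert not summary.defined and np.isnan(summary.fraction_small)


class TestEndToEndFixture:
    def test_calibers_match_truth_exactly(self, fixture_vessels, fixture_render):
        assert [v.caliber for v in fixture_vessels] == fixture_render.vessel_truth["caliber"].tolist()

    def test_diameters_within_one_pixel(self, fixture_vessels, fixture_render):
        for vessel, truth in zip(fixture_vessels, fixture_render.vessel_truth["diameter_um"]):
            assert abs(vessel.diameter_um - truth) <= 0.2
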