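import numpy as np
import pytest

from subchondral import (
    AnnotationSet,
    AwlSpec,
    BinaryMask,
    LesionSpec,
    OsteophyteSpec,
    PhantomSpec,
    analyze_image,
    generate_phantom,
    segment_bone,
)
from subchondral import morphometry as mm

PX = 0.015


def flat_plate_mask(depth_mm=1.5, shape=(300, 400), px=PX, slope=0.0):
    rows = (np.arange(shape[0]) + 0.5) * px
    cols = (np.arange(shape[1]) + 0.5) * px
    line = depth_mm + slope * cols
    return BinaryMask(rows[:, None] > line[None, :], px)


class TestCementLine:
    def test_flat_plate_recovered(self):
        line = mm.fit_cement_line(flat_plate_mask(1.5))
        assert line.intercept_mm == pytest.approx(1.5, abs=PX / 2)
        assert line.slope == pytest.approx(0.0, abs=0.005)

    def test_tilted_plate_slope_recovered(self):
        line = mm.fit_cement_line(flat_plate_mask(1.5, slope=0.05))
        assert line.slope == pytest.approx(0.05, abs=0.01)
        assert line.intercept_mm == pytest.approx(1.5, abs=2 * PX)

    def test_annotated_endpoints_echoed_exactly(self):
        mask = flat_plate_mask(1.5)
        line = mm.fit_cement_line(mask, endpoints=((0.0, 1.5), (6.0, 1.5)))
        assert line.provenance == "annotated"
        assert line.intercept_mm == 1.5 and line.slope == 0.0

    def test_no_flanking_bone_raises(self):
        mask = BinaryMask(np.zeros((50, 50), dtype=bool), PX)
        with pytest.raises(mm.CementLineError):
            mm.fit_cement_line(mask)

    def test_insufficient_flank_raises(self):
        mask = flat_plate_mask(1.5, shape=(300, 100))
        with pytest.raises(mm.CementLineError, match="flank"):
            mm.fit_cement_line(mask, defect_extent=(0.01, 1.49))


class TestDefectRegion:
    def test_intact_plate_has_no_region(self):
        mask = flat_plate_mask(1.5)
        line = mm.fit_cement_line(mask)
        assert mm.detect_defect_region(mask, line) is None

    def test_cavity_interval_located(self, awl):
        spec = PhantomSpec(
            lesions=(LesionSpec(3.0, 2.0, 1.8, 2.0),),
            defect_extent_mm=(1.5, 4.5),
        )
        img, _ = generate_phantom(spec)
        mask = segment_bone(img)
        line = mm.fit_cement_line(mask, defect_extent=(1.5, 4.5))
        region = mm.detect_defect_region(mask, line)
        # the deviating interval is the 2 mm opening centred at x = 3
        assert region.provenance == "auto-detected"
        assert region.x_left_mm == pytest.approx(2.0, abs=0.1)
        assert region.x_right_mm == pytest.approx(4.0, abs=0.1)

    def test_annotated_extent_echoed(self):
        mask = flat_plate_mask(1.5)
        line = mm.fit_cement_line(mask)
        region = mm.detect_defect_region(mask, line, annotated_extent=(1.0, 3.0))
        assert region.provenance == "annotated"
        assert (region.x_left_mm, region.x_right_mm) == (1.0, 3.0)


class TestBridge:
    def _analyzed(self, spec, awl):
        img, truth = generate_phantom(spec)
        mask = segment_bone(img)
        line = mm.fit_cement_line(mask, defect_extent=spec.defect_extent_mm)
        region = mm.detect_defect_region(mask, line, annotated_extent=spec.defect_extent_mm)
        return mask, line, region, truth

    def test_two_hole_bridge_depth(self, two_hole_spec, awl):
        mask, line, region, truth = self._analyzed(two_hole_spec, awl)
        bridge = mm.detect_bridge(mask, line, region)
        assert bridge.present
        assert bridge.apex_depth_mm == pytest.approx(0.6, abs=2 * PX)

    def test_single_hole_has_no_bridge(self, residual_hole_spec, awl):
        mask, line, region, _ = self._analyzed(residual_hole_spec, awl)
        assert not mm.detect_bridge(mask, line, region).present

    def test_osteophyte_capped_bridge_above_line(self, awl):
        spec = PhantomSpec(
            lesions=(LesionSpec(3.3, 1.8, 1.6, 2.0), LesionSpec(5.6, 1.8, 1.6, 2.0)),
            bridge_vd2_mm=0.0,
            osteophyte=OsteophyteSpec(4.45, 0.3, 0.5),
            defect_extent_mm=(1.5, 7.5),
        )
        mask, line, region, _ = self._analyzed(spec, awl)
        bridge = mm.detect_bridge(mask, line, region)
        assert bridge.present
        assert bridge.apex_depth_mm == pytest.approx(-0.3, abs=2 * PX)


class TestMeasurements:
    def test_vertical_distances(self, two_hole_spec, awl):
        img, _ = generate_phantom(two_hole_spec)
        mask = segment_bone(img)
        line = mm.fit_cement_line(mask, defect_extent=two_hole_spec.defect_extent_mm)
        region = mm.detect_defect_region(mask, line, annotated_extent=two_hole_spec.defect_extent_mm)
        bridge = mm.detect_bridge(mask, line, region)
        vd1, vd2, above = mm.measure_vertical(mask, line, region, bridge)
        assert vd1 == pytest.approx(2.0, abs=2 * PX)
        assert vd2 == pytest.approx(0.6, abs=2 * PX)
        assert not above

    def test_shallow_cavity_hd2_zero_with_warning(self, awl):
        # cavity reaching only 40% of the penetration depth
        spec = PhantomSpec(
            lesions=(LesionSpec(4.5, 2.0, 2.0, 0.8, "trapezoid"),),
            defect_extent_mm=(2.5, 6.5),
        )
        img, _ = generate_phantom(spec)
        mask = segment_bone(img)
        line = mm.fit_cement_line(mask, defect_extent=spec.defect_extent_mm)
        region = mm.detect_defect_region(mask, line, annotated_extent=spec.defect_extent_mm)
        comp = mm.cavity_component(mask, line, region)
        hd1, hd2, warn = mm.measure_horizontal(mask, line, comp, awl)
        assert hd1 == pytest.approx(2.0, abs=2 * PX)
        assert hd2 == 0.0
        assert warn

    def test_aligned_rectangle_area_is_exact(self):
        """A grid-aligned 2 mm x 1 mm void yields its analytic area to
        within four pixel areas (10 um grid divides the sides exactly)."""
        px = 0.01
        mask_arr = np.ones((400, 500), dtype=bool)
        mask_arr[:150, :] = False  # space above the plate (line at 1.5 mm)
        mask_arr[150 : 150 + 100, 100 : 100 + 200] = False  # 1 x 2 mm void
        mask = BinaryMask(mask_arr, px)
        line = mm.CementLineModel(1.5, 0.0, 0.0, 5.0)
        region = mm.DefectRegion(0.9, 3.2, "annotated", 1.0, np.array([2.0]), np.array([1.0]))
        comp = mm.cavity_component(mask, line, region)
        area = mm.measure_area(mask, line, comp)
        assert area == pytest.approx(2.0, abs=4 * px * px)

    def test_osteophyte_measurement(self, awl):
        spec = PhantomSpec(
            lesions=(LesionSpec(4.8, 2.0, 1.8, 2.0),),
            osteophyte=OsteophyteSpec(3.45, 0.3, 0.7),
            defect_extent_mm=(2.5, 6.5),
        )
        img, truth = generate_phantom(spec)
        mask = segment_bone(img)
        line = mm.fit_cement_line(mask, defect_extent=spec.defect_extent_mm)
        region = mm.detect_defect_region(mask, line, annotated_extent=spec.defect_extent_mm)
        osteo = mm.measure_osteophyte(mask, line, region)
        assert osteo is not None
        assert osteo.h0_mm == pytest.approx(0.3, abs=2 * PX)
        assert osteo.width_mm == pytest.approx(truth.osteophyte.width_mm, abs=2 * PX)
        assert osteo.area_mm2 > 0
        assert osteo.location == "peripheral"

    def test_no_overgrowth_returns_none(self, residual_hole_spec):
        img, _ = generate_phantom(residual_hole_spec)
        mask = segment_bone(img)
        line = mm.fit_cement_line(mask, defect_extent=residual_hole_spec.defect_extent_mm)
        region = mm.detect_defect_region(mask, line, annotated_extent=residual_hole_spec.defect_extent_mm)
        assert mm.measure_osteophyte(mask, line, region) is None


class TestInvariances:
    @pytest.mark.parametrize("seed", [3, 4, 5])
    def test_resolution_invariance(self, seed, awl):
        """Measurements at 15 and 30 um pixels agree within two coarse
        pixels."""
        from dataclasses import replace

        from subchondral.phantom import sample_random_spec

        spec = sample_random_spec(seed=seed)
        coarse = replace(spec, pixel_size_mm=0.030)
        results = []
        for s in (spec, coarse):
            img, _ = generate_phantom(s)
            res = analyze_image(img, s.awl, AnnotationSet(defect_extent_mm=s.defect_extent_mm))
            results.append(res)
        fine, coarse_res = results
        assert fine.hole_count == coarse_res.hole_count
        for (mf, cf), (mc, cc) in zip(fine.lesions, coarse_res.lesions):
            assert cf == cc
            assert mf.hd1_mm == pytest.approx(mc.hd1_mm, abs=2 * 0.030)
            assert mf.vd1_mm == pytest.approx(mc.vd1_mm, abs=2 * 0.030)

    @pytest.mark.parametrize("seed", [7, 8])
    def test_mirror_equivariance(self, seed):
        """Horizontally mirroring the image leaves scalar measurements
        unchanged and swaps the lesion order."""
        from subchondral.phantom import sample_random_spec
        from subchondral.image_io import CalibratedImage

        spec = sample_random_spec(seed=seed)
        img, _ = generate_phantom(spec)
        res = analyze_image(img, spec.awl, AnnotationSet(defect_extent_mm=spec.defect_extent_mm))

        mirrored = CalibratedImage(img.pixels[:, ::-1].copy(), img.pixel_size_mm)
        w = img.width_mm
        ext = (w - spec.defect_extent_mm[1], w - spec.defect_extent_mm[0])
        res_m = analyze_image(mirrored, spec.awl, AnnotationSet(defect_extent_mm=ext))

        assert res.hole_count == res_m.hole_count
        pairs = list(zip(res.lesions, reversed(res_m.lesions)))
        for (m, c), (mm_, cm) in pairs:
            assert c == cm
            assert m.hd1_mm == pytest.approx(mm_.hd1_mm, abs=2 * PX)
            assert m.vd1_mm == pytest.approx(mm_.vd1_mm, abs=2 * PX)

    def test_hd1_monotone_in_spec(self, awl):
        """Enlarging the spec opening strictly increases measured Hd1."""
        measured = []
        for hd1 in (1.2, 1.8, 2.4, 3.0):
            spec = PhantomSpec(
                lesions=(LesionSpec(4.5, hd1, hd1 - 0.2, 2.0),),
                defect_extent_mm=(2.0, 7.0),
            )
            img, _ = generate_phantom(spec)
            res = analyze_image(img, awl, AnnotationSet(defect_extent_mm=spec.defect_extent_mm))
            measured.append(res.lesions[0][0].hd1_mm)
        assert all(b > a for a, b in zip(measured, measured[1:]))
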