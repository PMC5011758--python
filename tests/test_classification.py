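import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from subchondral import (
    AnnotationSet,
    AwlSpec,
    LesionClass,
    LesionSpec,
    PhantomSpec,
    ThresholdConfig,
    analyze_defect,
    check_reconstitution,
    classify_lesion,
    classify_osteophyte,
    count_holes,
    generate_phantom,
    threshold_sweep,
)
from subchondral.morphometry import BridgeMeasure, DefectRegion, LesionMeasurement


class TestCountHoles:
    @pytest.mark.parametrize(
        "vd1,vd2,expected",
        [
            (2.0, 1.2, 1),  # remnant above half depth: erosion relief
            (2.0, 0.8, 2),  # persistent bridge below half depth
            (2.0, 1.0, 1),  # boundary: equality falls to the single hole
            (2.0, None, 1),  # no bridge at all
        ],
    )
    def test_relative_bridge_height_rule(self, vd1, vd2, expected):
        assert count_holes(vd1, vd2) == expected

    def test_bridge_below_base_is_impossible(self):
        with pytest.raises(ValueError):
            count_holes(1.0, 1.5)

    def test_requires_positive_depth(self):
        with pytest.raises(ValueError):
            count_holes(0.0, None)


class TestClassifyLesion:
    @pytest.mark.parametrize(
        "hd1,hd2,expected",
        [
            (2.0, 3.0, LesionClass.RESIDUAL_HOLE),
            (2.5, 3.0, LesionClass.PERI_HOLE_RESORPTION),
            (1.0, 4.0, LesionClass.SUBCHONDRAL_CYST),  # cyst regardless of Hd1
            (2.4, 3.0, LesionClass.RESIDUAL_HOLE),  # boundary: strict > required
            (5.0, 3.7, LesionClass.SUBCHONDRAL_CYST),  # cyst precedence over resorption
            (0.0, 0.0, LesionClass.RESIDUAL_HOLE),
        ],
    )
    def test_awl_diameter_thresholds(self, hd1, hd2, expected, awl):
        assert classify_lesion(hd1, hd2, awl) is expected

    def test_negative_inputs_rejected(self, awl):
        with pytest.raises(ValueError):
            classify_lesion(-0.1, 1.0, awl)

    @settings(deadline=None, max_examples=100)
    @given(
        hd1=st.floats(0, 10, allow_nan=False),
        hd2=st.floats(0, 10, allow_nan=False),
        scale=st.floats(0.01, 100, allow_nan=False),
    )
    def test_scale_invariance(self, hd1, hd2, scale):
        """Multiplying all lengths (including the awl diameter) by any
        positive factor leaves the class unchanged."""
        a1 = AwlSpec(1.2, 2.0)
        a2 = AwlSpec(1.2 * scale, 2.0 * scale)
        assert classify_lesion(hd1, hd2, a1) is classify_lesion(hd1 * scale, hd2 * scale, a2)

    @settings(deadline=None, max_examples=100)
    @given(hd1=st.floats(0, 10, allow_nan=False), hd2=st.floats(0, 10, allow_nan=False))
    def test_exactly_one_class(self, hd1, hd2):
        cls = classify_lesion(hd1, hd2, AwlSpec())
        assert cls in (
            LesionClass.RESIDUAL_HOLE,
            LesionClass.PERI_HOLE_RESORPTION,
            LesionClass.SUBCHONDRAL_CYST,
        )


class TestOsteophyteCall:
    def test_apex_above_line(self):
        assert classify_osteophyte(BridgeMeasure(True, -0.3, 4.0))

    def test_apex_below_line(self):
        assert not classify_osteophyte(BridgeMeasure(True, 0.8, 4.0))

    def test_apex_exactly_on_line_requires_strict_protrusion(self):
        assert not classify_osteophyte(BridgeMeasure(True, 0.0, 4.0))


class TestReconstitution:
    def _region(self, max_dev):
        return DefectRegion(1.0, 2.0, "annotated", max_dev, np.array([1.5]), np.array([max_dev]))

    def test_intact_stack_is_reconstituted(self):
        assert check_reconstitution([None, None, None])

    def test_any_cavity_breaks_reconstitution(self):
        assert not check_reconstitution([None, self._region(2.0)])

    def test_deviation_exactly_at_tolerance_still_reconstituted(self):
        assert check_reconstitution([self._region(0.1)], ThresholdConfig())


class TestAnalyzeDefect:
    def test_intact_stack_reports_complete_reconstitution(self, intact_spec, awl):
        imgs = [generate_phantom(intact_spec)[0] for _ in range(3)]
        report = analyze_defect(imgs, awl, AnnotationSet(defect_extent_mm=intact_spec.defect_extent_mm))
        assert report.reconstituted
        assert report.class_counts["complete_reconstitution"] == 1
        assert not report.holes

    def test_two_hole_worked_example(self, two_hole_spec, awl):
        """Wide + narrow hole pair split by a persistent bridge: resorption
        beside a residual hole."""
        img, _ = generate_phantom(two_hole_spec)
        report = analyze_defect([img], awl, AnnotationSet(defect_extent_mm=two_hole_spec.defect_extent_mm))
        assert not report.reconstituted
        assert report.slices[0].hole_count == 2
        assert [h.worst_class for h in report.holes] == [
            LesionClass.PERI_HOLE_RESORPTION,
            LesionClass.RESIDUAL_HOLE,
        ]

    def test_auto_detection_without_annotations(self, residual_hole_spec, awl):
        img, truth = generate_phantom(residual_hole_spec)
        report = analyze_defect([img], awl)
        assert report.slices[0].region.provenance == "auto-detected"
        assert [h.worst_class.value for h in report.holes] == ["residual_hole"]

    def test_hole_tracking_worst_case_across_slices(self, awl):
        # the same hole seen on two slices, residual on one and widened to
        # resorption on the other: the track reports the worst case
        base = dict(defect_extent_mm=(2.0, 7.0))
        s1 = PhantomSpec(lesions=(LesionSpec(4.5, 2.0, 1.8, 2.0),), **base)
        s2 = PhantomSpec(lesions=(LesionSpec(4.6, 2.7, 2.4, 2.0),), **base)
        imgs = []
        for i, s in enumerate((s1, s2)):
            img, _ = generate_phantom(s)
            from subchondral.image_io import CalibratedImage

            imgs.append(CalibratedImage(img.pixels, img.pixel_size_mm, slice_id=i))
        report = analyze_defect(imgs, awl, AnnotationSet(defect_extent_mm=(2.0, 7.0)))
        assert len(report.holes) == 1
        assert report.holes[0].n_slices == 2
        assert report.holes[0].worst_class is LesionClass.PERI_HOLE_RESORPTION


class TestThresholdSweep:
    def _meas(self, hd1, hd2):
        return LesionMeasurement(0, 2.0, None, hd1, hd2, 2.0, 1.0, 4.0)

    def test_multiplier_shift_reclassifies(self, awl):
        # Hd1 = 2.5: resorption at multiplier 2 (2.5 > 2.4), none at 3
        lesions = [self._meas(2.5, 3.0)] * 4
        table = threshold_sweep(lesions, awl, [2.0, 3.0], [3.0])
        at2 = table[table.hd1_multiplier == 2.0].iloc[0]
        at3 = table[table.hd1_multiplier == 3.0].iloc[0]
        assert at2["peri_hole_resorption"] == 4
        assert at3["peri_hole_resorption"] == 0

    def test_resorption_count_monotone_in_hd1_multiplier(self, awl):
        rng = np.random.default_rng(0)
        lesions = [self._meas(rng.uniform(0.5, 5), rng.uniform(0.5, 6)) for _ in range(60)]
        table = threshold_sweep(lesions, awl, [1.5, 2.0, 3.0], [3.0])
        counts = table.sort_values("hd1_multiplier")["peri_hole_resorption"].tolist()
        assert counts == sorted(counts, reverse=True)

    def test_cyst_count_monotone_in_hd2_multiplier(self, awl):
        rng = np.random.default_rng(1)
        lesions = [self._meas(rng.uniform(0.5, 5), rng.uniform(0.5, 6)) for _ in range(60)]
        table = threshold_sweep(lesions, awl, [2.0], [2.0, 3.0, 4.0])
        counts = table.sort_values("hd2_multiplier")["subchondral_cyst"].tolist()
        assert counts == sorted(counts, reverse=True)

    def test_empty_measurements_rejected(self, awl):
        with pytest.raises(ValueError):
            threshold_sweep([], awl)
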