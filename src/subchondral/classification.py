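"""The two-part decision algorithm for subchondral bone alterations.

Part one scans all consecutive cross sections of a treated defect: if the
subchondral bone contour is restored to the projected cement line everywhere
(within a small tolerance), the defect is *complete reconstitution*.

Part two runs per section when the bone is not restored:

1. Bridge check — a bone bridge protruding above the cement line is an
   *intra-lesional osteophyte* (reported alongside the cavity classes).
2. Hole count — the relative bridge height decides one vs. two holes:
   a persistent bridge (``Vd2 < 0.5 * Vd1``) separates two holes requiring
   separate analysis; a higher remnant (``Vd2 >= 0.5 * Vd1``) is erosion
   relief around a single hole.
3. Per-lesion discrimination against the awl diameter (the reference
   standard):

   * *subchondral bone cyst* when ``Hd2 > 3 x awl diameter`` — evaluated
     first, because the cyst rule holds irrespective of Hd1;
   * else *peri-hole bone resorption* when ``Hd1 > 2 x awl diameter``;
   * else *residual microfracture hole*.

Boundary handling: pathology requires a strict inequality; equality falls to
the milder category.  The three multipliers (0.5, 2, 3) are explicit in
:class:`ThresholdConfig` and sweepable (:func:`threshold_sweep`).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from enum import Enum
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from . import morphometry as mm
from .image_io import AnnotationSet, BinaryMask, CalibratedImage, GrayThreshold, segment_bone
from .phantom import AwlSpec

logger = logging.getLogger(__name__)

__all__ = [
    "ThresholdConfig",
    "LesionClass",
    "SliceAnalysis",
    "DefectReport",
    "check_reconstitution",
    "classify_osteophyte",
    "count_holes",
    "classify_lesion",
    "analyze_image",
    "analyze_defect",
    "threshold_sweep",
    "SEVERITY_ORDER",
]


@dataclass(frozen=True)
class ThresholdConfig:
    """The decision constants of the algorithm, made explicit.

    bridge_fraction
        fraction of Vd1 below which a bridge counts as persistent (two
        holes); default 0.5.
    hd1_multiplier
        awl-diameter multiple separating residual hole from peri-hole
        resorption; default 2.
    hd2_multiplier
        awl-diameter multiple defining a cyst at half penetration depth;
        default 3.
    reconstitution_tolerance_mm
        maximal surface deviation from the cement line still counting as
        completely reconstituted; default 0.1 mm.
    """

    bridge_fraction: float = 0.5
    hd1_multiplier: float = 2.0
    hd2_multiplier: float = 3.0
    reconstitution_tolerance_mm: float = 0.1

    def __post_init__(self) -> None:
        for name in ("bridge_fraction", "hd1_multiplier", "hd2_multiplier", "reconstitution_tolerance_mm"):
            if not (getattr(self, name) > 0):
                raise ValueError(f"{name} must be > 0")


class LesionClass(str, Enum):
    COMPLETE_RECONSTITUTION = "complete_reconstitution"
    INTRA_LESIONAL_OSTEOPHYTE = "intra_lesional_osteophyte"
    RESIDUAL_HOLE = "residual_hole"
    PERI_HOLE_RESORPTION = "peri_hole_resorption"
    SUBCHONDRAL_CYST = "subchondral_cyst"


#: worst-case ordering for aggregating a tracked hole across slices
SEVERITY_ORDER: Dict[str, int] = {
    LesionClass.RESIDUAL_HOLE.value: 0,
    LesionClass.PERI_HOLE_RESORPTION.value: 1,
    LesionClass.SUBCHONDRAL_CYST.value: 2,
}


def check_reconstitution(
    regions: Sequence[Optional[mm.DefectRegion]],
    cfg: ThresholdConfig = ThresholdConfig(),
) -> bool:
    """Part one: complete reconstitution iff on every slice no surface
    deviation from the cement line exceeds the tolerance (deviation exactly
    at the tolerance still counts as reconstituted)."""
    for region in regions:
        if region is not None and region.max_deviation_mm > cfg.reconstitution_tolerance_mm:
            return False
    return True


def classify_osteophyte(
    bridge: Optional[mm.BridgeMeasure] = None,
    osteophytes: Sequence[mm.OsteophyteMeasurement] = (),
) -> bool:
    """True iff bone within the defect rises strictly above the cement line
    (bridge apex above the line, or any measured overgrowth)."""
    if bridge is not None and bridge.present and bridge.apex_depth_mm is not None:
        if bridge.apex_depth_mm < 0:
            return True
    return len(osteophytes) > 0


def count_holes(vd1_mm: float, vd2_mm: Optional[float], cfg: ThresholdConfig = ThresholdConfig()) -> int:
    """One or two holes from the relative bridge height.

    No bridge -> 1.  A persistent bridge (``vd2 < bridge_fraction * vd1``,
    strict) -> 2.  A higher remnant (including equality) is erosion relief of
    a single hole -> 1.
    """
    if not (vd1_mm > 0):
        raise ValueError("vd1 must be > 0")
    if vd2_mm is None:
        return 1
    if vd2_mm > vd1_mm:
        raise ValueError("vd2 > vd1: a bridge top below the defect base is impossible")
    if vd2_mm < cfg.bridge_fraction * vd1_mm:
        return 2
    if vd2_mm == cfg.bridge_fraction * vd1_mm:
        logger.info("vd2 exactly at %.3g * vd1: counted as a single hole", cfg.bridge_fraction)
    return 1


def classify_lesion(
    hd1_mm: float,
    hd2_mm: float,
    awl: AwlSpec,
    cfg: ThresholdConfig = ThresholdConfig(),
) -> LesionClass:
    """Discriminate residual hole / peri-hole resorption / cyst.

    The cyst rule is evaluated first (it holds irrespective of Hd1, and this
    precedence also resolves threshold sweeps where the multipliers cross).
    Equalities fall to the milder class.
    """
    if hd1_mm < 0 or hd2_mm < 0:
        raise ValueError("horizontal diameters must be >= 0")
    d = awl.diameter_mm
    if hd2_mm > cfg.hd2_multiplier * d:
        return LesionClass.SUBCHONDRAL_CYST
    if hd1_mm > cfg.hd1_multiplier * d:
        return LesionClass.PERI_HOLE_RESORPTION
    if hd1_mm == cfg.hd1_multiplier * d or hd2_mm == cfg.hd2_multiplier * d:
        logger.info("diameter exactly at threshold: assigned the milder class")
    return LesionClass.RESIDUAL_HOLE


# ---------------------------------------------------------------------------
# whole-image / whole-defect analysis
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SliceAnalysis:
    """Everything measured and decided on one cross section."""

    slice_id: Optional[int]
    reconstituted: bool
    line: mm.CementLineModel
    region: Optional[mm.DefectRegion]
    bridge: Optional[mm.BridgeMeasure]
    hole_count: int
    lesions: Tuple[Tuple[mm.LesionMeasurement, LesionClass], ...]
    osteophytes: Tuple[mm.OsteophyteMeasurement, ...]
    osteophyte_present: bool


@dataclass(frozen=True)
class HoleTrack:
    """One microfracture hole followed across consecutive slices."""

    track_id: int
    center_x_mm: float
    worst_class: LesionClass
    n_slices: int
    max_hd1_mm: float
    max_hd2_mm: float
    max_depth_mm: float
    max_area_mm2: float


@dataclass(frozen=True)
class DefectReport:
    """Defect-level aggregate over a stack of consecutive sections."""

    reconstituted: bool
    slices: Tuple[SliceAnalysis, ...]
    holes: Tuple[HoleTrack, ...]
    class_counts: Dict[str, int]
    osteophyte_present: bool
    osteophyte_max_h0_mm: Optional[float]

    def to_dict(self) -> dict:
        return {
            "schema_version": 1,
            "reconstituted": self.reconstituted,
            "osteophyte_present": self.osteophyte_present,
            "osteophyte_max_h0_mm": self.osteophyte_max_h0_mm,
            "class_counts": dict(self.class_counts),
            "holes": [
                {
                    "track_id": h.track_id,
                    "center_x_mm": h.center_x_mm,
                    "worst_class": h.worst_class.value,
                    "n_slices": h.n_slices,
                    "max_hd1_mm": h.max_hd1_mm,
                    "max_hd2_mm": h.max_hd2_mm,
                    "max_depth_mm": h.max_depth_mm,
                    "max_area_mm2": h.max_area_mm2,
                }
                for h in self.holes
            ],
            "slices": [
                {
                    "slice_id": s.slice_id,
                    "reconstituted": s.reconstituted,
                    "hole_count": s.hole_count,
                    "lesions": [
                        {
                            "lesion_id": m.lesion_id,
                            "class": c.value,
                            "vd1_mm": m.vd1_mm,
                            "vd2_mm": m.vd2_mm,
                            "hd1_mm": m.hd1_mm,
                            "hd2_mm": m.hd2_mm,
                            "depth_mm": m.depth_mm,
                            "area_mm2": m.area_mm2,
                            "center_x_mm": m.center_x_mm,
                        }
                        for m, c in s.lesions
                    ],
                    "osteophytes": [
                        {
                            "h0_mm": o.h0_mm,
                            "width_mm": o.width_mm,
                            "area_mm2": o.area_mm2,
                            "location": o.location,
                        }
                        for o in s.osteophytes
                    ],
                }
                for s in self.slices
            ],
        }


def analyze_image(
    image: CalibratedImage,
    awl: AwlSpec,
    annotations: Optional[AnnotationSet] = None,
    cfg: ThresholdConfig = ThresholdConfig(),
    thr: GrayThreshold = GrayThreshold(),
    despeckle_px: int = 5,
) -> SliceAnalysis:
    """Run segmentation, cement line, defect detection, bridge/osteophyte
    analysis, hole counting, per-lesion measurement and classification on a
    single cross section."""
    mask = mm.despeckle(segment_bone(image, thr), despeckle_px)
    extent = annotations.defect_extent_mm if annotations else None
    endpoints = annotations.cement_line if annotations else None

    if endpoints is not None or extent is not None:
        line = mm.fit_cement_line(mask, defect_extent=extent, endpoints=endpoints)
        region = mm.detect_defect_region(mask, line, cfg.reconstitution_tolerance_mm, annotated_extent=extent)
    else:
        # no annotations: fit on everything (L1-robust), locate the defect,
        # then refit excluding it
        line = mm.fit_cement_line(mask)
        region = mm.detect_defect_region(mask, line, cfg.reconstitution_tolerance_mm)
        if region is not None:
            try:
                line = mm.fit_cement_line(mask, defect_extent=(region.x_left_mm, region.x_right_mm))
            except mm.CementLineError:
                pass  # defect fills the field of view; keep the robust fit
            region = mm.detect_defect_region(mask, line, cfg.reconstitution_tolerance_mm)

    if region is None or region.max_deviation_mm <= cfg.reconstitution_tolerance_mm:
        return SliceAnalysis(image.slice_id, True, line, region, None, 0, (), (), False)

    component = mm.cavity_component(mask, line, region)
    bridge = mm.detect_bridge(mask, line, region, cfg.reconstitution_tolerance_mm)
    vd1, vd2, above = mm.measure_vertical(mask, line, region, bridge, component=component)

    if vd1 <= 0:
        # overgrowth only: no cavity below the line
        osteos = tuple(mm.measure_osteophytes(mask, line, region))
        return SliceAnalysis(
            image.slice_id, False, line, region, bridge, 0, (), osteos, classify_osteophyte(bridge, osteos)
        )

    n_holes = count_holes(vd1, vd2, cfg) if bridge.present else 1
    if n_holes == 2:
        bounds_list = [(None, bridge.apex_x_mm), (bridge.apex_x_mm, None)]
    else:
        bounds_list = [(None, None)]

    depth_grid = None
    lesions: List[Tuple[mm.LesionMeasurement, LesionClass]] = []
    for idx, bounds in enumerate(bounds_list):
        hd1, hd2, warn = mm.measure_horizontal(mask, line, component, awl, bounds)
        area = mm.measure_area(mask, line, component, bounds)
        if depth_grid is None:
            depth_grid = mm._depth_grid(mask, line)
        x = mm._column_centers(mask)
        sel = component & (depth_grid > 0)
        lo, hi = bounds
        if lo is not None:
            sel &= (x >= lo)[None, :]
        if hi is not None:
            sel &= (x < hi)[None, :]
        depth_i = float(depth_grid[sel].max()) if sel.any() else 0.0
        center = float(x[sel.any(axis=0)].mean()) if sel.any() else float("nan")
        meas = mm.LesionMeasurement(
            idx, depth_i, vd2, hd1, hd2, depth_i, area, center, bridge_above_line=above, warnings=warn
        )
        lesions.append((meas, classify_lesion(hd1, hd2, awl, cfg)))

    centers = [m.center_x_mm for m, _ in lesions] if n_holes == 2 else []
    osteos = tuple(mm.measure_osteophytes(mask, line, region, lesion_centers=centers))
    return SliceAnalysis(
        image.slice_id,
        False,
        line,
        region,
        bridge,
        n_holes,
        tuple(lesions),
        osteos,
        classify_osteophyte(bridge, osteos),
    )


def analyze_defect(
    images: Sequence[CalibratedImage],
    awl: AwlSpec,
    annotations: Optional[AnnotationSet] = None,
    cfg: ThresholdConfig = ThresholdConfig(),
    thr: GrayThreshold = GrayThreshold(),
) -> DefectReport:
    """Analyze all consecutive sections of one defect and aggregate.

    Holes are tracked across slices by horizontal-centre proximity (nearest
    track within one awl diameter); each tracked hole is reported with its
    worst-case class (cyst > resorption > residual hole).
    """
    if not images:
        raise ValueError("no images supplied")
    slices = []
    for im in images:
        try:
            slices.append(analyze_image(im, awl, annotations, cfg, thr))
        except (mm.CementLineError, ValueError) as exc:
            raise type(exc)(f"slice {im.slice_id}: {exc}") from exc

    reconstituted = check_reconstitution([s.region for s in slices], cfg)

    tracks: List[dict] = []
    for s in slices:
        for meas, cls in s.lesions:
            best = None
            for t in tracks:
                if abs(t["center"] - meas.center_x_mm) < awl.diameter_mm:
                    if best is None or abs(t["center"] - meas.center_x_mm) < abs(best["center"] - meas.center_x_mm):
                        best = t
            if best is None:
                best = {
                    "id": len(tracks),
                    "center": meas.center_x_mm,
                    "cls": cls,
                    "n": 0,
                    "hd1": 0.0,
                    "hd2": 0.0,
                    "depth": 0.0,
                    "area": 0.0,
                }
                tracks.append(best)
            best["n"] += 1
            best["center"] = meas.center_x_mm  # follow the hole slice to slice
            if SEVERITY_ORDER[cls.value] > SEVERITY_ORDER[best["cls"].value]:
                best["cls"] = cls
            best["hd1"] = max(best["hd1"], meas.hd1_mm)
            best["hd2"] = max(best["hd2"], meas.hd2_mm)
            best["depth"] = max(best["depth"], meas.depth_mm)
            best["area"] = max(best["area"], meas.area_mm2)

    holes = tuple(
        HoleTrack(t["id"], t["center"], t["cls"], t["n"], t["hd1"], t["hd2"], t["depth"], t["area"])
        for t in tracks
    )
    counts: Dict[str, int] = {c.value: 0 for c in LesionClass}
    if reconstituted:
        counts[LesionClass.COMPLETE_RECONSTITUTION.value] = 1
    for h in holes:
        counts[h.worst_class.value] += 1
    osteo_present = any(s.osteophyte_present for s in slices)
    if osteo_present:
        counts[LesionClass.INTRA_LESIONAL_OSTEOPHYTE.value] = 1
    h0s = [o.h0_mm for s in slices for o in s.osteophytes]
    return DefectReport(
        reconstituted,
        tuple(slices),
        holes,
        counts,
        osteo_present,
        max(h0s) if h0s else None,
    )


def threshold_sweep(
    measurements: Sequence[mm.LesionMeasurement],
    awl: AwlSpec,
    hd1_multipliers: Sequence[float] = (1.5, 2.0, 3.0),
    hd2_multipliers: Sequence[float] = (2.0, 3.0, 4.0),
    cfg: ThresholdConfig = ThresholdConfig(),
) -> pd.DataFrame:
    """Re-classify stored measurements for every multiplier pair.

    Returns a table with one row per (hd1_multiplier, hd2_multiplier) pair
    and the class counts.  By construction the count of a pathology is
    non-increasing in its own multiplier.
    """
    if not measurements:
        raise ValueError("no measurements supplied")
    rows = []
    for m1 in hd1_multipliers:
        for m2 in hd2_multipliers:
            sweep_cfg = ThresholdConfig(
                bridge_fraction=cfg.bridge_fraction,
                hd1_multiplier=m1,
                hd2_multiplier=m2,
                reconstitution_tolerance_mm=cfg.reconstitution_tolerance_mm,
            )
            counts = {c.value: 0 for c in (LesionClass.RESIDUAL_HOLE, LesionClass.PERI_HOLE_RESORPTION, LesionClass.SUBCHONDRAL_CYST)}
            for meas in measurements:
                cls = classify_lesion(meas.hd1_mm, meas.hd2_mm, awl, sweep_cfg)
                counts[cls.value] += 1
            rows.append({"hd1_multiplier": m1, "hd2_multiplier": m2, **counts})
    return pd.DataFrame(rows)
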