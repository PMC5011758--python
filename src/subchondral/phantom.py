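"""Synthetic osteochondral cross-section phantoms with analytic ground truth.

A phantom emulates a binarizable micro-CT cross section through a
microfractured defect: a subchondral bone plate whose original surface is the
(possibly tilted) projected cement line, one or two awl cavities with
controllable opening width (Hd1), mid-depth width (Hd2) and depth, an
inter-hole bone bridge of controllable height (Vd2 below the line), optional
osteophytic overgrowth above the cement line, plus optional trabecular
texture and Gaussian gray noise.

The ground truth is computed *analytically* from the geometric specification
(never from the rendered raster), under the same operational conventions the
measurement stack uses:

* All vertical distances are measured from the projected cement line,
  positive downward.
* When a bridge with top below the line separates two holes, the void above
  the bridge is split at the bridge apex, and each hole's horizontal
  diameters include its share of that eroded notch.  When the bridge reaches
  the line (the intra-lesional-osteophyte configuration) each hole keeps its
  own opening.
* Hd2 is read at exactly half the awl penetration depth below the line.

Cavity wall profiles are piecewise linear in depth:

``trapezoid``
    width interpolates linearly from Hd1 at the opening through Hd2 at half
    the penetration depth down to the base.
``bulb``
    a vertical neck of width Hd1 (upper 15 % of the penetration depth), a
    linear flare to Hd2, an equatorial plateau of width Hd2 spanning
    40-60 % of the penetration depth (so Hd2 is realized exactly at the
    measurement level), then a linear taper to half the neck width at the
    base.  This renders narrow-neck cystic cavities.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from typing import List, Optional, Sequence, Tuple

import numpy as np
from scipy import ndimage as ndi

from .image_io import CalibratedImage

__all__ = [
    "AwlSpec",
    "LesionSpec",
    "OsteophyteSpec",
    "PhantomSpec",
    "LesionTruth",
    "OsteophyteTruth",
    "GroundTruth",
    "generate_phantom",
    "sample_random_spec",
    "DEFAULT_RANGES",
]

# Nominal gray levels of mineralized bone and marrow/background, chosen to
# straddle the default 89-255 bone window with realistic contrast.
BONE_GRAY = 180.0
BACKGROUND_GRAY = 40.0

# Trabecular pores are carved only deeper than this below the cement line so
# the plate stays solid, and never closer than the rim margin to a cavity
# (mimicking the sclerotic rim around lesions and keeping the cavity's
# connected component well defined).
TRABECULAR_MIN_DEPTH_MM = 0.5
TRABECULAR_RIM_MARGIN_MM = 0.15


@dataclass(frozen=True)
class AwlSpec:
    """Microfracture awl: cylindrical body diameter and penetration depth.

    The 1.2 mm body diameter is the reference standard of the decision rules.
    The penetration depth is set by the instrument's stop; 2.0 mm is the
    package convention for phantoms (the stop standardizes it but its value
    is instrument specific).
    """

    diameter_mm: float = 1.2
    penetration_depth_mm: float = 2.0

    def __post_init__(self) -> None:
        if not (self.diameter_mm > 0 and self.penetration_depth_mm > 0):
            raise ValueError("awl diameter and penetration depth must be > 0")


@dataclass(frozen=True)
class LesionSpec:
    """One cavity: horizontal centre, opening width Hd1, width Hd2 at half
    the awl penetration depth, vertical extent below the cement line, and the
    wall profile tag (``trapezoid`` or ``bulb``)."""

    center_x_mm: float
    hd1_mm: float
    hd2_mm: float
    depth_mm: float
    profile: str = "trapezoid"

    def __post_init__(self) -> None:
        if not (self.hd1_mm > 0 and self.hd2_mm > 0 and self.depth_mm > 0):
            raise ValueError("lesion lengths must be > 0")
        if self.profile not in ("trapezoid", "bulb"):
            raise ValueError("profile must be 'trapezoid' or 'bulb'")

    def width_at(self, depth_mm, awl: AwlSpec):
        """Cavity width (mm) at a given depth below the cement line.

        Vectorized over ``depth_mm``; zero outside [0, depth_mm].
        """
        p = awl.penetration_depth_mm
        d = np.asarray(depth_mm, dtype=float)
        hd1, hd2, dep = self.hd1_mm, self.hd2_mm, self.depth_mm
        if self.profile == "trapezoid":
            w = hd1 + (hd2 - hd1) * d / (0.5 * p)
        else:  # bulb
            neck, flare_lo, flare_hi = 0.15 * p, 0.4 * p, 0.6 * p
            base_w = 0.5 * hd1
            w = np.empty_like(d)
            w[...] = hd1
            seg = (d > neck) & (d <= flare_lo)
            w = np.where(seg, hd1 + (hd2 - hd1) * (d - neck) / (flare_lo - neck), w)
            w = np.where((d > flare_lo) & (d <= flare_hi), hd2, w)
            if dep > flare_hi:
                seg = d > flare_hi
                w = np.where(seg, hd2 + (base_w - hd2) * (d - flare_hi) / (dep - flare_hi), w)
        w = np.where((d < 0) | (d > dep), 0.0, np.maximum(w, 0.0))
        return float(w) if w.ndim == 0 else w

    def max_width_mm(self, awl: AwlSpec) -> float:
        """Maximal cavity width over the whole profile (piecewise linear, so
        the extremum is at a breakpoint)."""
        p = awl.penetration_depth_mm
        pts = [0.0, 0.15 * p, 0.4 * p, 0.5 * p, 0.6 * p, self.depth_mm]
        pts = [d for d in pts if 0 <= d <= self.depth_mm]
        return float(max(self.width_at(d, awl) for d in pts))

    def base_width_mm(self, awl: AwlSpec) -> float:
        return float(self.width_at(self.depth_mm, awl))


@dataclass(frozen=True)
class OsteophyteSpec:
    """Circular-arc bone cap protruding ``h0_mm`` above the cement line with
    chord width ``width_mm`` centred at ``center_x_mm``."""

    center_x_mm: float
    h0_mm: float
    width_mm: float

    def __post_init__(self) -> None:
        if not (self.h0_mm > 0 and self.width_mm > 0):
            raise ValueError("osteophyte height and width must be > 0")

    @property
    def radius_mm(self) -> float:
        w, h = self.width_mm, self.h0_mm
        return (w * w / 4.0 + h * h) / (2.0 * h)

    @property
    def true_width_mm(self) -> float:
        # If the cap is more than a half disc the widest point lies above the
        # chord and the rendered width is the full diameter.
        r = self.radius_mm
        return 2.0 * r if r < self.h0_mm else self.width_mm

    @property
    def area_mm2(self) -> float:
        r, h = self.radius_mm, self.h0_mm
        return r * r * float(np.arccos((r - h) / r)) - (r - h) * float(
            np.sqrt(2.0 * r * h - h * h)
        )


@dataclass(frozen=True)
class PhantomSpec:
    """Full parametric description of one synthetic cross section."""

    width_mm: float = 9.0
    height_mm: float = 5.0
    pixel_size_mm: float = 0.015
    cement_line_depth_mm: float = 1.5
    cement_line_slope: float = 0.0
    defect_extent_mm: Optional[Tuple[float, float]] = None
    lesions: Tuple[LesionSpec, ...] = ()
    bridge_vd2_mm: Optional[float] = None
    osteophyte: Optional[OsteophyteSpec] = None
    noise_sigma: float = 0.0
    trabecular_porosity: float = 0.0
    awl: AwlSpec = field(default_factory=AwlSpec)
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.lesions) > 2:
            raise ValueError("at most two lesions per cross section")
        if self.bridge_vd2_mm is not None and len(self.lesions) != 2:
            raise ValueError("a bridge requires exactly two lesions")
        if len(self.lesions) == 2 and self.bridge_vd2_mm is None:
            raise ValueError("two lesions require bridge_vd2_mm (0 = bridge at the line)")
        if self.bridge_vd2_mm is not None and self.bridge_vd2_mm < 0:
            raise ValueError("bridge_vd2_mm must be >= 0 (above-line bridges are osteophytes)")
        if not (0 <= self.trabecular_porosity < 1):
            raise ValueError("trabecular_porosity must lie in [0, 1)")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be >= 0")
        for les in self.lesions:
            if self.cement_line_depth_mm + les.depth_mm > self.height_mm:
                raise ValueError("lesion extends below the canvas")
            if les.base_width_mm(self.awl) <= 0:
                raise ValueError(
                    "cavity wall profile pinches to zero width above its nominal depth"
                )
        if len(self.lesions) == 2:
            a, b = self.lesions
            if a.center_x_mm >= b.center_x_mm:
                raise ValueError("lesions must be ordered left to right")
            gap = (b.center_x_mm - b.hd1_mm / 2) - (a.center_x_mm + a.hd1_mm / 2)
            if gap < -1e-9:
                raise ValueError("lesion openings overlap")
        if self.defect_extent_mm is not None:
            left, right = self.defect_extent_mm
            if not (0 <= left < right <= self.width_mm):
                raise ValueError("defect extent must lie inside the canvas")
            for les in self.lesions:
                half = les.max_width_mm(self.awl) / 2
                if les.center_x_mm - half < left - 1e-9 or les.center_x_mm + half > right + 1e-9:
                    raise ValueError("lesion wider than the defect extent")
        if self.osteophyte is not None:
            if self.cement_line_depth_mm - self.osteophyte.h0_mm <= 0:
                raise ValueError("osteophyte apex lies above the canvas")

    # -- analytic void geometry -------------------------------------------

    def line_depth_at(self, x_mm):
        return self.cement_line_depth_mm + self.cement_line_slope * np.asarray(x_mm, dtype=float)

    def void_intervals(self, depth_mm: float) -> List[Tuple[float, float]]:
        """Disjoint horizontal void intervals at a depth below the cement
        line, merging intervals that touch; the analytic counterpart of a
        raster row scan."""
        ivals: List[Tuple[float, float]] = []
        for les in self.lesions:
            w = les.width_at(depth_mm, self.awl)
            if w > 0:
                ivals.append((les.center_x_mm - w / 2, les.center_x_mm + w / 2))
        if (
            self.bridge_vd2_mm is not None
            and self.bridge_vd2_mm > 0
            and 0 <= depth_mm < self.bridge_vd2_mm
        ):
            a, b = self.lesions
            lo = a.center_x_mm + a.width_at(depth_mm, self.awl) / 2
            hi = b.center_x_mm - b.width_at(depth_mm, self.awl) / 2
            if hi > lo:
                ivals.append((lo, hi))
        ivals.sort()
        merged: List[Tuple[float, float]] = []
        for lo, hi in ivals:
            if merged and lo <= merged[-1][1] + 1e-9:
                merged[-1] = (merged[-1][0], max(merged[-1][1], hi))
            else:
                merged.append((lo, hi))
        return merged

    def bridge_apex_x_mm(self) -> Optional[float]:
        """Horizontal centre of the bridge top plateau (two-lesion specs)."""
        if len(self.lesions) != 2:
            return None
        a, b = self.lesions
        vd2 = self.bridge_vd2_mm or 0.0
        lo = a.center_x_mm + a.width_at(vd2, self.awl) / 2
        hi = b.center_x_mm - b.width_at(vd2, self.awl) / 2
        return 0.5 * (lo + hi)


@dataclass(frozen=True)
class LesionTruth:
    lesion_id: int
    class_label: str
    vd1_mm: float
    vd2_mm: Optional[float]
    hd1_mm: float
    hd2_mm: float
    depth_mm: float
    area_mm2: float
    center_x_mm: float


@dataclass(frozen=True)
class OsteophyteTruth:
    h0_mm: float
    width_mm: float
    area_mm2: float
    location: str


@dataclass(frozen=True)
class GroundTruth:
    """Label and analytic measurements the decision rules force on a spec."""

    reconstituted: bool
    hole_count: int
    lesions: Tuple[LesionTruth, ...]
    osteophyte: Optional[OsteophyteTruth]
    defect_extent_mm: Optional[Tuple[float, float]]
    bridge_apex_x_mm: Optional[float]

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2)


# ---------------------------------------------------------------------------
# ground truth
# ---------------------------------------------------------------------------


def _interval_len_clipped(ivals, lo=None, hi=None) -> float:
    """Longest contiguous void run after clipping to [lo, hi]."""
    best = 0.0
    for a, b in ivals:
        if lo is not None:
            a = max(a, lo)
        if hi is not None:
            b = min(b, hi)
        best = max(best, b - a)
    return max(best, 0.0)


def _side_area(spec: PhantomSpec, max_depth: float, lo=None, hi=None, n=2048) -> float:
    d = np.linspace(0.0, max_depth, n)
    widths = np.empty(n)
    for i, dd in enumerate(d):
        total = 0.0
        for a, b in spec.void_intervals(float(dd)):
            aa = a if lo is None else max(a, lo)
            bb = b if hi is None else min(b, hi)
            total += max(bb - aa, 0.0)
        widths[i] = total
    return float(np.trapezoid(widths, d))


def ground_truth_from_spec(spec: PhantomSpec, cfg=None) -> GroundTruth:
    """Apply the decision rules to the spec's analytic geometry.

    The lesion classes are *forced* by the rules: this is the oracle against
    which the measurement/classification stack is validated.
    """
    from .classification import ThresholdConfig, classify_lesion, count_holes

    cfg = cfg or ThresholdConfig()
    awl = spec.awl
    half_pen = 0.5 * awl.penetration_depth_mm
    eps = 1e-6

    osteo = None
    if spec.osteophyte is not None:
        o = spec.osteophyte
        location = "peripheral"
        if len(spec.lesions) == 2:
            a, b = spec.lesions
            if a.center_x_mm < o.center_x_mm < b.center_x_mm:
                location = "central"
        osteo = OsteophyteTruth(o.h0_mm, o.true_width_mm, o.area_mm2, location)

    if not spec.lesions:
        return GroundTruth(
            reconstituted=osteo is None,
            hole_count=0,
            lesions=(),
            osteophyte=osteo,
            defect_extent_mm=spec.defect_extent_mm,
            bridge_apex_x_mm=None,
        )

    if len(spec.lesions) == 1:
        les = spec.lesions[0]
        hd1 = _interval_len_clipped(spec.void_intervals(eps))
        hd2 = _interval_len_clipped(spec.void_intervals(half_pen)) if les.depth_mm >= half_pen else 0.0
        area = _side_area(spec, les.depth_mm)
        label = classify_lesion(hd1, hd2, awl, cfg).value
        truth = LesionTruth(0, label, les.depth_mm, None, hd1, hd2, les.depth_mm, area, les.center_x_mm)
        return GroundTruth(False, 1, (truth,), osteo, spec.defect_extent_mm, None)

    # two lesions + bridge
    a, b = spec.lesions
    vd2 = float(spec.bridge_vd2_mm)
    vd1 = max(a.depth_mm, b.depth_mm)
    n_holes = count_holes(vd1, vd2, cfg)
    apex_x = spec.bridge_apex_x_mm()

    if n_holes == 2:
        lesions = []
        for idx, les in enumerate((a, b)):
            lo, hi = (None, apex_x) if idx == 0 else (apex_x, None)
            hd1 = _interval_len_clipped(spec.void_intervals(eps), lo, hi)
            hd2 = (
                _interval_len_clipped(spec.void_intervals(half_pen), lo, hi)
                if les.depth_mm >= half_pen
                else 0.0
            )
            area = _side_area(spec, les.depth_mm, lo, hi)
            label = classify_lesion(hd1, hd2, awl, cfg).value
            lesions.append(
                LesionTruth(idx, label, les.depth_mm, vd2, hd1, hd2, les.depth_mm, area, les.center_x_mm)
            )
        return GroundTruth(False, 2, tuple(lesions), osteo, spec.defect_extent_mm, apex_x)

    # merged: the bridge is erosion relief around a single hole
    hd1 = _interval_len_clipped(spec.void_intervals(eps))
    hd2 = _interval_len_clipped(spec.void_intervals(half_pen)) if vd1 >= half_pen else 0.0
    area = _side_area(spec, vd1)
    label = classify_lesion(hd1, hd2, awl, cfg).value
    center = 0.5 * (a.center_x_mm + b.center_x_mm)
    truth = LesionTruth(0, label, vd1, vd2, hd1, hd2, vd1, area, center)
    return GroundTruth(False, 1, (truth,), osteo, spec.defect_extent_mm, apex_x)


# ---------------------------------------------------------------------------
# rendering
# ---------------------------------------------------------------------------


def generate_phantom(spec: PhantomSpec) -> Tuple[CalibratedImage, GroundTruth]:
    """Render a spec to a calibrated 8-bit image and its ground truth.

    Identical spec (including ``seed``) yields a bit-identical image; the
    ground truth is derived analytically from the spec, never from the
    raster.
    """
    px = spec.pixel_size_mm
    n_rows = int(round(spec.height_mm / px))
    n_cols = int(round(spec.width_mm / px))
    x = (np.arange(n_cols) + 0.5) * px
    y = (np.arange(n_rows) + 0.5) * px
    line = spec.line_depth_at(x)  # (cols,)
    depth = y[:, None] - line[None, :]  # depth below cement line, (rows, cols)

    void = np.zeros((n_rows, n_cols), dtype=bool)
    for les in spec.lesions:
        w = les.width_at(depth, spec.awl)
        void |= (depth > 0) & (np.abs(x[None, :] - les.center_x_mm) <= w / 2)
    if spec.bridge_vd2_mm is not None and spec.bridge_vd2_mm > 0:
        a, b = spec.lesions
        lo = a.center_x_mm + a.width_at(depth, spec.awl) / 2
        hi = b.center_x_mm - b.width_at(depth, spec.awl) / 2
        void |= (depth > 0) & (depth < spec.bridge_vd2_mm) & (x[None, :] > lo) & (x[None, :] < hi)

    bone = (depth > 0) & ~void

    if spec.osteophyte is not None:
        o = spec.osteophyte
        r = o.radius_mm
        cap = (
            (depth <= 0)
            & (depth >= -o.h0_mm)
            & ((x[None, :] - o.center_x_mm) ** 2 + (depth - (r - o.h0_mm)) ** 2 <= r * r)
        )
        bone |= cap

    rng = np.random.default_rng(spec.seed)

    if spec.trabecular_porosity > 0:
        bone = _carve_trabecular_pores(bone, void, depth, px, spec.trabecular_porosity, rng)

    gray = np.where(bone, BONE_GRAY, BACKGROUND_GRAY)
    if spec.noise_sigma > 0:
        gray = gray + rng.normal(0.0, spec.noise_sigma, gray.shape)
    pixels = np.clip(np.rint(gray), 0, 255).astype(np.uint8)

    image = CalibratedImage(pixels, px)
    return image, ground_truth_from_spec(spec)


def _carve_trabecular_pores(bone, cavity_void, depth, px, porosity, rng):
    """Carve random elliptical marrow spaces into the deep bone.

    Pores stay below ``TRABECULAR_MIN_DEPTH_MM`` and keep a sclerotic rim of
    ``TRABECULAR_RIM_MARGIN_MM`` around the lesion cavities so the cavity's
    connected component is unchanged.
    """
    margin_px = max(1, int(round(TRABECULAR_RIM_MARGIN_MM / px)))
    near_cavity = ndi.binary_dilation(cavity_void, iterations=margin_px)
    eligible = bone & (depth > TRABECULAR_MIN_DEPTH_MM) & ~near_cavity
    coords = np.argwhere(eligible)
    if coords.size == 0:
        return bone
    target = porosity * eligible.sum()
    bone = bone.copy()
    carved = 0
    h, w = bone.shape
    max_attempts = int(target / 10) + 2000
    for _ in range(max_attempts):
        if carved >= target:
            break
        r0, c0 = coords[rng.integers(len(coords))]
        a = rng.uniform(2.0, 6.0)  # semi-axes in pixels
        b = rng.uniform(2.0, 6.0)
        theta = rng.uniform(0, np.pi)
        ext = int(np.ceil(max(a, b))) + 1
        rr = np.arange(max(0, r0 - ext), min(h, r0 + ext + 1))
        cc = np.arange(max(0, c0 - ext), min(w, c0 + ext + 1))
        dr = (rr - r0)[:, None]
        dc = (cc - c0)[None, :]
        ct, st = np.cos(theta), np.sin(theta)
        u = dr * ct + dc * st
        v = -dr * st + dc * ct
        ell = (u / a) ** 2 + (v / b) ** 2 <= 1.0
        window = np.ix_(rr, cc)
        pore = ell & eligible[window] & bone[window]
        bone[window] &= ~pore
        carved += int(pore.sum())
    return bone


# ---------------------------------------------------------------------------
# random spec sampling
# ---------------------------------------------------------------------------

#: Default sampling ranges.  Lengths in mm.  ``guard_mm`` is the margin kept
#: between every sampled analytic quantity and its decision threshold so that
#: the class a phantom realizes is unambiguous at the render resolution.
DEFAULT_RANGES: dict = {
    "hd1_residual": (0.8, 2.26),
    "hd1_resorption": (2.54, 3.4),
    "hd2": (0.8, 3.46),
    "hd2_cyst": (3.74, 4.4),
    "depth": (1.3, 2.6),
    "depth_cyst": (1.5, 2.9),
    "cement_line_depth": (1.3, 1.7),
    "cement_line_slope": (-0.04, 0.04),
    "osteophyte_h0": (0.15, 0.45),
    "osteophyte_width_factor": (2.4, 4.0),  # width = factor * h0
    "p_two_lesions": 0.55,
    "p_relief_bridge": 0.3,  # among two-lesion sections: vd2 > 0.5 vd1
    "p_osteophyte": 0.25,
    "noise_sigma": 0.0,
    "trabecular_porosity": 0.0,
    "guard_mm": 0.12,
}


class SpecSamplingError(RuntimeError):
    """Raised when no feasible spec is found within the attempt budget."""


def _sample_lesion_dims(rng, ranges, target_class):
    if target_class == "subchondral_cyst":
        hd2 = rng.uniform(*ranges["hd2_cyst"])
        hd1 = rng.uniform(0.9, 2.2)
        depth = rng.uniform(*ranges["depth_cyst"])
        profile = "bulb"
    else:
        if target_class == "residual_hole":
            hd1 = rng.uniform(*ranges["hd1_residual"])
        else:
            hd1 = rng.uniform(*ranges["hd1_resorption"])
        hd2 = rng.uniform(*ranges["hd2"])
        depth = rng.uniform(*ranges["depth"])
        # keep the trapezoid wall taper gentle (|dw/dd| <= 0.6) so that the
        # rendered opening matches Hd1 to within the half-pixel cement-line
        # phase uncertainty; steeper flares use the necked bulb profile
        profile = "trapezoid" if abs(hd2 - hd1) <= 0.6 else "bulb"
    return hd1, hd2, depth, profile


def sample_random_spec(
    ranges: Optional[dict] = None,
    seed: Optional[int] = None,
    rng: Optional[np.random.Generator] = None,
    max_attempts: int = 500,
) -> PhantomSpec:
    """Draw a random feasible phantom spec (rejection sampling).

    The sampler keeps every analytic quantity at least ``guard_mm`` away from
    its decision threshold (and the bridge height away from the 0.5*Vd1 and
    half-penetration levels), so the class the rules force on the spec is
    stable under the <= 2 pixel render/measure uncertainty.
    """
    merged = dict(DEFAULT_RANGES)
    if ranges:
        merged.update(ranges)
    rg = merged
    if rng is None:
        rng = np.random.default_rng(seed)

    awl = rg.get("awl", AwlSpec())
    guard = rg["guard_mm"]
    width_mm, height_mm = 9.0, 5.0
    classes = ("residual_hole", "peri_hole_resorption", "subchondral_cyst")

    for _ in range(max_attempts):
        two = rng.random() < rg["p_two_lesions"]
        line_depth = rng.uniform(*rg["cement_line_depth"])
        slope = rng.uniform(*rg["cement_line_slope"])
        osteo_kind = None
        if rng.random() < rg["p_osteophyte"]:
            osteo_kind = "central" if (two and rng.random() < 0.5) else "peripheral"

        dims = [_sample_lesion_dims(rng, rg, classes[rng.integers(3)]) for _ in range(2 if two else 1)]
        spec = _assemble_spec(rng, rg, awl, dims, two, osteo_kind, line_depth, slope, width_mm, height_mm)
        if spec is None:
            continue
        if _passes_guards(spec, awl, guard):
            return spec
    raise SpecSamplingError(f"no feasible phantom spec found in {max_attempts} attempts")


def _assemble_spec(rng, rg, awl, dims, two, osteo_kind, line_depth, slope, width_mm, height_mm):
    p = awl.penetration_depth_mm
    max_depth_allowed = height_mm - line_depth - abs(slope) * width_mm - 0.2
    fixed = []
    for h1, h2, dep, prof in dims:
        dep = min(dep, max_depth_allowed)
        if dep < 0.5 * p + 0.25:
            return None
        if prof == "trapezoid":
            base = h1 + (h2 - h1) * dep / (0.5 * p)
            if base < 0.12:
                prof = "bulb"  # narrowing too steep for a trapezoid of this depth
        fixed.append((h1, h2, dep, prof))
    dims = fixed

    if not two:
        hd1, hd2, dep, prof = dims[0]
        half_w = LesionSpec(0.0, hd1, hd2, dep, prof).max_width_mm(awl) / 2
        cx = width_mm / 2 + rng.uniform(-0.5, 0.5)
        lesions = (LesionSpec(cx, hd1, hd2, dep, prof),)
        vd2 = None
        extent_lo = cx - half_w - 0.3
        extent_hi = cx + half_w + 0.3
    else:
        (h1a, h2a, da, pa), (h1b, h2b, db, pb) = dims
        vd1 = max(da, db)
        min_dep = min(da, db)
        if osteo_kind == "central":
            vd2 = 0.0
            gap = rng.uniform(0.35, 0.7)
        else:
            relief = rng.random() < rg["p_relief_bridge"]
            if relief:
                # equalize depths so the bridge can sit above half depth on
                # both sides
                da = db = vd1 = min_dep = 0.5 * (da + db)
                lo_v, hi_v = 0.58 * vd1, 0.85 * vd1
            else:
                lo_v, hi_v = 0.15, min(0.42 * vd1, min_dep - 0.2)
            if hi_v <= lo_v:
                return None
            vd2 = rng.uniform(lo_v, hi_v)
        les_a_tmp = LesionSpec(0.0, h1a, h2a, da, pa)
        les_b_tmp = LesionSpec(1e3, h1b, h2b, db, pb)
        if osteo_kind != "central":
            # each cavity must keep its full width on its own side of the
            # bridge apex at every depth, so the apex split is unambiguous
            flare_a = les_a_tmp.max_width_mm(awl) - h1a
            flare_b = les_b_tmp.max_width_mm(awl) - h1b
            gap = max(flare_a, flare_b, 0.0) + 0.12 + rng.uniform(0.1, 0.4)
        half_wa = les_a_tmp.max_width_mm(awl) / 2
        half_wb = les_b_tmp.max_width_mm(awl) / 2
        ca_off = h1a / 2 + gap / 2
        cb_off = h1b / 2 + gap / 2
        span = (half_wa + ca_off) + (half_wb + cb_off)
        if span + 1.8 > width_mm:
            return None
        x_mid = width_mm / 2 + rng.uniform(-0.3, 0.3)
        ca = x_mid - ca_off
        cb = x_mid + cb_off
        if osteo_kind == "central" and (ca + half_wa > x_mid - gap / 2 or cb - half_wb < x_mid + gap / 2):
            return None  # flaring walls would undercut the plate-level bridge
        lesions = (LesionSpec(ca, h1a, h2a, da, pa), LesionSpec(cb, h1b, h2b, db, pb))
        if vd2 is not None and vd2 > 0:
            apex = 0.5 * (
                (ca + lesions[0].width_at(vd2, awl) / 2) + (cb - lesions[1].width_at(vd2, awl) / 2)
            )
            if ca + half_wa > apex - 0.05 or cb - half_wb < apex + 0.05:
                return None  # a flaring wall would cross the apex at depth
        extent_lo = ca - half_wa - 0.3
        extent_hi = cb + half_wb + 0.3

    osteophyte = None
    if osteo_kind is not None:
        h0 = rng.uniform(*rg["osteophyte_h0"])
        w = h0 * rng.uniform(*rg["osteophyte_width_factor"])
        if osteo_kind == "central" and two:
            w = min(w, gap - 0.08)
            if w < 2.2 * h0:
                return None
            # the bridge-top gap is centred on x_mid by construction
            gap_mid = 0.5 * (
                (lesions[0].center_x_mm + lesions[0].hd1_mm / 2)
                + (lesions[1].center_x_mm - lesions[1].hd1_mm / 2)
            )
            osteophyte = OsteophyteSpec(gap_mid, h0, w)
        else:
            # attach the cap to the outer opening edge of a flanking hole
            les = lesions[0] if (not two or rng.random() < 0.5) else lesions[-1]
            left_side = les is lesions[0]
            half = les.max_width_mm(awl) / 2
            edge = les.center_x_mm - half if left_side else les.center_x_mm + half
            cx = edge - 0.02 - w / 2 if left_side else edge + 0.02 + w / 2
            osteophyte = OsteophyteSpec(cx, h0, w)
            extent_lo = min(extent_lo, cx - w / 2 - 0.2)
            extent_hi = max(extent_hi, cx + w / 2 + 0.2)

    extent = (max(extent_lo, 0.2), min(extent_hi, width_mm - 0.2))
    # the cement-line fit needs intact plate on both flanks
    if extent[0] < 0.8 or extent[1] > width_mm - 0.8 or extent[0] >= extent[1]:
        return None
    try:
        return PhantomSpec(
            width_mm=width_mm,
            height_mm=height_mm,
            pixel_size_mm=rg.get("pixel_size_mm", 0.015),
            cement_line_depth_mm=line_depth,
            cement_line_slope=slope,
            defect_extent_mm=extent,
            lesions=lesions,
            bridge_vd2_mm=vd2,
            osteophyte=osteophyte,
            noise_sigma=rg["noise_sigma"],
            trabecular_porosity=rg["trabecular_porosity"],
            awl=awl,
            seed=int(rng.integers(2**31 - 1)),
        )
    except ValueError:
        return None


def _passes_guards(spec: PhantomSpec, awl: AwlSpec, guard: float) -> bool:
    from .classification import ThresholdConfig

    cfg = ThresholdConfig()
    truth = ground_truth_from_spec(spec, cfg)
    t1 = cfg.hd1_multiplier * awl.diameter_mm
    t2 = cfg.hd2_multiplier * awl.diameter_mm
    half_pen = 0.5 * awl.penetration_depth_mm
    for les in truth.lesions:
        if abs(les.hd1_mm - t1) < guard or abs(les.hd2_mm - t2) < guard:
            return False
        if les.vd2_mm is not None:
            if abs(les.vd2_mm - cfg.bridge_fraction * les.vd1_mm) < 0.08 * les.vd1_mm:
                return False
            if les.vd2_mm > 0 and abs(les.vd2_mm - half_pen) < 0.1:
                return False
    return True


def save_ground_truth(path, truth: GroundTruth) -> None:
    from pathlib import Path

    Path(path).write_text(truth.to_json())
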