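# Methods

## The analysis problem

Marrow stimulation (microfracture) perforates the subchondral bone plate of
a debrided cartilage defect with a conical-tipped awl so that marrow cells
reach the lesion.  On follow-up micro-CT, the treated subchondral bone shows
a spectrum of alterations: the plate may be fully restored, bone may
overgrow above its original level, the awl channels may persist, their
openings may be widened by resorption, or cystic cavities may form at depth.
These entities have distinct biological interpretations but shade into each
other visually, so this package implements a purely geometric decision
algorithm on calibrated 2D cross sections: every boundary between entities
is an explicit length comparison against the awl itself.

## Reference frame and measured quantities

All measurements are anchored to the **projected cement line** — the
straight line marking the original top of the subchondral bone plate,
extended across the defect.  Coordinates are physical: pixel centres at
`x = (col + 0.5)·s`, `depth = (row + 0.5)·s` with `s` the pixel size in mm
(default 0.015 mm; depth increases toward the subarticular spongiosa).
Distances below the line are positive.

Per section, the pipeline measures:

* `Vd1` — line to the base of the defect (deepest void pixel of the cavity
  component);
* `Vd2` — line to the top of a suspected bone bridge between two cavities;
* `Hd1` — horizontal void run along the line across a hole's opening;
* `Hd2` — maximal horizontal void run parallel to the line at **half the
  awl penetration depth** (not half the actual cavity depth — cysts extend
  beyond the awl track);
* osteophyte `H0`/width/2D area for bone protruding strictly above the line;
* lesion depth and 2D void area below the line.

## Decision rules

Part one: if no surface deviation from the line exceeds the reconstitution
tolerance (0.1 mm) on any section of the defect, the defect is **complete
reconstitution**.

Part two, per section:

1. Bone rising strictly above the line within the defect is an
   **intra-lesional osteophyte** (central if between two holes, peripheral
   if between a hole and the defect edge).  It is reported alongside the
   cavity classes; a bridge protruding above the line is assigned `Vd2 = 0`
   for the hole-count rule.
2. Hole count: a bridge with `Vd2 < 0.5·Vd1` (strict) is persistent and
   separates **two holes**, each analyzed separately; a higher remnant is
   erosion relief of a **single hole**.
3. Per hole, with awl diameter Ø (1.2 mm):
   `Hd2 > 3·Ø` → **subchondral bone cyst** (evaluated first; it holds
   irrespective of Hd1 and also resolves sweeps in which the multipliers
   cross); else `Hd1 > 2·Ø` → **peri-hole bone resorption**; else
   **residual microfracture hole**.

Boundary policy: pathology requires the strict inequality; exact equality
falls to the milder category and is logged.  The three constants (0.5, 2, 3)
live in `ThresholdConfig` and `threshold_sweep` re-tabulates class counts
over multiplier grids; by construction each pathology count is
non-increasing in its own multiplier.

Across consecutive sections, holes are tracked by horizontal-centre
proximity (nearest track within one awl diameter — holes are placed roughly
one diameter apart or more) and each tracked hole reports its worst-case
class, ordered cyst > resorption > residual hole.  The aggregation rule
is this package's choice; per-section outcomes are also reported.

## Operational definitions the raters left implicit

Manual raters draw the cement line and outline the defect; an algorithm
needs reproducible substitutes:

* **Cement line**: least-absolute-deviations straight-line fit to the
  topmost-bone profile of the intact plate flanking the defect (annotated
  endpoints override the fit).  The profile uses pixel centres, which sit
  half a pixel below the true bone boundary; the fit subtracts this bias.
  On a perfectly flat plate the residual sub-pixel phase of the line is
  unobservable, so all downstream operators are designed to tolerate a
  half-pixel line offset (see *Numerical choices*).
* **Defect region**: the maximal contiguous column interval whose surface
  deviates from the line by more than 0.1 mm in either direction, or an
  annotated extent.  The same 0.1 mm is the complete-reconstitution
  tolerance.
* **Bridge**: an interior surface maximum separating two basins that each
  deviate below the line and are deeper than the apex by at least 0.1 mm.
  The apex depth is the plateau minimum; the apex position is the midpoint
  of the plateau (within 1.5 px of the minimum, absorbing the one-pixel
  sawtooth a tilted line produces on a flat bridge top).
* **Per-hole Hd with a sub-line bridge**: erosion above a persistent bridge
  connects both openings at line level, so the void is split at the bridge
  apex and each hole's Hd1/Hd2 includes its share of the eroded notch.
  When the bridge reaches the line (osteophyte configuration) each hole
  keeps its own opening.
* **Connectivity**: 4-connectivity for void, 8-connectivity for bone, so
  diagonal void chains cannot leak through a diagonal bone wall.

## Synthetic phantoms and what passing tests show

No imaging data accompany the method, so validation uses parametric
phantoms: a plate with a straight (optionally tilted) cement line, one or
two cavities with prescribed `Hd1`/`Hd2`/depth, an inter-hole bridge at
prescribed `Vd2`, optional circular-arc osteophyte caps, optional
trabecular texture (random elliptical marrow spaces carved only >0.5 mm
below the line and ≥0.15 mm away from cavities, mimicking the sclerotic
rim) and Gaussian gray noise.  Bone gray is N(180, σ), background N(40, σ),
straddling the default 89–255 bone window; the default noise condition used
in the noisy validation batches is σ = 10 with porosity 0.15.

Cavity wall profiles are piecewise linear: a *trapezoid* interpolates from
`Hd1` at the opening through `Hd2` at half penetration depth to the base; a
*bulb* has a vertical neck (upper 15 % of the penetration depth), a flare to
an equatorial plateau of width `Hd2` spanning 40–60 % of the penetration
depth, and a taper to half the neck width — so both `Hd1` and `Hd2` are
realized exactly at their measurement levels.  The generator constrains
geometry so the rendered image determines the label unambiguously:
trapezoid tapers are capped at |ΔHd| ≤ 0.6 (steeper flares become bulbs),
two-hole gaps keep each cavity's full width on its own side of the bridge
apex, and the random sampler keeps every analytic quantity ≥0.12 mm away
from its decision threshold (the phantom's class is *forced* by the rules;
a phantom whose truth depends on sub-pixel detail would validate nothing).

Ground truth is computed analytically from the spec geometry (interval
arithmetic plus quadrature for areas), never from the raster, under the
same operational conventions listed above.  Rendered phantoms reproduce
every analytic quantity within two pixels, and the full pipeline recovers
100 % of classes and hole counts on 500 random noiseless phantoms and ≥95 %
(measured: 100 %) under noise.

Phantoms emulate binarizable cross sections with at most two holes per
section and straight cement lines.  They do not emulate curved plates,
partial bony fill inside channels, beam hardening, ring artifacts, or
contrast variation with mineral density — passing tests therefore show the
decision logic and the geometric operators are correct, not that
segmentation is robust to every scanner artifact.  Real acquisitions also
need their own gray window and BMD rod calibration.

## Numerical choices

* Gray bone window closed on both bounds (89–255 read as a closed range).
* BMD: exact line through the 250/750 mg CaHA/cm³ rod points;
  extrapolation allowed with a logged warning.
* LAD line fit solved as a linear program (HiGHS); deterministic.
* Sub-pixel line phase handling: (i) half-pixel debias of the surface
  profile; (ii) a *sliver filter* removes void pixels that lie above their
  own column's bone surface when that column is not depressed by more than
  two pixels (intact plate whose top pokes just below the fitted line);
  (iii) Hd1 is extrapolated from its sampling row back to line level using
  the wall taper estimated two rows deeper; (iv) osteophyte components drop
  runs of single-pixel-tall columns longer than four columns (plate-top
  strips), while short single-pixel runs (tapering cap ends) are kept.
* Bone speckle smaller than 5 pixels is removed before analysis
  (standard despeckling; a single noise pixel above the line would
  otherwise masquerade as overgrowth).
* Osteophytes require ≥3 pixels and >1 pixel of height; `measure_osteophyte`
  returns the tallest, `measure_osteophytes` all of them.
* The awl penetration depth is a required input (the instrument's stop
  standardizes it, but its value is instrument specific); phantoms default
  to 2.0 mm as a package convention.
* Degenerate inputs: `Vd2 > Vd1` is rejected (a bridge below the defect
  base is geometrically impossible); a cavity shallower than half the
  penetration depth reports `Hd2 = 0` with a warning; a defect without
  flanking intact plate requires an annotated cement line.

## Validation problem sizes

The shipped validation batches use 500 noiseless and 200 noisy random
phantoms (9 × 5 mm canvas at 15 µm, ~200k pixels each) and 1000 random
measurement sets for the sweep-monotonicity property; these sizes give
tight empirical bounds (a single class flip would move accuracy by ~0.2 %)
while keeping a full run in a few minutes on one core.

## Known limitations

* Sections with more than two holes per image (possible with dense hole
  patterns) are outside the two-branch hole-count rule; the bridge detector
  finds the most prominent bridge only.
* General upward migration of the whole subchondral plate is not a class
  of this algorithm (deliberately excluded from its scope).
* Inter-rater agreement utilities compute percent agreement and unweighted
  Cohen's kappa for any supplied rating pairs; confidence intervals and
  weighted kappa variants are not implemented.
* The cement line is modelled as straight; strongly curved plates would
  need a curved reference or piecewise annotation.
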