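# Methods

## Maze model

The maze is modeled in pixel space as a central disc of radius `R` with
`n_arms` rectangular arms (default eight at 45° spacing, 70 cm long and
10 cm wide).  Coordinates are `(x, y) = (col, row)`, 0-based, origin at the
top-left of the 480×480 working subimage; the default scale is 0.4 cm/px,
which puts the maze span (≈166 cm across opposite arm tips) comfortably
inside the frame.

An arm rectangle starts at the chord offset `x_j = sqrt(R² − (W/2)²)` so it
meets the platform rim at full width.  The lens-shaped overlap between the
rectangle and the disc is assigned to the arm's proximal segment.  This
choice makes each of the ten per-arm segments an exact `7 cm × 10 cm =
70 cm²` rectangle.

The platform is partitioned into nine pieces as a central disc of radius
`R/3` plus eight annular sectors: all nine are exactly one ninth of the
disc area (70 cm² for the default platform, which is sized so that a
platform piece matches an arm segment) before arm clipping; the sectors
facing arms lose the ~6 cm² junction sliver and end ≈9 % below 70 cm².  A
3×3 grid was considered and rejected: no grid pitch that still covers the
disc keeps the corner cells within 15 % of the target area, while the
disc-plus-sectors partition is exact by construction.  The total is
`10·n_arms + 9` zones — 89 for the default maze.

Entry lines are the chords across each arm's proximal end (endpoints on the
platform rim, length = arm width).  Point classification is analytic
(rotation into each arm's frame, then radius/angle tests) and resolves the
disc/arm overlap in favor of the arm, mirroring the zone partition; the
shapely zone polygons (circular edges discretized at 256 vertices) exist
for area accounting and as an independent oracle in the tests.

## Localization pipeline

Per frame: grayscale conversion with weights (0.299, 0.589, 0.114) — the
published coefficients for this pipeline, kept as printed even though they
sum to 1.002 — then strict binarization at 127.  The binary image is
duplicated; one copy is intersected with the filled footprint mask and
opened with the 5×5 all-ones element, the other is opened directly, and the
two results are intersected.  Because opening is increasing and the masked
image is a subset of the unmasked one, this final intersection equals the
masked-and-opened image; it is kept for structural fidelity to the
dual-image procedure, and the masked-opened image also serves as the
explicit fallback when the intersection yields no candidate.

Morphology follows the set definitions with the *reflected* element
(`A⊖B = {z | (B̂)_z ⊆ A}`, `A⊕B = {z | (B̂)_z ∩ A ≠ ∅}`); out-of-image
pixels are background for both operations, which keeps opening
anti-extensive at the borders.  The implementation delegates to
`scipy.ndimage` (`binary_erosion` on the flipped element, `binary_dilation`,
8-connected `label`); the tests verify it against a brute-force evaluation
of the definitions over every translation.

Candidates are 8-connected components with area ≥ `min_component_area`
(default 25 px = the element's area, rejecting marginal opening survivors)
whose centroid lies inside the mask.  One candidate → the rat; several →
the largest (in-maze noise residue is smaller than the animal); none → the
largest qualifying component of the masked-opened image; failing that, the
frame is flagged not-found and the last known position is carried forward
(flagged) so the behavioral layer always has a position per tick.
Rounding is deferred until after thresholding and the centroid is
real-valued.

## Behavioral scoring

The arm-access machine holds `maze_state` (0 = platform, else the 1-based
current arm), per-arm food flags and entry counters.  An entry fires when
the center is within `entry_distance_px` (default half the arm width) of an
arm's entry line *and* on the arm side of it; an exit requires the platform
side.  The side-of-line requirement is a hysteresis: a single distance test
would chatter when the animal hovers on the line, and it also defines the
edge case of an aborted visit (an entry counts once the animal is on the
arm side).  Scoring happens at entry time: a re-entry into any previously
entered arm increments the working-memory count; a first entry into a
never-baited arm increments the reference-memory count.  Entry counts every
completed entry event (the standard RAM convention), and a baited arm's
food flag clears when the animal reaches the arm's distal segment — food
taking is inferred purely from position.  When no baited arm retains food
the session is complete, the state freezes, and latency = completion time −
first-update time.  Re-entry into an emptied baited arm scores as a
working-memory error (entered-before takes precedence over the food state).

## Metrics

* **Path length** — sum of consecutive dot distances × cm/px; carried-forward
  samples duplicate the previous position and add zero displacement.
* **Average speed** — path length / session duration.
* **Dwell fractions** — classified per sample; the denominator is the full
  session sample count, so out-of-footprint samples make the three
  percentages sum below 100.
* **S spots** — stillness episodes: a spot anchors at the first sample whose
  next `min_duration_s` (default 2 s) stays within `radius_cm` (default
  2.5 cm, about a quarter body length) of it, extends while samples remain
  within the radius of the anchor, and scanning resumes after it ends —
  spots never overlap.  The measured episode includes the transit through
  the stillness radius (≈ `3·radius/speed` extra for a retraced approach),
  which the tests account for analytically.
* **Zone histogram** — per-zone sample counts; the "dots" are the logged
  samples themselves.

## Synthetic scenes

The generator emulates overhead IR footage at the study conditions: a
uniform dark background (gray 40), a bright elliptical rat (30×15 px ≈
12×6 cm, gray 200) oriented along its motion on a constant-speed waypoint
itinerary (12 cm/s with ~4 s food pauses, matching typical healthy-animal
travel speeds), ten dropping spots deposited near the path at seeded times
that persist for the rest of the session (2–4 px by default — erased by the
opening; the robustness scenes use 2–8 px so some survivors exercise the
largest-component rule), three bright clutter blocks outside the footprint,
and an optional intruder.  The intruder strip (200×40 px, gray 220) enters
from the image edge along one arm's axis, rests covering the outermost
10 px of the arm (in-maze residue ≈250 px, smaller than the ≈350 px rat),
and once per presence block steps fully across the arm for ~2 s — during
that transit the residue exceeds the rat and the tracker honestly loses the
animal, which is what degrades the Case-2 detection rate below the Case-1
value.  The `occluder` variant covers the distal part of an arm for its
whole block.  All randomness flows through one seeded generator; renders
are bit-identical given the seed.

Event logs are derived from region-classification transitions of the true
path (not from the scoring machine), so the test that the state machine
reproduces them is a genuine closure check.

What the generator does *not* emulate: sensor noise and illumination
gradients (the background is exactly uniform), fur texture and shadows,
body articulation (the blob is a rigid ellipse), occlusion of the rat *by*
the intruder, and lens distortion.  Passing the robustness suites therefore
demonstrates the pipeline's noise-rejection logic (opening, mask,
largest-component selection), not photometric robustness on real video.

## Problem sizes and numerics

The robustness runs use 3000 frames (5 min at 10 fps) per case — the
package's chosen simulation scale for a 5-minute-equivalent session; the
logging tick (0.05 s) is exposed independently of the frame rate.  The
detection criterion is strict membership of the reported centroid in the
true elliptical body.  Zone rasterization assigns each pixel center to
exactly one zone, so zone raster areas sum exactly to the mask raster area;
the analytic circle and its 256-gon polygon disagree only within ~10⁻³ px,
which the polygon-oracle tests exempt via a 0.05 px boundary band.
Trajectory CSVs round-trip bit-exactly (floats are written at full
precision and parsed with the round-trip parser).

## Known limitations

* One animal, one blob: no identity handling, no multi-animal support.
* A lost rat is carried forward indefinitely; there is no re-acquisition
  gating, so a long occlusion biases dwell statistics toward the last seen
  position.
* An intruder residue larger than the animal (e.g., a limb resting across
  a proximal arm) captures the tracker for as long as it persists; the
  method's own largest-component assumption is the limit here.
* Video-file input requires an imageio video backend; the tested input
  path is a directory of numbered PNG/BMP frames.
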