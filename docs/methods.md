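# Methods

## Sensor model and units

All geometry assumes a depth camera mounted on the ceiling, optical axis
vertical, at `max_height` millimeters above the floor (default 3,000 mm,
the operating point for which every threshold below was calibrated). Depth
is the distance from the sensor plane to the first surface along each
pixel's ray, in integer millimeters; 0 is reserved for sensor dropouts.
The field of view is ±28.5° horizontally across 320 pixels and ±21.5°
vertically across 240, so a pixel extent `Wp` at depth `d` corresponds to a
real extent

    Wr_x = 2 d tan(28.5°) Wp / 320      (horizontal)
    Wr_y = 2 d tan(21.5°) Wp / 240      (vertical)
    Wr_diag = sqrt(Wr_x² + Wr_y²)       (diagonal steps: one row + one column each)

These relations are used in both directions: to convert measured pixel
spans into head dimensions, and to convert metric windows (e.g. the peak
averaging radius) into pixels at a given depth.

## Preprocessing choices

* **Floor clamp band** (200 mm, inclusive): applied to every non-null pixel
  within the band, regardless of what the pixel belongs to; a thin carpet
  or a lying person's feet inside the band are deliberately absorbed into
  the floor.
* **Null filling** is directional: interior and trailing runs of zeros copy
  the nearest valid value to their left, a leading run copies the first
  valid value to its right, and an all-null row becomes the floor. This is
  a single deterministic pass; it is total (no zero survives) and
  idempotent.
* **Foreground test** is strict: `|CF − RF| > th_person` (a deviation of
  exactly 50 mm is background). The reference frame is captured once from
  person-free frames (pixel-wise median) and never updated; adaptive
  background maintenance is out of scope.
* **Sobel carving** uses the standard 3×3 kernels with edge replication and
  the L1 magnitude `|Gx| + |Gy|`, which keeps the computation exact in
  integer arithmetic. `th_sobel` = 2,000 is calibrated against this
  operator: a clean step of Δ between neighbouring columns reads as 4Δ, so
  steps of 500 mm and above are carved. The gradient is evaluated on the
  sliced foreground frame (not the raw current frame): only after the
  6,000 mm boost is a person guaranteed to exceed the threshold against
  furniture of similar raw depth. Pixels at or above threshold are set to
  the floor level — carving the *bounds* of objects; carving below the
  threshold would erase object interiors instead.
* **Super-pixel binarization** is conservative: a 6×8 block is occupied only
  if *every* pixel differs from the floor level, so the carved one- to
  two-pixel boundary reliably severs block adjacency between elements.

## Blob labeling

The row-scan labeler is equivalent to 4-connected component labeling
(verified against an independent flood fill on random grids), but is
specified operationally because its intermediate structures (row spans,
the previous row's occupancy vector, the bitwise AND) are what the tracking
layer reuses. Conventions: spans separated by at least one empty cell are
distinct; diagonal contact does not join; when one span bridges several
existing labels, the smallest label survives (merges may chain within a
row and are resolved transitively); final ids are renumbered densely in
row-major first-occurrence order. Internal coordinates are 0-based
(row, column); published worked examples use 1-based (x = column,
y = row) and are converted at the fixture boundary.

## Person identification

All three checks start from the blob's **peak point** `mp`: the pixel of
minimum depth, refined by averaging the blob pixels within a 100 mm planar
radius and 50 mm depth window of the minimum (both configurable). Ties
among equal-depth minima resolve to the pixel nearest the blob's pixel
centroid, then row-major — so a perfectly flat slab peaks at its centroid
rather than its top-left corner. The averaged point is snapped back into
the blob footprint if rounding leaves it.

* **Head–ground gap**: some direction shows a *single-step* drop
  ≥ depth(mp)/2. The halved depth makes the criterion self-scaling: a
  standing person's silhouette step always passes, a desk's never does.
* **Head–shoulder gap**: the *cumulative* drop from `mp` first lands inside
  200–300 mm before exceeding it, in at least 2 of 8 directions. Cumulative
  (rather than single-step) because the drop over the head's curvature is
  spread across several pixels; a 350 mm drop straight to a surface skips
  the window and does not count.
* **Head dimension**: per direction, the pixel distance at which either gap
  condition is first met (the smaller if both); a direction meeting neither
  contributes its distance to the frame border, which pushes the paired sum
  of any non-head shape far out of range. The four paired extents (N+S,
  NE+SW, E+W, SE+NW), converted at depth(mp), must all lie in 200–400 mm
  and be mutually comparable. "Comparable" is quantified as
  max/min ≤ 1.5 — a testable surrogate for an otherwise qualitative
  criterion, configurable via `head_comparability_ratio`.

## Tracking

Association is anchor-based: each tracked element stores its central
super-pixel `scp` (blob member nearest the coordinate centroid; the
corresponding full-resolution point `cp` is the center pixel of that 6×8
block) and its peak super-pixel `smp`. The blob of the next frame that
contains `scp` inherits the identity. Per-blob conditions:

* **A** (no person, ≤ 1 object): the anthropometric checks run — only blobs
  not yet classified as human are ever examined — and the blob is promoted
  to a new person or recorded/re-centered as an object.
* **B** (one person, no object): anchors recomputed on the new shape.
* **C** (anything else): fusion. Blob cells within a Chebyshev radius of 5
  super-pixels (≈ one torso at 3 m; configurable) of each member's `smp`
  are kept, contested cells go to the nearest peak (ties to the lower
  member id), each window is re-labeled, and the piece containing the peak
  becomes that member's blob. This preserves all identities through
  shoulder-contact fusions of two or more subjects.

A person unmatched for more than 15 consecutive frames (0.5 s at 30 fps)
is retired; unmatched objects are dropped immediately (the scene is
assumed static apart from its subjects). Both choices concern exit
handling, on which the method itself is silent.

**Fall rule**: height above the floor is read at the person's `cp`
(deliberately literal: the central point, not the blob minimum), and an
event fires when it drops strictly below 400 mm — the body thickness a
top-view sensor reads for a person lying on the floor. Exactly 400 mm does
not alarm. Events are edge-triggered (one per excursion below threshold)
while per-frame heights are logged for trace plots. Only tracked persons
can raise events; an unidentified low object never does.

## Synthetic scenes

The simulator renders what the geometry of the method assumes and nothing
more: a flat floor, axis-aligned furniture slabs, and subjects built from a
spherical head cap (apex at body height), a shoulder slab
`shoulder_drop` = 250 mm below the apex, and a torso cylinder. During a
fall the body height interpolates from standing to a 350 mm prone slab over
0.15 s while the footprint grows as the body tips over; 350 mm sits below
the 400 mm rule so falls are detectable by construction (configurable).
Dropouts are injected as an exact, seeded count of zeroed pixels; optional
±5 mm integer depth noise is off by default so worked-example fixtures stay
exact. Rendering is deterministic per (scene, seed).

Canonical scenarios: `simple_fall` (one subject, one desk, no contact, 6 s),
`complex_fall` (below), `fusion_walk` (two subjects converge to shoulder
contact amid three furniture pieces, then separate, 4 s),
`outstretched_arms` (a U-shaped blob whose branches merge mid-scan), and
`table1_seven_blobs` (seven disjoint static clusters). Default sequence
lengths (120–180 frames) are chosen to cover each scenario's full
narrative arc at 30 fps.

`complex_fall` is built to exhibit the documented failure mode of running
without a reference frame: its desk top (1,250 mm) lies within the 500 mm
carve window of the walking subject's shoulders, so without the RF boost
the subject is merged with the desk from first appearance, the track
anchors to the (larger) desk surface, and the prone body — separating only
once it is near the floor, with no head geometry left — is classified as a
new *object*: the fall is missed. With the true reference frame the subject
is always sliced apart from the desk and the same fall is detected within
5 frames.

What the simulator does **not** emulate: IR speckle and material-dependent
noise, articulated limbs, lens distortion, motion blur, or partially
reflective surfaces. Passing tests therefore demonstrate the logic of the
pipeline under its stated geometric assumptions, not robustness to real
sensor artifacts.

## Numerical and degenerate-input conventions

Depth arithmetic is integer throughout (sliced values exceed 16-bit range
and are carried as int64 internally; raw I/O is uint16). Empty blobs,
zero-frame references, non-binary label inputs, wrong-stage frames and
malformed raw payloads raise `ValueError`/`KeyError` rather than
propagating garbage. All randomness (dropouts, noise, scenario seeds) flows
through explicit integer seeds.

## Known limitations

* A subject entering the scene already merged with furniture of similar
  height is not recognized until the silhouettes separate (inherent to the
  identification-on-unclassified-blobs rule).
* The fall height is read at the central point, so a body draped over
  furniture can hover above threshold even when most of it is on the floor.
* The reference frame is static; moved furniture becomes permanent
  foreground until recapture.
* Tracking assumes 30 fps; identity hand-off degrades if subjects move more
  than one blob diameter between frames.
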