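# Methods

## The measurement problem

A side-view chlorophyll-fluorescence image of a young maize plant is a bright
silhouette on a dark background.  The package recovers organ-level traits
from that silhouette alone: whole-plant height/width/area, the *segmented
stem* (soil line up to the node bearing the youngest fully expanded leaf, the
Leaf Collar convention), its diameter, the number of fully expanded leaves,
and per-leaf area and tip-to-stem angle.  The method is classical image
analysis — thresholding, morphology, skeleton topology, distance transforms —
chosen for determinism and auditability rather than learned models.

## Pipeline stages and the choices inside them

**Segmentation.**  Otsu's threshold on the full intensity histogram;
foreground is `intensity >= t` (pixels strictly below the threshold are
background).  Ties in the between-class variance go to the smallest
maximising threshold so the result is unique.  Cleanup is opening then
closing with a disk of radius `morph_radius_px` (default 2 px — opening first
removes speckle before closing fills pinholes), removal of components smaller
than `min_component_px` (default 64 px), then keep-largest-component under
the one-plant-per-image assumption.  A constant image raises a degenerate-
histogram error; an empty cleaned mask is reported as "no plant".

**Skeleton.**  `skeletonize(medial_axis(mask))` followed by removal of
redundant corner pixels (degree-2 pixels whose two neighbours are mutually
adjacent).  The medial axis is used instead of plain thinning because it
extends to within a few pixels of the shape's extremities; Zhang-style
thinning retracts the bottom endpoint by roughly half the stalk width, a
systematic stem-height bias of several percent on short stems.  The medial
axis tie-break order is explicitly seeded — it is randomised by default in
scikit-image, which would make the whole pipeline nondeterministic.  Spur
pruning iteratively removes terminal branches shorter than `spur_length_px`
(default 10 px), re-thinning after each round because pruning both prongs of
a tiny tip fork can leave a blunt three-pixel cycle with no endpoint.

**Landmarks.**  Endpoints are skeleton pixels of degree 1, branch points of
degree ≥ 3; adjacent branch pixels are clustered and represented by the
skeleton pixel nearest the cluster centroid.  The stem start is the endpoint
of maximal row whose column lies within `midline_tolerance_frac` (default 5%)
of the mask width from the half-area column — the column where the cumulative
column-wise mask area reaches 50%.  A tolerance is unavoidable on a discrete
grid; 5% keeps drooping leaf tips (which can lie *lower* than the stem base
but off the midline) classified as tips.  If no endpoint qualifies, the
lowest endpoint is used and the record flagged `stem_start_fallback` so batch
runs survive and flagged rows can be filtered downstream.

**Stem.**  The top node is the branch-point representative closest
(Euclidean; ties to smaller row, then column) to the skeleton's centre of
mass.  This works because in vegetative maize the whorl and the young upper
leaves concentrate skeletal mass near the top of the stalk.  The stem path
minimises the summed geodesic field `d(·, start) + d(·, top)` on the skeleton
graph; geodesic distance is unit-cost over 8-connected steps (chessboard
metric), so the path's step count equals the breadth-first-search distance
and the summed field is constant and globally minimal along it.  Backtracking
from the top node with a deterministic tie-break (smaller row, then column)
yields a simple path.  The radius profile is the Euclidean distance transform
of the plant mask sampled along the path, median-filtered with an 11-sample
window (junction bulges are localised; the window just has to span them), and
the representative radius is the median of the filtered profile — robust to
the leaf-junction bulges that a mean would absorb.  Stem height is reported
three ways because the field convention is ambiguous: straight-line
start→top distance (`stem_height_cm`, the primary figure), the vertical drop
(`vertical_stem_height_cm`) and the path arc length (`stem_path_length_cm`).
The stem mask is every plant pixel within the representative radius of the
path, restricted to the component containing the path.

**Leaves.**  Blobs are connected components of plant − stem with at least
`min_component_px` pixels; smaller fragments are discarded but their pixel
count is retained so that `|plant| = |stem| + |whorl| + Σ|blobs| +
|discarded|` holds exactly on every run (asserted in the tests).  The whorl —
the cluster of unexpanded leaves at the top — is the blob with the highest
centre of mass; with a single blob there are zero expanded leaves.  Remaining
blobs are ranked bottom-up by centre-of-mass row (rank 1 = lowest = oldest),
which equals phytomer order for non-drooping plants; the known failure mode
(a drooping young leaf ranked below an older one) is documented, not
corrected.  Leaf area is the blob pixel count times `cm_per_px²`.

**Leaf angle.**  The angle's vertex is the attachment: the stem-path pixel
nearest the blob.  The direction reference is the local upward stem
direction, fitted by principal axis (SVD — a column-on-row regression
degenerates on vertical stems) over path pixels 6–24 steps away from the
attachment *excluding* the junction-adjacent pixels: thinning bends the
skeleton toward the departing blade at a junction and including those pixels
tilts the reference by up to ~18°, far beyond the few-degree accuracy the
rest of the measurement supports.  A blob containing zero or multiple
skeleton tips is an occluded/merged leaf: it keeps its area but gets no angle
and carries the `occluded_or_merged` flag rather than a silently wrong value.

**Whole plant, orientation, mirroring.**  Height/width are inclusive
bounding-box extents (`max − min + 1` pixels); area is the mask pixel count.
Top-view orientation is the angle of the farthest foreground pixel pair,
folded into [0, 180); only convex-hull vertices are searched, which is exact
(the farthest pair of a point set is attained on its hull), with degenerate
masks handled by direct pairwise search.  Because maize is roughly
bilaterally symmetric, a side view and its left-right mirror are
interchangeable: the full pipeline is mirror-invariant to within
discretisation (≤1% on lengths and areas, ≤1° on angles), which is tested.

## Calibration

A single isotropic `cm_per_px` per camera converts pixels to physical units:
lengths scale linearly, areas quadratically.  Lens distortion or
distance-dependent scale is not modelled; if the imaging geometry needs a
nonlinear correction it must be applied upstream.

## The synthetic plant generator

The generator exists so that every stage is testable with *exact* truth.  It
renders, into a label image (0 background, 1 stem, 2… leaves in phytomer
order, 255 whorl):

- a vertical stalk, full width over the lower 60% and tapering to 80% width
  at the top node; the bottom 30 px taper to a point at the soil line so
  that the medial-axis skeleton terminates exactly at the stem base (a
  blunt base splits the axis into cap branches whose endpoint wanders by up
  to half the stalk width, which alone would dominate the stem-height error);
- expanded leaves as quadratic arcs leaving their attachment at a prescribed
  tip angle (the attachment→tip chord against the upward stem direction),
  alternating sides, width tapering linearly to a 5-px tip; older (lower)
  leaves droop (up to ~125°), younger ones stand upright (the youngest ≥66°),
  matching maize habit — and, not incidentally, making organ separation and
  top-node identification structurally well-posed;
- a whorl of near-vertical furled blades splaying from the top node plus two
  or three large "uncollared" leaf arcs on alternating sides: the partially
  expanded leaves that dominate the upper skeletal mass of a real young
  plant.  Keeping the whorl side-balanced keeps the skeleton centre of mass
  on the stalk axis, which the top-node rule depends on;
- sheath fillets (stem-labelled disks) at each attachment so the leaf/stalk
  wedge is not an acute crevice;
- intensities: foreground ~ N(200, 8), background ~ N(20, 5) on 8 bits
  (contrast ≥ 5 sd is enforced), optional Gaussian blur (default off).

The silhouette is regularised at render time to the fixpoint of
opening-then-closing with the default disk — the rendered plant *is* a
morphologically regular shape — so a correct segmentation of the noiseless
render reproduces the label foreground pixel-for-pixel, and plant
height/width/area recovery can be asserted exactly.  Crevice pixels filled by
this regularisation inherit the label of the nearest organ.  Ground truth is
then *measured on the label image* (areas are label pixel counts, tips are
the farthest labelled pixels, mid-stem diameter is the median per-row stem
width over the middle third of the stalk), so recovery tests measure
algorithm error, not rendering error.

`default_suite(n, seed)` cycles through tiers of 2, 3, 4, 5, 6 and 8
expanded leaves with jittered geometry (stem 300–490 px ≈ 15–25 cm at the
default 0.05 cm/px; stalk 1.3–1.7 cm wide; leaf areas ≈ 5–9 cm²) — a
desk-scale compression of the V4→V10 range.  Tiers up to 6 leaves carry a
non-overlapping-blade guarantee enforced by construction checks (pairwise
dilated disjointness of leaf labels, and one-blob-per-organ resolvability
after subtracting a nominal stem over a band of plausible radii) with
deterministic resampling of the jitter; the 8-leaf tier deliberately crosses
two same-side blades to exercise occlusion flagging.  Suite geometry was
fixed after verifying the structural properties on several independent
seeds; it is part of the study conditions, not a tuning knob.

**What the generator does not emulate** — and therefore what passing tests do
not show about real greenhouse images: pot/soil reflections and non-plant
bright objects (only a keep-largest rule guards against them), senescent
low-fluorescence tissue, torn or crossing leaves outside the one deliberate
overlap tier, tillers and multiple stems, reproductive-stage morphology
(ears shift the centre of mass and break the top-node rule), leaf rolling and
twist, and any lens or perspective distortion.

## Numerical conventions and degenerate inputs

Raster coordinates are (row, col), 0-based, row increasing downward; the
up-axis is −row.  Connectivity defaults to 8 everywhere.  All tie-breaks are
deterministic and documented (smallest Otsu threshold; smaller row then
column for top-node and path steps; smaller angle for equal farthest pairs;
smaller column for equal blob centres).  Degenerate cases: constant image →
error; empty mask → "no plant"; no branch point → no stem (plant-level traits
still reported); path shorter than the median window → unfiltered median with
a flag; single-pixel top view → orientation 0 with the pair/degenerate path.

## Known limitations

- On real images with a blunt occluded stalk base, the stem start sits on the
  skeleton a few pixels above the soil line, biasing stem height low by up to
  half the stalk width in pixels.  The medial-axis skeleton was chosen partly
  to keep this bias small, and the synthetic stalks end in a visible taper at
  the soil line precisely so that recovery tests measure the rest of the
  pipeline rather than this unavoidable base effect.
- Side-view diameter measures the stalk axis facing the camera; a real stalk
  is an elliptical cylinder, so diameter can be overestimated when the major
  axis faces the lens.  No elliptical correction is attempted.
- Leaf ranking by centre of mass mis-orders drooping young leaves; blobs with
  multiple tips are flagged, never split.
- One global threshold assumes uniformly fluorescing tissue; windowed
  thresholding for partially senescent plants is out of scope.
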