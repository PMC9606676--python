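# Methods

This note documents the models and numerical choices behind `plexcyto`:
what the synthetic generator emulates, how each stage works, which
parameters matter, and what the tests do and do not demonstrate about
real data.

## Coordinate and transform conventions

Pixels are 0-based and pixel-centered; `x` is the column index growing
rightward, `y` the row index growing downward.  A `RigidTransform`
`(θ, t)` rotates counter-clockwise (in the x/y sense above) about the
image center `((W−1)/2, (H−1)/2)` and then translates; it always maps
*moving-image* coordinates into *reference-image* coordinates, so
applying it to the moving image aligns it onto the reference.
`scale_of_definition` records the resolution the parameters refer to;
rescaling by `f` multiplies the translation by `f` and leaves the angle
unchanged.  Group operations (compose, invert, rescale) are exact to
1e−9 on parameters and are property-tested.

Stage coordinates are `stage = origin + signed (and possibly transposed)
pixel offset × pixel size`.  The axis signs and transposition are
explicit data (`AxisConvention`) because stage handedness is
vendor-specific; the default is stage x growing with image column and
stage y with image row.

## Synthetic tissue model

The generator is the package's study stand-in, with full ground truth.
Its components and defaults:

* **Geometry.** Nuclei are disks (radius uniform in 7–11 px at
  0.325 µm/px) with mild sinusoidal boundary irregularity (±6%/±5% on the
  2nd/3rd angular harmonic).  A configurable fraction of cells
  (`touching_fraction`, default 0.15) is placed as deliberately touching
  pairs (center distance `r₁+r₂−0.5` px, producing 8-connected masks);
  all other nuclei keep ≥4 px clearance.  Cell bodies are the
  nearest-nucleus partition clipped at 8 px beyond the nucleus — exactly
  the structure the segmentation contract (nucleus seed → bounded cell)
  needs to be testable.  Unsatisfiable densities raise a placement error
  after a bounded number of rejection-sampling attempts.
* **Markers.** Each marker channel has a positive fraction and bimodal
  lognormal intensities (e.g. KI67: 35% positive, medians 7000 vs 250
  counts, σ=0.3 on the log scale) rendered uniformly over its compartment
  (nucleus, cytoplasm, or whole cell).
* **Puncta.** Foci and RNA spots are 2D Gaussians (σ 1.2–1.4 px,
  amplitudes 2.5–9×10³ counts) clipped to their compartment.  Counts are
  Poisson per cell (means 2–7).  Objects keep a minimum separation
  (max(5 px, 3σ)) and foci sit ≥2 px inside the nuclear boundary: puncta
  are discrete diffraction-limited objects, and without a resolvable
  spacing "count per cell" is not a well-defined quantity at the
  rendering resolution.  A `diffuse_fraction` of cells (default 8% for
  γH2A.X) instead shows a compartment-wide elevation with zero foci — the
  phenotype that makes per-nucleus mean intensity decorrelate from focus
  count.  The elevation ramps down linearly over 3 px at the nuclear
  envelope, as an optically blurred boundary would; a hard step there is
  both unphysical and an adversarial fixture for any band-pass detector.
* **Noise.** Poisson photon statistics (gain 1.0) followed by Gaussian
  read noise (σ=8 counts) over a uniform autofluorescent background
  (150 counts), clipped and quantized to the camera's 16-bit scale.
  These levels emulate a cooled CMOS camera generically; no instrument is
  modeled.
* **Rounds, magnifications, stacks.**  A round's misplacement is stated
  as the transform registration must recover (round frame → scene frame)
  at the base pixel size and is rescaled automatically when rendering at
  other magnifications.  Z-stacks give every object a Gaussian axial
  profile (σ_z = 1.2 µm) around its per-object z; weights are normalized
  over the offset-0 plane grid so a single-plane stack equals the 2D
  render and a zero-noise sum projection conserves each object's flux.
  Per-round axial offsets are whole planes.  All rendering is
  bit-deterministic in (spec, seed, round, channel, plane).

What the generator does **not** emulate: optical PSFs and spectral
crosstalk, stain-stripping residuals, autofocus drift, illumination
falloff, tissue texture and autofluorescence structure.  Passing tests
therefore demonstrate algorithmic correctness under controlled,
moderately realistic conditions — not performance on real tissue.

## Registration

Estimation is coarse-to-fine over `downscale_factors` (default 0.25 then
1.0).  At the coarsest level an exhaustive 1° angle scan (range ±12°)
with per-angle phase-correlation translation seeds the refinement, so no
initial guess is required.  Each refinement iteration estimates the
residual translation by subpixel phase correlation (upsampling ×20) and
the rotation by bounded golden-section search on normalized
cross-correlation over the central ¾ of the frame; iteration stops at
Δθ < 0.01° and Δt < 0.1 px (max 50 iterations).  Whatever the coarsest
estimation scale, the result is re-expressed at full resolution —
translations scale with resolution, angles do not.  Near-constant images
raise an error instead of silently returning the identity.

Cross-magnification registration resamples the coarser image by the
metadata pixel-size ratio and then runs the same estimator; rigid-body
only — scale is metadata, never a fitted parameter.  Stacks are aligned
laterally on sum projections, then the integer plane offset is chosen by
exhaustive search of the mean plane-wise correlation (ties go to the
smallest offset scanned).

Measured on zero-noise scenes, ≥95% of random transforms (|θ| ≤ 10°,
‖t‖ ≤ 100 px) are recovered within 0.2° and 2 px (≥90% at default
noise); typical residuals are below 0.01° and 0.1 px.

## Mosaics

Tile grids cover a stage rectangle at spacing `fov × (1 − overlap)`
(default overlap 0.10); the grid is minimal for coverage, and the last
row/column may overhang the region.  Stitching places tiles at nominal
stage positions and blends overlaps with separable linear feathering
whose weights are normalized to sum to one — identical overlapping
content is conserved and non-overlap regions are reproduced bit-exactly.
Optional refinement measures pairwise translation offsets on the nominal
overlap strips by phase correlation and propagates them from the
top-left anchor tile along the grid (translation only; a mosaic has no
internal rotation).  Global bundle adjustment and flat-field correction
are out of scope.

## Segmentation

* **Nuclei:** Gaussian smoothing (σ=2 px) → global Otsu threshold
  (manual override available) → hole filling → Euclidean distance
  transform → local-maxima seeds (minimum separation 6 px, numbered in
  row-major order so masks are reproducible) → watershed on the inverted
  distance → area filter (60–2500 px).  Decomposition can be disabled,
  in which case touching clusters stay single components.
* **Cell bodies:** each nucleus grows into the boundary-positive
  territory (robust threshold at median + 5×MAD·1.4826 of the smoothed
  membrane/cytokeratin channel, so dim cells are kept) by nearest-nucleus
  proximity, clipped at a maximum radius (8 px) beyond the nucleus.  With
  a flat or absent boundary channel the same partition applies without
  the territory constraint.  An earlier gradient-watershed variant was
  abandoned: with a cytoplasm-filling marker the flat extracellular
  background lets a neighbor's flood bypass the intensity ridge at the
  true interface.
* **Puncta:** the local background is the upper envelope of a rolling
  median (window `4r+1`, default 17 px) and a grayscale opening (disk
  radius `r`, default 4 px); the first ignores clustered puncta, the
  second tracks sharp compartment edges, and their maximum also cancels
  uniformly bright nuclear-diffuse compartments.  The residue is
  thresholded at `k·σ` (k = 5) where σ is the global robust residue sigma
  scaled by the Poisson square-root law `√(local/background median)`.
  Touching detections are deblended by a watershed seeded at residue
  peaks ≥2 px apart (found on a lightly smoothed residue, σ=0.8 px);
  components are area-filtered (2–400 px) and optionally re-merged within
  a user distance.  Intensities are measured on the raw channel;
  ownership is the cell label at the spot's intensity-weighted centroid,
  and background centroids stay in the population as unassigned.

## Cytometry

Totals accumulate in 64-bit integers (no floating drift on 16-bit data);
the mean is total/area.  Circularity uses the perimeter of
`skimage.measure.regionprops` (weighted boundary-step estimator, diagonal
steps √2) and is capped at 1.0 because that estimator overshoots for
small round masks; the closed forms (circle = 1, square = π/4, n×1 bar =
4πn/(2n+2)²) are asserted in the tests.  The "image localization" of a
cell is its core id, round id, and bounding box.  Cross-round merging is
by centroid containment: a measurement belongs to the anchor cell whose
mask contains its transformed center — chosen over IoU matching for
speed and determinism — and anything landing on background is flagged
unmatched, never dropped.  When rounds have already been warped into the
anchor frame (as the pipeline does), the merge runs under identity
transforms.

## Gating and targeting

Gate membership is pure and row-order independent; rectangles default to
lower-inclusive / upper-exclusive bounds (per-edge override), polygons
include their boundary, and spot positivity is strictly `count >
threshold`, so a cell at exactly the threshold is negative.  Cross-tabs
report counts and row-conditional fractions.  TMA cores are dearrayed by
a triangle threshold on the map's total signal (robust for sparse bright
disks on dark background), morphological closing, and an
equivalent-diameter filter of 0.4–1.6× the expected core diameter
(default 1200 µm).  The focus surface is a least-squares plane
`z = ax + by + c` (≥3 non-collinear support points; exact for 3);
evaluation outside the support hull warns about extrapolation.  Position
lists are exported in µm, ordered row-major by stage y then x, as JSON
(canonical) and CSV.

## Pipeline

The config (single YAML) names every open default: round inputs and the
unique anchor round, registration factors, segmentation/spot parameters,
gates, output directory.  Validation runs before any computation and
checks paths, channel presence, and anchor uniqueness.  Stage failures
abort with a stage-named error and a manifest marking the run
incomplete; a completed run writes registered images, masks, the unified
database, gate outputs, position lists, and a JSON report with per-stage
durations, counts, and residuals.  Reruns on the same inputs are
byte-identical.

The demo builds a 140-cell, 512×512 px two-round scene (4x-like maps at
4× the base pixel size, a random misplacement of ≤2.5° and ≤20 px,
3D stacks with a known axial offset), runs the pipeline, and scores
relocation against ground truth, counting a prediction as correct within
2 high-resolution pixels (⅓ of a cell-resolution pixel each).  The test
suite uses 320–512 px fields with 40–140 cells — sizes chosen so the
full suite runs in about a minute while every statistical criterion
still has dozens to hundreds of events behind it.

## Known limitations

Rigid registration only (no affine or nonrigid residuals); segmentation
is classical and intensity-based, with no learned priors; stacks are
measured plane-wise or on projections (no 3D segmentation); the
synthetic scene's simplifications listed above.  The acceptance numbers
quantify behavior on the generator's conditions; on real slides the
same code paths apply but the error budgets will differ.
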