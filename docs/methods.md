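# Methods

## The screen being modeled

A TopoChip screen measures how designed surface microtopographies modulate
a per-cell marker (ICAM-1) in stromal cells.  One chip carries 2176 unique
topographies in duplicate plus 4 flat wells on a 66×66 grid of 300 µm
wells; a screen uses 8 chip replicas, so each unique surface contributes
16 replica wells.  Cells are segmented per well; each cell contributes
shape features and a median marker intensity.  The analysis classifies
every surface as marker-High, marker-Low, or non-significant, then asks
which design parameters and which cell-shape features predict the class.

## Topography designs and descriptors

Each design is a square *feature cell* of width w populated with geometric
primitives (circle, equilateral triangle, square), tiled periodically over
the active well area.  Defaults:

| parameter | default | rationale |
|---|---|---|
| active well side | 290 µm | 300 µm pitch minus 10 µm walls (wall width not published; configurable) |
| feature cell w | one of {10, 29, 58} µm | must divide 290 µm exactly; spans fine-dense to coarse-sparse patterns |
| primitive count k | uniform 1–16 | yields compound pillars from tens to hundreds of µm² |
| primitive size | uniform 3–30 µm (clipped to fit the cell) | same |
| raster resolution | 0.5 µm/cell (1.0 µm in the test suite) | ≤5% area error for the smallest primitive |

Primitive positions are uniform, constrained so the bounding circle stays
inside the feature cell at any rotation; overlapping primitives union into
compound pillars.  All draws are seeded; a catalog is a pure function of
(n, seed, parameter ranges).

Descriptors per design: pattern area = total foreground area / number of
4-connected components; space area = total background area / number of
components (its per-pillar counterpart; the total is recoverable from the
foreground fraction); foreground fraction; and the wave-number vector
WN_q, defined here as the fraction of non-DC spectral power of the binary
mask at radial spatial frequencies ≤ q × Nyquist, q ∈ {0.1, 0.25, 0.5}.
This definition is resolution-stable after normalization and captures both
structure density and size: a periodic tiling only has power at harmonics
of 1/w, so fine dense patterns (small w) carry no low-frequency power
while coarse patterns concentrate power there.  Over the exhaustive
partition (adding the spectrum corner up to √2 × Nyquist) the bin masses
sum to 1 for any non-flat design.

Design archetypes, used only to plant plausible effects in the synthetic
screen: *high_like* = pattern area 100–400 µm² at moderate density
(foreground fraction ≤ 0.25); *low_like* = pattern area < 100 µm² at high
density.  With the default generator ranges a 2176-design catalog contains
roughly 140 high_like and 340 low_like designs, comfortably above the 112
and 72 needed for planting.

## The synthetic screen

The generator emulates the statistical structure the analysis assumes; it
is first-class, tested code.

* **Counts.**  Cells per well ~ Poisson(λ); λ defaults to 9 = seeding
  density 10,000 cells/cm² × (300 µm)².  A screen at λ = 10 (per-well
  median 10) pools a median of ~160 cells per surface over its 16
  replicas.
* **Intensity.**  Per-cell median intensity is a two-component lognormal
  mixture: log-means 4.0 (negative) and 5.18 (positive), common σ_log 0.4,
  in arbitrary fluorescence units.  These were chosen so the control
  distributions intersect at the negative control's 93rd percentile
  (the crossing of equal-variance components lies at the log-midpoint
  4.59 = 4.0 + 1.476·0.4, and Φ(1.476) ≈ 0.93).  All four numbers are
  configuration, not constants.
* **Batch effects.**  Each chip multiplies all its intensities by a
  lognormal factor (σ = 0.15), which the per-chip adaptive threshold must
  absorb.
* **Effects.**  A cell is truly positive with probability 0.07 (an
  intrinsic positive subpopulation) plus a planted effect: +0.20 on 112
  high_like surfaces, −0.05 on 72 low_like surfaces, floored at 0.005.
* **Controls.**  Off-chip flat-polystyrene cultures: the negative
  (unstimulated) condition is modeled as the pure low component — basal
  cultures sit at the bottom of the intensity range, and the
  intersection-at-93rd-percentile geometry requires it — while the
  cytokine-stimulated positive control has positive weight 0.70 (the
  stimulated positive fraction is not published; configurable).  5000
  cells per condition are simulated by default (the control culture has
  chip-scale area, so this is conservative).
* **Shape.**  Shape features are drawn from class-conditional Gaussians on
  transformed scales (log area/perimeter/median radius, logit
  solidity/form factor, clipped eccentricity) with a shared correlation
  structure capped at |ρ| ≤ 0.7.  Only orderings are published, and the
  profiles respect them: flat-well cells are large and round (largest form
  factor); marker-negative cells on topographies are thinnest and most
  eccentric; positives are intermediate.
* **Actin.**  Per-cell actin intensity is an affine blend of the
  standardized marker intensity and independent noise, giving a sample
  Pearson correlation equal to the configured ρ = 0.5 regardless of the
  mixture shape.

One master seed drives everything; per-stage generators are derived by
hashing the stage name, so adding a stage never shifts another's stream.

What the generator does **not** emulate: raw micrographs and segmentation
errors (cells are never mis-segmented, so the QC stage removes only true
cells from distribution tails), spatial well–well correlations, migration
between wells, or proliferation differences.  Passing tests therefore
demonstrate that the pipeline machinery is correct and calibrated on data
satisfying its assumptions — not that real micrographs would yield the
published effect sizes.

## Screening statistics

* **QC.**  Per unique surface, pooled over all replicas on all chips, a
  cell is excluded iff its area **or** perimeter lies strictly outside
  [median − 1.5·IQR, median + 1.5·IQR]; boundary values are retained.
  The "1.5 quantiles from the median" rule is interpreted as
  median-centered IQR fences; both the multiplier and the statistic are
  configuration.  Surfaces with fewer than 4 cells pass unfiltered and
  are flagged.  Note a structural bias: when a biological subpopulation
  (here, marker-positive cells) has distinct morphology, median-centered
  fences exclude it preferentially (measured 17% vs 9% on the default
  generator).
* **Calibration.**  Gaussian KDEs are fit to the log intensities of both
  controls; the crossing of the two densities is located between the two
  density modes (sign flips from kernel noise in sparse tails are not
  population intersections), interpolated linearly, and returned as its
  percentile rank within the negative sample — 93 for the default
  mixture.  Degenerate inputs raise: disjoint supports ("no intersection
  in overlap"), identical samples ("no unique intersection"); a crossing
  above the 99th percentile warns.
* **Threshold.**  Per chip, the cutoff is the calibrated percentile
  (type-7, linear interpolation) of that chip's own post-QC intensity
  distribution; a cell is positive when strictly above it.  By
  construction every chip flags ≈ (100 − p)% of its cells, which is what
  makes the threshold robust to chip-level batch scaling.  A fixed-93
  shortcut and full recalibration are both selectable.
* **Hit calling.**  Per surface, pooled (positive, negative) counts are
  tested against flat polystyrene with a 2×2 Pearson chi-square (no
  continuity correction; pooled n ≈ 140 makes it immaterial), switching
  to Fisher's exact test whenever an expected count drops below 5.  The
  default reference is the off-chip negative control with positives at
  the calibrated percentile of its own distribution: a shared reference
  of only ~290 on-chip flat cells makes all 2176 tests fluctuate
  together (the null hit rate then varies by ±0.06 between screens) and
  halves planted-Low power, so the large off-chip control is the default
  and on-chip flats remain selectable.  Classes: High/Low at raw
  p < 0.05 with the matching direction, NS otherwise; BH-adjusted
  p-values are reported alongside and can optionally gate the classes.
  Surfaces are ranked by positive fraction, ties broken by unit id,
  zero-cell surfaces last (NS, p = 1).
* **Known limitation.**  With the default effect sizes, the planted-Low
  recovery sits near its detection limit: a −0.05 shift on a 0.07
  baseline with ~140 pooled cells gives two-proportion power ≈ 0.55
  under ideal cell classification, and the percentile threshold (which
  must place its cutoff inside the positive component) plus the QC bias
  above reduce the measured sensitivity to ≈ 0.4–0.55 depending on seed.
  High-surface recovery (+0.20) is essentially complete, with no
  direction flips.

## Random-forest protocol

Feature matrices join High/Low surfaces with either design descriptors or
per-surface medians of cell-shape features; NS surfaces are dropped,
zero-variance columns dropped with a warning, and columns standardized
over the included rows (the forest is scale-invariant; standardization
uses no labels, so it leaks nothing).  Per repeat: a stratified 75/25
split (stratification guards the 112/72 imbalance; no reweighting); the
forest's `max_features` is tuned by 10-fold CV on the training part; the
held-out accuracy and permutation importance on the held-out split are
recorded.  100 repeats are aggregated as mean ± sd, and the per-repeat
split seeds are stored so any report is exactly reproducible.  Permutation
importance was chosen because it is model-agnostic and comparable across
repeats.  The suite runs the protocol with 50-tree forests and a 2-point
tuning grid; both are configuration.

The "planted-class" benchmark classifies the 112 + 72 planted surfaces by
their planted class from design descriptors.  Because planting selects
surfaces by design archetype, the classes are nearly separable by
construction and accuracy approaches 1 — this validates the machinery,
not real-data difficulty.  Classifying the *called* hit table instead
(which contains false calls whose features are uninformative) yields
lower accuracies, as expected.

## Morphometrics

Features: area; perimeter; form factor 4πA/P²; solidity (region/convex
area); eccentricity from second central moments; median radius via exact
Euclidean distance transform.  Conventions: 8-connected foreground,
4-connected background; even pixel counts take the mean of the central
order statistics; µm units via the pixel size.

Perimeter estimation is the one genuinely estimator-dependent feature.
The raw weighted boundary-step count overshoots a digitized disk's
perimeter by ~4% (form factor 0.92), and the Crofton estimator undershoots
a square's by ~6%.  The implementation traces the outer boundary (Moore
neighborhood), applies Vossepoel–Smeulders step weights (0.980 per axis
step, 1.406 per diagonal, −0.091 per corner), and adds π for the
half-pixel outward offset of the closed boundary — exact for convex
shapes.  This keeps the form factor of disks at 1.00 ± 0.01 down to
radius 10, a square at 0.83, a 37°-rotated square at 0.78, and an 8:1
ellipse at 0.296 (analytic 0.294).  Holes are ignored (outer boundary
only); a single-pixel mask returns defined degenerate values (area one
pixel, median radius half a pixel) and is flagged.

## Numerical and I/O conventions

CSV: UTF-8, comma, header, dot decimal, floats re-read with round-trip
precision so write→read→write is byte-identical.  Layout: headerless TSV
grid + JSON sidecar; coordinates 0-based, row 0 at chip top.  Quantiles:
type-7 throughout (stated because small-sample percentiles depend on it).
Every output directory receives a provenance.json from which the run can
be reproduced bit-identically; the orchestrator skips the simulation
stage on reruns when its configuration hash matches.
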