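# Methods

This note documents the models, algorithms and numerical choices behind
`gridscreen`, and what the synthetic-data tests do and do not demonstrate
about real microscope data.

## Coordinate and intensity conventions

All modules share one convention: 0-based coordinates, `x` = column,
`y` = row, origin at the centre of the top-left pixel.  A target list
declares the image span as `[-0.5, w-0.5] × [-0.5, h-0.5]` (pixel-area
convention) when validating that centres are in bounds.  Intensities are
kept as stored — no normalisation at I/O time — because detectors have
different normalisation needs and the relative ice-thickness proxy must
read raw values.  MRC files are written as mode-2 float32 with the pixel
size encoded in the header cell; only 2D real modes are read, and stacks
are rejected rather than silently sliced.

## Square detection (classical stand-in)

The per-tile detector emulates the output contract of an ML square finder
without learning anything: it must find mesh squares of any brightness —
including "dry" (film-bright) squares, whose removal is a *selection*
decision, not a detection one — and report centroid, area, mean intensity
and a score in [0, 1].

Two-stage segmentation:

1. **Rough pass.**  The tile is min–max normalised and smoothed (Gaussian,
   σ = 2 px).  Grid bars dominate the tile area, so the median sits on the
   background; the noise level is estimated from the lower half of the
   intensity distribution (half-sample MAD).  Pixels above
   `background + max(4σ_bg, 0.02)` seed rough regions.  A global Otsu
   split is deliberately avoided: when square brightnesses span a wide
   range it separates dim from bright squares instead of squares from
   bars.
2. **Refinement.**  Each rough region is re-thresholded in its own padded
   window at the *half-maximum* level — the midpoint of background and the
   region's median smoothed intensity.  For a step edge, Gaussian blurring
   preserves the half-maximum contour position, so areas and centroids are
   recovered accurately despite the smoothing.  Morphological closing
   (disk radius 2) bridges thin crack lines so a cracked square stays one
   component.

The score is `extent × (0.3 + 0.7 × normalised brightness)`, clipped to
[0, 1] — a monotone proxy for "regular and bright".  Components smaller
than 100 px² or with extent < 0.4 are treated as noise.

## Seam merging

Atlas mosaics are acquired tile by tile with overlap, so a square on a
seam appears as partial squares in adjacent tiles.  Merging follows the
weighted-mean rules exactly: area = ΣA_i, centroid = ΣA_i·c_i / ΣA_i,
intensity = ΣA_i·I_i / ΣA_i, score = max s_i, source tiles = union.

Two choices are this package's own:

* **Match criterion.**  Two candidates merge iff they come from adjacent
  tiles, both touch the shared boundary band (width = `match_tolerance`,
  default 1% of the tile width) and their intervals projected along the
  boundary overlap.  Merge groups are connected components of this
  relation, so a square split across 3+ tiles merges once.  This restricts
  merging to genuine seam-split squares; the tolerance is exposed because
  mosaic misregistration widens the band a physical split can occupy.
* **Exclusive regions.**  The plain sum-of-areas rule double-counts the
  overlap strip when both tiles see the same pixels.  Each `TileTransform`
  can therefore carry `exclusive_bounds` — the Voronoi cell of the tile
  grid — and detection masks each tile to its exclusive region, making
  partial squares an exact partition.  With real, imperfectly registered
  mosaics this guarantee degrades gracefully into the tolerance above.

## Grouped selection

`equal_count` mode sorts by the group parameter and splits into N_g
contiguous groups of as-equal-as-possible size ("equally sized" read as
equal member count); `predefined_range` mode bins the area range into N_g
equal-width bins.  Quotas are ⌊N_s/N_g⌋ per group with the remainder going
one-per-group in order of each group's best score.  Ties (on boundary
values or scores) are broken by larger area, then lower centroid y, then
lower x — a total order without randomness.

When a group cannot fill its quota, equal-count mode redistributes the
deficit to the group with the best remaining candidate so the total still
reaches min(N_s, available).  Predefined-range mode does *not*
redistribute: its purpose is to protect under-represented area ranges on
unbalanced grids (e.g. mostly-dry grids), and refilling from populated
bins would reintroduce exactly that bias — an empty bin is skipped with a
warning and the total may fall below N_s.

## Hole lattice detection

The detector must work for either contrast polarity, for hole spacings of
tens to a hundred-plus pixels, and in the presence of empty holes,
contamination and border truncation — with no per-image parameters beyond
a generous nominal radius range.

For each candidate radius on a coarse geometric scan (6 steps over the
nominal range):

1. **Blobs.**  The image is standardised and correlated with a zero-mean,
   unit-norm disk.  Peaks of the response *magnitude* (polarity-agnostic)
   at least 1.5 radii apart, with quadratic subpixel refinement, give blob
   centres.  Blobs whose disk would cross the image border are excluded
   from fitting — truncated holes have asymmetric responses whose peaks
   bias inward.
2. **Basis.**  Difference vectors to each blob's four nearest neighbours
   cluster at ±v₁ and ±v₂; the two dominant non-collinear clusters,
   Lagrange-reduced to the shortest basis, seed the lattice.
3. **Fit.**  Origin and basis are refined by iteratively reweighted least
   squares (Cauchy weights, scale = max(2 px, 5% of spacing)) over the
   integer-indexed blob centres; reweighting rather than hard rejection
   keeps the fit anchored across the whole image.
4. **Feasibility and scoring.**  A radius incompatible with its own fitted
   spacing (r > 0.48·s) is rejected — an oversized kernel aliases onto the
   interstitial lattice, which has the same spacing but the wrong phase.
   Surviving fits are scored by the median absolute contrast between the
   disk of radius r and its surrounding annulus (1.35 r) at interior
   lattice points, × √(points explained).  This image-domain score
   penalises phase-shifted lattices (both regions mix hole and film), too
   small radii (annulus still inside the hole) and too large ones (disk
   diluted with film), for either polarity.

The winning lattice then gets a fine radius scan (same score, fixed
lattice) and a polish pass: every predicted interior lattice point is
snapped to its local response maximum and a weighted least-squares re-fit
uses all of them — many more constraints than the initial blob set, which
brings spacing errors to the ~0.1% level needed to place truncated border
holes correctly.  Candidates are emitted for every lattice point whose
disk (with a small margin for radius-estimate error) intersects the image;
points whose centre is outside the image carry no patch statistics.

A blank image, too few blobs, or no second lattice direction raise
`NoLatticeError`; the workflow treats that square as failed and moves on.

## Ice proxy, border filter, sampling, focus

* Relative ice thickness = mean intensity of the (2·h+1)² patch at the
  hole centre, h = 2 by default (a 5×5 patch), clipped at image edges.
  It is a *relative* proxy only — thicker ice scatters more and appears
  darker — with no absolute (nm) calibration.
* Exclusion border: keep holes with inside fraction ≥ 0.80 (boundary
  inclusive).  The 80% default mirrors the visual-analysis criterion used
  for quality accounting.
* Sampling: survivors sorted by the proxy (ties by centre y then x), split
  into N_h contiguous equal-count classes (`np.array_split`), one uniform
  seeded draw per non-empty class.  Class boundaries depend only on the
  data; the seed changes only within-class picks.
* Focus: midpoint of the two lattice points nearest the image centre;
  among ties, the pair whose midpoint is nearest the centre, then
  lexicographic (y, x).  For a full square lattice the two nearest points
  are always an adjacent pair (or a diagonal pair under a central 4-way
  tie, which is even farther from the holes), so the focus is ≥ half a
  spacing from every hole.  Fewer than two points, or a midpoint outside
  the image, raises `FocusPlacementError` and the workflow falls back to
  the image centre with a warning.
* The score filter before sampling exists but is off by default; the
  ice-thickness proxy is the primary selection variable.

## Autoscreen driver

The queue runs under a simulated clock: hardware steps (grid exchange 5
min by default, square acquisition, exposures) are no-op events with
configurable durations, preserving the state machine's shape without a
microscope — no wall-clock figure produced here is a claim about real
hardware.  Settings are recalled from an example-session JSON file
(export∘import is identity).  Per-square hole-sampling seeds derive from
SHA-256 of (session seed, grid id, square index), truncated below 2³¹, so
records are reproducible and squares are independent.  Every failure is
logged as an error event followed by a continuation event; a grid failure
never touches other grids' records; the completion message is emitted via
a pluggable notifier (stdout by default) even for an empty queue.
Quality accounting counts good/empty/contaminated/cracked labels and
displays percentage-good rounded half-up to one decimal.

## The synthetic generator

Both generators are pure functions of (spec, seed) with exact ground
truth recorded *from the rendered, noiseless image* — piecewise-constant
intensities plus additive Gaussian noise.  Defaults describe a plausible
screening scenario: 2×2 mosaics of 512² tiles with 10% overlap, 120 px
mesh pitch, square side jitter ±20%, 10% dry and 8% cracked squares;
400² hole images, holes at 0.24× the lattice spacing (a Quantifoil
R1.2/1.3-like ratio), 5% empty, 8% contaminated (a dark blob occluding
~50% of the hole, above the ~40% contamination rule so the label is
unambiguous), 2% cracked, noise σ = 0.03 on a 0–1 intensity scale.  The
atlas mesh phase is pinned to the first seam midline so multi-tile mosaics
always contain seam-straddling squares and the merge path is always
exercised.

What this does **not** model: contrast transfer, dose and detector
statistics, intensity gradients across tiles (a known failure mode for
per-tile normalisation in learned detectors), mosaic misregistration,
tilted or bent grids (the lattice is strictly planar and square), lacey
substrates, and any absolute ice-thickness scale.  Passing tests
demonstrate the *algorithms* — merge arithmetic, grouping, stratification,
lattice fitting, focus geometry, error recovery — under controlled
conditions, not detector robustness on arbitrary real micrographs.

## Problem sizes used in tests

The default suite runs in well under a minute of CPU: atlases are 2×2
tiles of 512² px (49 squares), lattice recovery is measured on 50 images
of 400² px spanning spacings 30–120 px and both polarities, merge
arithmetic on 1,000 random candidate sets, sampling on 500 random hole
sets, focus safety on 200 random lattices, and the unattended dry run on
a 3-grid queue with N_g = 4, N_s = 4, N_h = 5 — the configuration used
for multi-grid screening comparisons — including one deliberately
corrupted image.
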