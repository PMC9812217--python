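# gridscreen

Smart targeting and unattended multi-grid screening for single-particle
cryo-EM, as a standalone Python toolkit.

## The problem

Screening cryo-EM grids is the main consumer of microscope-operator time.
Before any high-resolution collection, each grid must be examined through
the multi-scale imaging (MSI) hierarchy — a grid **atlas** (a mosaic of
low-magnification tiles) to find mesh **squares**, square magnification to
find regions, **hole** magnification to find the foil holes, and exposure
magnification to judge the ice and the particles.  Done by hand, that is
hours per session; done by fixed template matching, it breaks whenever the
grid type, hole spacing or contrast polarity changes.

`gridscreen` implements the targeting and orchestration layer of an
automated screening system:

* **Square detection and seam merging.**  Squares are detected per atlas
  tile (a classical detector standing in for an ML square finder, honouring
  the same JSON results contract).  Partial squares cut by tile seams are
  merged: the merged area is the sum of partial areas *A_i*, the centroid
  the area-weighted centre of gravity Σ*A_i c_i* / Σ*A_i*, the mean
  intensity the area-weighted mean Σ*A_i I_i* / Σ*A_i*, and the merged
  score the maximum of the partial scores *s_i*.
* **Grouped square selection.**  Area-filtered squares are split into
  *N*<sub>g</sub> groups by a chosen parameter (area, mean intensity or
  score) and the top-scoring squares of each group are taken until
  *N*<sub>s</sub> squares are targeted — e.g. *N*<sub>g</sub> = 4,
  *N*<sub>s</sub> = 8 selects 2 squares per group.  With prior knowledge,
  *N*<sub>g</sub> = 1 plus a restricted area range collects only the best
  squares of the right size; a predefined-range mode bins by area instead
  of by count for grids where most squares are dry.
* **Hole lattice detection and stratified sampling.**  Foil holes form a
  regular square lattice.  A polarity-agnostic detector (matched disk
  filter + lattice fit) finds every hole whether holes are lighter or
  darker than the film, without per-grid parameters.  Holes cut off at the
  image border are removed by an exclusion border (default: at least 80%
  of the hole inside the image).  Relative ice thickness is proxied by the
  mean intensity of a small patch at each hole centre; survivors are
  sorted by this proxy into *N*<sub>h</sub> classes and one hole is drawn
  per class, so every image samples its full ice-thickness range.
* **Focus placement.**  The focus target goes halfway between the two
  lattice points nearest the image centre — on film, maximally far from
  any hole, with no parameters to tune.
* **Autoscreen.**  An unattended multi-grid driver runs the whole MSI
  hierarchy per grid from a queue, with settings recalled from an example
  session, per-stage error recovery (a bad image skips a square or grid,
  never the queue), session records and a completion notification.
* **Synthetic data.**  A generator renders atlas mosaics (squares of
  varying area/brightness, dry and cracked squares, seam-straddling
  squares) and hole images (both polarities, empty/contaminated/cracked
  holes, border truncation) with exact ground truth, so the entire
  pipeline is testable without a microscope.

## Worked example

```python
from gridscreen import *
from gridscreen.synthetic import AtlasSpec, HoleImageSpec, generate_atlas, generate_hole_image
from gridscreen.selection import SelectionConfig, group_and_select

# 2x2-tile synthetic atlas; detect per tile, then merge seam-split squares
tiles, transforms, truth = generate_atlas(AtlasSpec(seed=3))
candidates = [c for tile, tr in zip(tiles, transforms)
              for c in detect_squares(tile, tr)]
squares = merge_tile_squares(candidates, transforms)
print(f"{len(candidates)} per-tile candidates -> {len(squares)} squares "
      f"({sum(s.merged for s in squares)} merged across seams)")

chosen = group_and_select(squares, SelectionConfig(N_g=4, N_s=4, N_h=5))
for s in chosen:
    print(f"  square at ({s.centroid[0]:7.1f}, {s.centroid[1]:7.1f})  "
          f"area {s.area:7.0f} px^2  score {s.score:.2f}")

# a hole-magnification image for one square
image, _, _ = generate_hole_image(
    HoleImageSpec(lattice_spacing=50, lattice_angle=10, hole_radius=10, seed=7))
lattice, holes = detect_hole_lattice(image)
kept = apply_exclusion_border(holes, image.shape)
picks = sample_holes(kept, N_h=5, seed=1)
focus = place_focus(lattice, image.shape)
print(f"lattice spacing {lattice.spacing:.1f} px, {len(holes)} holes, "
      f"{len(kept)} after border filter")
print("sampled ice-thickness proxies:",
      [round(h.relative_ice_thickness, 3) for h in picks])
print(f"focus target at ({focus[0]:.1f}, {focus[1]:.1f})")
```

prints

```
64 per-tile candidates -> 49 squares (13 merged across seams)
  square at (  486.0,   486.0)  area    3237 px^2  score 0.93
  square at (  846.0,   846.0)  area    3709 px^2  score 0.94
  square at (  606.0,   366.0)  area    5029 px^2  score 0.94
  square at (  606.0,   246.0)  area    5917 px^2  score 0.94
lattice spacing 50.0 px, 73 holes, 62 after border filter
sampled ice-thickness proxies: [0.431, 0.635, 0.679, 0.731, 0.734]
focus target at (206.5, 195.5)
```

One square was chosen from each of the four area groups (note the spread
of areas); the hole detector recovered the 50 px lattice exactly; the five
sampled holes span the image's ice-thickness range from thin (bright,
0.734) to thick (dark, 0.431); and the focus target sits between holes,
25 px from the nearest lattice point.

The same stages are available as a CLI: `gridscreen simulate-atlas`,
`simulate-holes`, `find-squares`, `select-squares`, `find-holes`,
`select-holes` and `autoscreen` (see `gridscreen --help`).

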