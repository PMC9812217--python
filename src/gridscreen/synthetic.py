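"""Synthetic atlas tiles and hole-magnification images with exact ground truth.

Every downstream stage of the screening pipeline is testable without real
microscope data.  The generator emulates, with a deliberately simple
piecewise-constant intensity model plus additive Gaussian noise:

* **Atlas mosaics** — dark grid bars with brighter mesh squares of varying
  area and brightness; occasional "dry" squares (no ice, film-bright) and
  cracked squares (a dark fracture line); adjacent tiles overlap and share
  the partial squares that straddle their seam.  The mesh phase is chosen
  so that whenever the mosaic has more than one tile, at least one column
  (or row) of squares straddles a seam, guaranteeing the merge path is
  exercised.
* **Hole images** — a regular square lattice of circular holes in either
  contrast polarity (holes lighter than the film for thin ice, darker for
  thick ice), with per-hole intensity variation standing in for ice
  thickness, empty holes (brightest), contamination (a dark blob occluding
  about half the hole, above the ~40% rule used for quality accounting)
  and cracked holes, and holes cut off at the image borders.

All outputs are pure functions of (spec, seed); ground truth records every
square/hole with its exact rendered area, centroid and noiseless intensity.
"""

from __future__ import annotations

import math
from typing import Literal

import numpy as np
from pydantic import BaseModel, ConfigDict, model_validator

from .errors import ConfigurationError
from .holes import HoleCandidate, Lattice, disk_inside_fraction
from .image_io import ImageGrid
from .targets import Target, TargetList, TileTransform

__all__ = ["AtlasSpec", "HoleImageSpec", "generate_atlas", "generate_hole_image"]


class AtlasSpec(BaseModel):
    """Parameters of a synthetic grid-atlas mosaic."""

    model_config = ConfigDict(extra="forbid")

    n_tiles_x: int = 2
    n_tiles_y: int = 2
    tile_shape: tuple[int, int] = (512, 512)  # (rows, columns)
    overlap_fraction: float = 0.10
    mesh_pitch: float = 120.0  # px between square centres
    square_fill_fraction: float = 0.55  # square side / mesh pitch
    square_brightness_mean: float = 0.55
    square_brightness_sd: float = 0.12
    bar_intensity: float = 0.15
    dry_intensity: float = 0.90
    crack_intensity: float = 0.05
    crack_width: int = 2
    size_jitter: float = 0.20  # relative side-length jitter
    crack_prob: float = 0.08
    dry_prob: float = 0.10
    noise_sigma: float = 0.02
    seed: int = 0

    @model_validator(mode="after")
    def _feasible(self) -> "AtlasSpec":
        if self.n_tiles_x < 1 or self.n_tiles_y < 1:
            raise ConfigurationError("need at least one tile in each direction")
        if not (0.0 <= self.overlap_fraction < 0.5):
            raise ConfigurationError("overlap_fraction must be in [0, 0.5)")
        if self.mesh_pitch > min(self.tile_shape):
            raise ConfigurationError("mesh_pitch larger than the tile: no square fits")
        if not (0.0 < self.square_fill_fraction < 1.0):
            raise ConfigurationError("square_fill_fraction must be in (0, 1)")
        for p in (self.crack_prob, self.dry_prob):
            if not 0.0 <= p <= 1.0:
                raise ConfigurationError("defect probabilities must be in [0, 1]")
        return self


def generate_atlas(
    spec: AtlasSpec,
) -> tuple[list[ImageGrid], list[TileTransform], TargetList]:
    """Render an atlas mosaic; return (tiles, transforms, ground truth).

    The ground-truth :class:`~gridscreen.targets.TargetList` is at atlas
    level: each square appears once with its exact rendered area, centroid
    and noiseless mean intensity; ``extra`` carries the defect label, the
    owning source tiles and whether the square is split across a seam.
    """
    rng = np.random.default_rng(spec.seed)
    th, tw = spec.tile_shape
    stride_x = int(round(tw * (1.0 - spec.overlap_fraction)))
    stride_y = int(round(th * (1.0 - spec.overlap_fraction)))
    offsets = [
        (float(ix * stride_x), float(iy * stride_y))
        for iy in range(spec.n_tiles_y)
        for ix in range(spec.n_tiles_x)
    ]
    atlas_w = (spec.n_tiles_x - 1) * stride_x + tw
    atlas_h = (spec.n_tiles_y - 1) * stride_y + th

    # Voronoi boundaries between adjacent tiles (midline of the overlap strip)
    vx = [0.0] + [i * stride_x + (tw - stride_x) / 2 for i in range(1, spec.n_tiles_x)] + [float(atlas_w)]
    vy = [0.0] + [i * stride_y + (th - stride_y) / 2 for i in range(1, spec.n_tiles_y)] + [float(atlas_h)]

    # Mesh phase: put square centres on the first seam midline so that
    # multi-tile mosaics always contain seam-straddling squares.
    phase_x = (vx[1] % spec.mesh_pitch) if spec.n_tiles_x > 1 else spec.mesh_pitch / 2
    phase_y = (vy[1] % spec.mesh_pitch) if spec.n_tiles_y > 1 else spec.mesh_pitch / 2

    canvas = np.full((atlas_h, atlas_w), spec.bar_intensity, dtype=np.float64)
    base_side = spec.mesh_pitch * spec.square_fill_fraction
    targets: list[Target] = []

    n_cols = int(atlas_w // spec.mesh_pitch) + 2
    n_rows = int(atlas_h // spec.mesh_pitch) + 2
    for jj in range(n_rows):
        for ii in range(n_cols):
            cx = phase_x + ii * spec.mesh_pitch
            cy = phase_y + jj * spec.mesh_pitch
            side = base_side * rng.uniform(1 - spec.size_jitter, 1 + spec.size_jitter)
            x0, x1 = int(round(cx - side / 2)), int(round(cx + side / 2))
            y0, y1 = int(round(cy - side / 2)), int(round(cy + side / 2))
            dry = rng.uniform() < spec.dry_prob
            cracked = rng.uniform() < spec.crack_prob
            if dry:
                value = spec.dry_intensity
            else:
                value = float(
                    np.clip(
                        rng.normal(spec.square_brightness_mean, spec.square_brightness_sd),
                        spec.bar_intensity + 0.10,
                        spec.dry_intensity - 0.10,
                    )
                )
            crack_pos = rng.uniform()  # consumed regardless, keeps the stream aligned
            crack_vertical = rng.uniform() < 0.5
            if not (0 <= x0 and x1 <= atlas_w and 0 <= y0 and y1 <= atlas_h):
                continue  # only fully-in-atlas squares are rendered
            canvas[y0:y1, x0:x1] = value
            if cracked:
                if crack_vertical:
                    cx0 = x0 + int(crack_pos * max(1, (x1 - x0 - spec.crack_width)))
                    canvas[y0:y1, cx0:cx0 + spec.crack_width] = spec.crack_intensity
                else:
                    cy0 = y0 + int(crack_pos * max(1, (y1 - y0 - spec.crack_width)))
                    canvas[cy0:cy0 + spec.crack_width, x0:x1] = spec.crack_intensity

            block = canvas[y0:y1, x0:x1]
            area = float(block.size)
            centroid = ((x0 + x1 - 1) / 2.0, (y0 + y1 - 1) / 2.0)
            mean_intensity = float(block.mean())
            label = "dry" if dry else ("cracked" if cracked else "normal")
            source_tiles = _owning_tiles(x0, y0, x1, y1, vx, vy, spec.n_tiles_x)
            score = {"normal": 0.85, "cracked": 0.45, "dry": 0.25}[label] + float(
                rng.uniform(-0.05, 0.05)
            )
            targets.append(
                Target(
                    center=centroid,
                    score=float(np.clip(score, 0.0, 1.0)),
                    area=area,
                    mean_intensity=mean_intensity,
                    extra={
                        "label": label,
                        "source_tiles": source_tiles,
                        "split": len(source_tiles) > 1,
                        "bbox": [x0, y0, x1, y1],
                    },
                )
            )

    tiles: list[ImageGrid] = []
    transforms: list[TileTransform] = []
    for k, (ox, oy) in enumerate(offsets):
        ix, iy = k % spec.n_tiles_x, k // spec.n_tiles_x
        pix = canvas[int(oy):int(oy) + th, int(ox):int(ox) + tw].copy()
        pix += rng.normal(0.0, spec.noise_sigma, size=pix.shape)
        tiles.append(ImageGrid(pixels=pix))
        transforms.append(
            TileTransform(
                tile_id=f"tile_{iy}_{ix}",
                offset=(ox, oy),
                overlap_fraction=spec.overlap_fraction,
                tile_shape=(th, tw),
                exclusive_bounds=(vx[ix], vy[iy], vx[ix + 1], vy[iy + 1]),
            )
        )

    ground_truth = TargetList(
        magnification_level="atlas", image_shape=(atlas_h, atlas_w), targets=targets
    )
    return tiles, transforms, ground_truth


def _owning_tiles(
    x0: int, y0: int, x1: int, y1: int, vx: list[float], vy: list[float], n_tiles_x: int
) -> list[str]:
    """Tiles whose exclusive (Voronoi) region intersects the square."""
    owners = []
    for iy in range(len(vy) - 1):
        if min(y1, vy[iy + 1]) - max(y0, vy[iy]) <= 0:
            continue
        for ix in range(len(vx) - 1):
            if min(x1, vx[ix + 1]) - max(x0, vx[ix]) > 0:
                owners.append(f"tile_{iy}_{ix}")
    return owners


class HoleImageSpec(BaseModel):
    """Parameters of a synthetic hole-magnification image."""

    model_config = ConfigDict(extra="forbid")

    image_shape: tuple[int, int] = (400, 400)  # (rows, columns)
    lattice_spacing: float = 50.0  # px between hole centres
    lattice_angle: float = 0.0  # degrees
    hole_radius: float = 10.0  # px
    polarity: Literal["holes_lighter", "holes_darker"] = "holes_lighter"
    film_intensity: float = 0.50
    ice_contrast_mean: float = 0.18  # |hole - film| for iced holes
    ice_contrast_sd: float = 0.06
    empty_intensity: float = 0.95  # empty hole: no ice, brightest
    contamination_intensity: float = 0.08
    contamination_fraction: float = 0.5  # of the hole area occluded
    crack_intensity: float = 0.10
    empty_prob: float = 0.05
    contamination_prob: float = 0.08
    crack_prob: float = 0.02
    noise_sigma: float = 0.03
    border_truncation: bool = True
    seed: int = 0

    @model_validator(mode="after")
    def _feasible(self) -> "HoleImageSpec":
        if self.hole_radius >= self.lattice_spacing / 2:
            raise ConfigurationError("hole_radius must be < lattice_spacing / 2")
        if self.hole_radius < 2:
            raise ConfigurationError("hole_radius must be >= 2 px")
        for p in (self.empty_prob, self.contamination_prob, self.crack_prob):
            if not 0.0 <= p <= 1.0:
                raise ConfigurationError("defect probabilities must be in [0, 1]")
        return self


def generate_hole_image(
    spec: HoleImageSpec,
) -> tuple[ImageGrid, Lattice, list[HoleCandidate]]:
    """Render a hole-magnification image; return (image, lattice, ground truth).

    Ground truth lists every hole whose disk intersects the image —
    truncated border holes included — with its exact centre, inside-image
    fraction, noiseless central intensity and defect label.
    """
    rng = np.random.default_rng(spec.seed)
    h, w = spec.image_shape
    s = spec.lattice_spacing
    theta = math.radians(spec.lattice_angle)
    b1 = np.array([s * math.cos(theta), s * math.sin(theta)])
    b2 = np.array([-s * math.sin(theta), s * math.cos(theta)])
    basis = np.column_stack([b1, b2])
    center = np.array([(w - 1) / 2.0, (h - 1) / 2.0])
    origin = center + basis @ rng.uniform(-0.5, 0.5, size=2)

    r = spec.hole_radius
    corners = np.array([[-r, -r], [w + r, -r], [-r, h + r], [w + r, h + r]])
    ij = np.linalg.solve(basis, (corners - origin).T).T
    i0, j0 = np.floor(ij.min(axis=0)).astype(int) - 1
    i1, j1 = np.ceil(ij.max(axis=0)).astype(int) + 1

    img = np.full((h, w), spec.film_intensity, dtype=np.float64)
    yy, xx = np.mgrid[0:h, 0:w]
    sign = 1.0 if spec.polarity == "holes_lighter" else -1.0

    holes: list[HoleCandidate] = []
    lattice_pts: list[tuple[float, float]] = []
    # fixed iteration order keeps the RNG stream deterministic
    for i in range(i0, i1 + 1):
        for j in range(j0, j1 + 1):
            p = origin + basis @ np.array([i, j], dtype=float)
            x, y = float(p[0]), float(p[1])
            if not (-r <= x <= w - 1 + r and -r <= y <= h - 1 + r):
                continue
            frac = disk_inside_fraction((x, y), r, (h, w))
            if frac <= 0.0:
                continue
            fully_inside = frac >= 1.0
            if not spec.border_truncation and not fully_inside:
                continue

            u = rng.uniform()
            if u < spec.empty_prob:
                defect = "empty"
            elif u < spec.empty_prob + spec.contamination_prob:
                defect = "contaminated"
            elif u < spec.empty_prob + spec.contamination_prob + spec.crack_prob:
                defect = "cracked"
            else:
                defect = "good"
            contrast = float(np.clip(rng.normal(spec.ice_contrast_mean, spec.ice_contrast_sd),
                                     0.05, 0.45))
            value = spec.empty_intensity if defect == "empty" else (
                spec.film_intensity + sign * contrast
            )
            dist2 = (xx - x) ** 2 + (yy - y) ** 2
            disk = dist2 <= r * r
            img[disk] = value
            # consume defect-geometry draws unconditionally for stream stability
            blob_angle = rng.uniform(0, 2 * math.pi)
            blob_shift = rng.uniform(0, 1)
            if defect == "contaminated":
                rb = r * math.sqrt(spec.contamination_fraction)
                bx = x + blob_shift * (r - rb) * math.cos(blob_angle)
                by = y + blob_shift * (r - rb) * math.sin(blob_angle)
                blob = (xx - bx) ** 2 + (yy - by) ** 2 <= rb * rb
                img[blob & disk] = spec.contamination_intensity
            elif defect == "cracked":
                nx_, ny_ = math.cos(blob_angle), math.sin(blob_angle)
                band = np.abs((xx - x) * nx_ + (yy - y) * ny_) <= 1.0
                img[band & disk] = spec.crack_intensity

            if 0 <= x <= w - 1 and 0 <= y <= h - 1:
                lattice_pts.append((x, y))
                cx_, cy_ = int(round(x)), int(round(y))
                px0, px1 = max(0, cx_ - 2), min(w, cx_ + 3)
                py0, py1 = max(0, cy_ - 2), min(h, cy_ + 3)
                central = float(img[py0:py1, px0:px1].mean())
            else:
                central = float("nan")
            holes.append(
                HoleCandidate(
                    center=(x, y),
                    radius=r,
                    inside_fraction=frac,
                    relative_ice_thickness=central,
                    score=0.9 if defect == "good" else 0.4,
                    defect_label=defect,
                )
            )

    img += rng.normal(0.0, spec.noise_sigma, size=img.shape)
    lattice = Lattice(
        origin=(float(origin[0]), float(origin[1])),
        basis=((float(b1[0]), float(b1[1])), (float(b2[0]), float(b2[1]))),
        points_in_image=tuple(lattice_pts),
    )
    return ImageGrid(pixels=img), lattice, holes
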