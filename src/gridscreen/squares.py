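"""Mesh-square detection on atlas tiles and cross-tile merging.

An atlas of the whole grid is acquired as a mosaic of overlapping tiles, so
mesh squares that happen to lie on a seam are imaged as partial squares in
two (or more) adjacent tiles.  Detection runs per tile; a merging pass then
identifies partial squares on facing tile boundaries and fuses them:

* merged area       = sum of partial areas,
* merged centroid   = area-weighted centre of gravity,
* merged intensity  = area-weighted mean of partial mean intensities,
* merged score      = maximum of the partial scores,
* source tiles      = union of the partials' tiles.

The per-tile detector is a classical stand-in for an ML square finder and
honours the same output contract: candidates with centroid, area, mean
intensity and a score in [0, 1] that increases with square regularity and
brightness.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from skimage.filters import gaussian
from skimage.measure import label, regionprops
from skimage.morphology import closing, disk

from .image_io import ImageGrid
from .targets import TileTransform

__all__ = ["SquareCandidate", "detect_squares", "merge_tile_squares"]

#: Components smaller than this (px^2) are treated as noise by the detector.
MIN_SQUARE_AREA = 100.0


@dataclass(frozen=True)
class SquareCandidate:
    """A detected mesh square in atlas coordinates."""

    centroid: tuple[float, float]  # (x, y), atlas px
    area: float  # px^2
    mean_intensity: float
    score: float
    source_tiles: frozenset[str] = frozenset()
    merged: bool = False
    #: axis-aligned bounding box (x0, y0, x1, y1) in atlas coordinates, half-open
    bbox: tuple[float, float, float, float] | None = None
    #: indices into the input list of :func:`merge_tile_squares`, set by that function
    member_indices: tuple[int, ...] = field(default=(), compare=False)

    def __post_init__(self) -> None:
        if not (np.isfinite(self.area) and self.area > 0):
            raise ValueError("square candidate area must be positive and finite")
        if not np.isfinite(self.mean_intensity):
            raise ValueError("square candidate mean_intensity must be finite")


def detect_squares(
    tile: ImageGrid,
    transform: TileTransform,
    min_area: float = MIN_SQUARE_AREA,
) -> list[SquareCandidate]:
    """Detect mesh squares on one atlas tile, reported in atlas coordinates.

    Two-stage segmentation: a smoothed tile is thresholded just above the
    grid-bar background (bars dominate the tile area, so the median sits on
    the background; noise is estimated from the lower half of the intensity
    distribution) to find rough square regions of any brightness, then each
    region is re-segmented at the half-maximum level — the midpoint of
    background and square brightness — which recovers step-edge positions
    accurately despite the smoothing.  Thin cracks are bridged by
    morphological closing.  When ``transform.exclusive_bounds`` is set,
    detection is restricted to the tile's exclusive atlas region so
    seam-split squares partition exactly between adjacent tiles.  A blank
    (near-constant) tile yields an empty list.
    """
    img = np.asarray(tile.pixels, dtype=np.float64)
    h, w = img.shape
    lo, hi = float(img.min()), float(img.max())
    if hi - lo < 1e-12 or not np.isfinite(hi - lo):
        return []
    norm = (img - lo) / (hi - lo)
    sm = gaussian(norm, sigma=2, preserve_range=True)

    bg = float(np.median(sm))
    lower = bg - sm[sm <= bg]
    sigma_bg = float(np.median(lower)) / 0.6745 if lower.size else 0.0
    rough = sm > bg + max(4.0 * sigma_bg, 0.02)
    rough = closing(rough, disk(2))

    if transform.exclusive_bounds is not None:
        ex0, ey0, ex1, ey1 = transform.exclusive_bounds
        ox, oy = transform.offset
        cols = np.arange(w) + ox
        rows = np.arange(h) + oy
        keep = ((cols >= ex0) & (cols < ex1))[None, :] & ((rows >= ey0) & (rows < ey1))[:, None]
        rough &= keep
    else:
        keep = np.ones_like(rough)

    # refine each rough region at its own half-maximum level
    final = np.zeros_like(rough)
    pad = 4
    for region in regionprops(label(rough)):
        if region.area < 0.5 * min_area:
            continue
        r0, c0, r1, c1 = region.bbox
        r0, c0 = max(0, r0 - pad), max(0, c0 - pad)
        r1, c1 = min(h, r1 + pad), min(w, c1 + pad)
        window = sm[r0:r1, c0:c1]
        level = float(np.median(sm[tuple(region.coords.T)]))
        local = window > (bg + level) / 2.0
        local = closing(local, disk(2)) & keep[r0:r1, c0:c1]
        lab = label(local)
        # keep the component under the rough region's centroid (largest fallback)
        cy, cx = region.centroid
        iy, ix = int(round(cy)) - r0, int(round(cx)) - c0
        comp = lab[iy, ix] if (0 <= iy < lab.shape[0] and 0 <= ix < lab.shape[1]) else 0
        if comp == 0:
            sizes = np.bincount(lab.ravel())
            if len(sizes) < 2:
                continue
            comp = int(np.argmax(sizes[1:])) + 1
        final[r0:r1, c0:c1] |= lab == comp

    candidates: list[SquareCandidate] = []
    ox, oy = transform.offset
    for region in regionprops(label(final), intensity_image=img):
        if region.area < min_area:
            continue
        # regularity: fraction of the bounding box filled by the component
        if region.extent < 0.4:
            continue
        cy, cx = region.centroid
        brightness = (region.intensity_mean - lo) / (hi - lo)
        score = float(np.clip(region.extent * (0.3 + 0.7 * brightness), 0.0, 1.0))
        r0, c0, r1, c1 = region.bbox
        candidates.append(
            SquareCandidate(
                centroid=(cx + ox, cy + oy),
                area=float(region.area),
                mean_intensity=float(region.intensity_mean),
                score=score,
                source_tiles=frozenset({transform.tile_id}),
                merged=False,
                bbox=(c0 + ox, r0 + oy, c1 + ox, r1 + oy),
            )
        )
    return candidates


def _tile_boundaries(
    transforms: dict[str, TileTransform]
) -> dict[str, tuple[float, float, float, float]]:
    """Effective detection bounds per tile (exclusive bounds if set, else footprint)."""
    bounds = {}
    for tid, t in transforms.items():
        bounds[tid] = t.exclusive_bounds if t.exclusive_bounds is not None else t.footprint()
    return bounds


def _facing_edge(
    a: tuple[float, float, float, float],
    b: tuple[float, float, float, float],
    tol: float,
) -> tuple[int, float] | None:
    """If regions ``a`` and ``b`` share a facing boundary, return (axis, position).

    axis 0 means the shared boundary is a vertical line x=position (tiles are
    left/right neighbours); axis 1 a horizontal line y=position.
    """
    ax0, ay0, ax1, ay1 = a
    bx0, by0, bx1, by1 = b
    # left/right neighbours: a's right edge meets b's left edge (either order)
    if abs(ax1 - bx0) <= tol and min(ay1, by1) - max(ay0, by0) > 0:
        return (0, (ax1 + bx0) / 2)
    if abs(bx1 - ax0) <= tol and min(ay1, by1) - max(ay0, by0) > 0:
        return (0, (bx1 + ax0) / 2)
    if abs(ay1 - by0) <= tol and min(ax1, bx1) - max(ax0, bx0) > 0:
        return (1, (ay1 + by0) / 2)
    if abs(by1 - ay0) <= tol and min(ax1, bx1) - max(ax0, bx0) > 0:
        return (1, (by1 + ay0) / 2)
    return None


class _UnionFind:
    def __init__(self, n: int) -> None:
        self.parent = list(range(n))

    def find(self, i: int) -> int:
        while self.parent[i] != i:
            self.parent[i] = self.parent[self.parent[i]]
            i = self.parent[i]
        return i

    def union(self, i: int, j: int) -> None:
        ri, rj = self.find(i), self.find(j)
        if ri != rj:
            self.parent[rj] = ri


def merge_tile_squares(
    candidates: list[SquareCandidate],
    transforms: list[TileTransform],
    match_tolerance: float | None = None,
) -> list[SquareCandidate]:
    """Merge partial squares detected on facing boundaries of adjacent tiles.

    Two candidates from different tiles match when both touch the shared
    tile boundary (within a band of width ``match_tolerance``, default 1%
    of the tile width) and their intervals projected along that boundary
    overlap.  Merge groups are connected components of the match relation,
    so a square split across three or more tiles merges once.  Candidates
    with no partner pass through unchanged.  Every output candidate carries
    ``member_indices`` pointing back into the input list.
    """
    for c in candidates:
        if c.area <= 0:
            raise ValueError("candidate areas must be positive")
    tmap = {t.tile_id: t for t in transforms}
    if match_tolerance is None:
        widths = [t.tile_shape[1] for t in transforms if t.tile_shape is not None]
        match_tolerance = 0.01 * (min(widths) if widths else 512)
    bounds = _tile_boundaries(tmap)

    uf = _UnionFind(len(candidates))
    n = len(candidates)
    for i in range(n):
        ci = candidates[i]
        if ci.bbox is None:
            continue
        for j in range(i + 1, n):
            cj = candidates[j]
            if cj.bbox is None or ci.source_tiles & cj.source_tiles:
                continue
            if _pair_matches(ci, cj, bounds, match_tolerance):
                uf.union(i, j)

    groups: dict[int, list[int]] = {}
    for i in range(n):
        groups.setdefault(uf.find(i), []).append(i)

    out: list[SquareCandidate] = []
    for members in groups.values():
        if len(members) == 1:
            i = members[0]
            out.append(replace(candidates[i], member_indices=(i,)))
            continue
        parts = [candidates[i] for i in members]
        total = sum(p.area for p in parts)
        cx = sum(p.area * p.centroid[0] for p in parts) / total
        cy = sum(p.area * p.centroid[1] for p in parts) / total
        intensity = sum(p.area * p.mean_intensity for p in parts) / total
        score = max(p.score for p in parts)
        tiles = frozenset().union(*(p.source_tiles for p in parts))
        boxes = [p.bbox for p in parts if p.bbox is not None]
        bbox = (
            min(b[0] for b in boxes),
            min(b[1] for b in boxes),
            max(b[2] for b in boxes),
            max(b[3] for b in boxes),
        ) if boxes else None
        out.append(
            SquareCandidate(
                centroid=(cx, cy),
                area=total,
                mean_intensity=intensity,
                score=score,
                source_tiles=tiles,
                merged=len(tiles) > 1,
                bbox=bbox,
                member_indices=tuple(members),
            )
        )
    # deterministic output order: by first member index
    out.sort(key=lambda c: c.member_indices[0])
    return out


def _pair_matches(
    ci: SquareCandidate,
    cj: SquareCandidate,
    bounds: dict[str, tuple[float, float, float, float]],
    tol: float,
) -> bool:
    for ti in ci.source_tiles:
        for tj in cj.source_tiles:
            if ti not in bounds or tj not in bounds:
                continue
            edge = _facing_edge(bounds[ti], bounds[tj], 2 * tol)
            if edge is None:
                continue
            axis, pos = edge
            bi, bj = ci.bbox, cj.bbox
            # both bboxes must touch the boundary band from their own side
            if axis == 0:
                touch = (
                    min(abs(bi[2] - pos), abs(bi[0] - pos)) <= tol
                    and min(abs(bj[0] - pos), abs(bj[2] - pos)) <= tol
                )
                lo, hi = max(bi[1], bj[1]), min(bi[3], bj[3])
            else:
                touch = (
                    min(abs(bi[3] - pos), abs(bi[1] - pos)) <= tol
                    and min(abs(bj[1] - pos), abs(bj[3] - pos)) <= tol
                )
                lo, hi = max(bi[0], bj[0]), min(bi[2], bj[2])
            if touch and hi - lo > -tol:
                return True
    return False
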