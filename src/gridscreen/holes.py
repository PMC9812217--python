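"""Hole-lattice detection, ice-thickness stratified sampling and focus placement.

Holes in the foil film form a regular (near-square) lattice.  The detector
here is a classical, parameter-free stand-in for an ML hole finder with the
same contract: it must find the lattice regardless of contrast polarity
(thin ice makes holes lighter than the film, thick ice makes them darker),
tolerate contamination and empty holes, and report truncated border holes.

Relative ice thickness is proxied by the mean pixel intensity of a small
patch at the hole centre: thicker ice scatters more electrons and appears
darker.  Hole sampling stratifies the surviving holes into ``N_h`` classes
by this proxy and draws one hole per class, so each image samples the full
range of ice thicknesses it contains.

The focus target is placed halfway between the two lattice points nearest
the image centre — on film, maximally far from any hole — so that focusing
never doses an exposure area.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Literal, Optional, Sequence

import numpy as np
from scipy.signal import fftconvolve
from skimage.feature import peak_local_max

from .errors import FocusPlacementError, NoLatticeError
from .image_io import ImageGrid

__all__ = [
    "Lattice",
    "HoleCandidate",
    "detect_hole_lattice",
    "relative_ice_thickness",
    "apply_exclusion_border",
    "sample_holes",
    "place_focus",
    "disk_inside_fraction",
]

#: Default half-width of the centre patch used for the ice-thickness proxy
#: (2 -> a 5x5 pixel patch, the "small group of pixels" at the hole centre).
DEFAULT_PATCH_HALFWIDTH = 2

#: Default exclusion-border threshold: holes need >= 80% of their disk
#: inside the image to be considered targetable.
DEFAULT_MIN_INSIDE_FRACTION = 0.80


@dataclass(frozen=True)
class Lattice:
    """A regular 2D lattice: ``origin + i*basis[0] + j*basis[1]``."""

    origin: tuple[float, float]
    basis: tuple[tuple[float, float], tuple[float, float]]
    points_in_image: tuple[tuple[float, float], ...] = ()

    def __post_init__(self) -> None:
        b = np.asarray(self.basis, dtype=float)
        if abs(np.linalg.det(b)) < 1e-9:
            raise ValueError("lattice basis vectors must be linearly independent")

    @property
    def spacing(self) -> float:
        """Mean basis length (lattice constant for a square lattice)."""
        b = np.asarray(self.basis, dtype=float)
        return float((np.hypot(*b[0]) + np.hypot(*b[1])) / 2)


@dataclass(frozen=True)
class HoleCandidate:
    """A (possibly truncated) hole at one lattice point."""

    center: tuple[float, float]  # (x, y), px
    radius: float  # px
    inside_fraction: float  # disk area inside image / full disk area
    relative_ice_thickness: float  # intensity units (darker = thicker)
    score: float
    defect_label: Optional[Literal["good", "empty", "contaminated", "cracked"]] = None


def relative_ice_thickness(
    image: ImageGrid, hole: HoleCandidate, patch_halfwidth: int = DEFAULT_PATCH_HALFWIDTH
) -> float:
    """Mean intensity of the patch centred on the hole (the ice proxy).

    The patch is ``(2*patch_halfwidth + 1)**2`` pixels, clipped to the image
    bounds for holes near the edge.
    """
    h, w = image.shape
    cx, cy = int(round(hole.center[0])), int(round(hole.center[1]))
    if not (0 <= cx < w and 0 <= cy < h):
        raise ValueError("hole center must be inside the image")
    x0, x1 = max(0, cx - patch_halfwidth), min(w, cx + patch_halfwidth + 1)
    y0, y1 = max(0, cy - patch_halfwidth), min(h, cy + patch_halfwidth + 1)
    return float(np.mean(image.pixels[y0:y1, x0:x1]))


def disk_inside_fraction(
    center: tuple[float, float], radius: float, image_shape: tuple[int, int]
) -> float:
    """Fraction of a disk's pixel area that falls inside the image."""
    h, w = image_shape
    cx, cy = center
    r = int(math.ceil(radius))
    xs = np.arange(math.floor(cx) - r, math.floor(cx) + r + 2)
    ys = np.arange(math.floor(cy) - r, math.floor(cy) + r + 2)
    dx = xs[None, :] - cx
    dy = ys[:, None] - cy
    disk = dx * dx + dy * dy <= radius * radius
    total = int(disk.sum())
    if total == 0:
        return 0.0
    inside = disk & ((xs >= 0) & (xs < w))[None, :] & ((ys >= 0) & (ys < h))[:, None]
    return float(inside.sum() / total)


def apply_exclusion_border(
    holes: Sequence[HoleCandidate],
    image_shape: tuple[int, int],
    min_inside_fraction: float = DEFAULT_MIN_INSIDE_FRACTION,
) -> list[HoleCandidate]:
    """Drop holes cut off by the image border.

    Keeps exactly the holes with ``inside_fraction >= min_inside_fraction``
    (boundary inclusive).  ``image_shape`` is accepted for interface
    symmetry; the stored ``inside_fraction`` is authoritative.
    """
    if not 0.0 <= min_inside_fraction <= 1.0:
        raise ValueError("min_inside_fraction must be in [0, 1]")
    return [hole for hole in holes if hole.inside_fraction >= min_inside_fraction]


def sample_holes(
    holes: Sequence[HoleCandidate],
    N_h: int,
    filters: Optional[dict] = None,
    seed: int = 0,
) -> list[HoleCandidate]:
    """Stratified random sampling of ``N_h`` holes by relative ice thickness.

    Optional ``filters`` keys: ``ice_min``, ``ice_max`` (inclusive bounds on
    the intensity proxy) and ``score_min``.  Survivors are sorted by the
    proxy and split into ``N_h`` contiguous classes of as-equal-as-possible
    size; one hole is drawn uniformly (seeded) from each non-empty class.
    Returns ``min(N_h, survivors)`` holes, ordered thin to thick ice class;
    an empty list when nothing survives.
    """
    if N_h < 1:
        raise ValueError("N_h must be >= 1")
    filters = filters or {}
    survivors = list(holes)
    if (v := filters.get("ice_min")) is not None:
        survivors = [h for h in survivors if h.relative_ice_thickness >= v]
    if (v := filters.get("ice_max")) is not None:
        survivors = [h for h in survivors if h.relative_ice_thickness <= v]
    if (v := filters.get("score_min")) is not None:
        survivors = [h for h in survivors if h.score >= v]
    if not survivors:
        return []
    survivors.sort(key=lambda h: (h.relative_ice_thickness, h.center[1], h.center[0]))
    classes = [c for c in np.array_split(np.arange(len(survivors)), N_h) if len(c)]
    rng = np.random.default_rng(seed)
    return [survivors[int(rng.choice(c))] for c in classes]


def place_focus(lattice: Lattice, image_shape: tuple[int, int]) -> tuple[float, float]:
    """Midpoint of the two lattice points nearest the image centre.

    This is the parameter-free focus rule: for a full square lattice the
    returned point sits on film, at least half a lattice spacing away from
    every hole.  Ties on "the two nearest points" are broken by preferring
    the pair whose midpoint is nearest the image centre, then lexicographic
    (y, x) order.  Raises :class:`FocusPlacementError` when fewer than two
    lattice points are available or the midpoint falls outside the image.
    """
    pts = np.asarray(lattice.points_in_image, dtype=float)
    if pts.ndim != 2 or len(pts) < 2:
        raise FocusPlacementError("need at least two lattice points in the image")
    h, w = image_shape
    center = np.array([(w - 1) / 2.0, (h - 1) / 2.0])
    d = np.hypot(*(pts - center).T)
    order = np.lexsort((pts[:, 0], pts[:, 1], d))
    d_sorted = d[order]
    eps = 1e-6
    # tie-expanded sets of rank-1 and rank-2 distances
    tier1 = [i for i in order if d[i] <= d_sorted[0] + eps]
    if len(tier1) >= 2:
        pair_pool = [(i, j) for k, i in enumerate(tier1) for j in tier1[k + 1:]]
    else:
        d2 = min(d[i] for i in order if i != tier1[0])
        tier2 = [i for i in order if i != tier1[0] and d[i] <= d2 + eps]
        pair_pool = [(tier1[0], j) for j in tier2]

    def pair_key(pair: tuple[int, int]) -> tuple:
        i, j = pair
        mid = (pts[i] + pts[j]) / 2
        return (
            float(np.hypot(*(mid - center))),
            pts[i][1], pts[i][0], pts[j][1], pts[j][0],
        )

    i, j = min(pair_pool, key=pair_key)
    mid = (pts[i] + pts[j]) / 2
    if not (-0.5 <= mid[0] <= w - 0.5 and -0.5 <= mid[1] <= h - 0.5):
        raise FocusPlacementError("midpoint of nearest lattice points falls outside the image")
    return (float(mid[0]), float(mid[1]))


# ---------------------------------------------------------------------------
# lattice detection


def detect_hole_lattice(
    image: ImageGrid,
    nominal_radius_range: tuple[float, float] = (4.0, 40.0),
    patch_halfwidth: int = DEFAULT_PATCH_HALFWIDTH,
) -> tuple[Lattice, list[HoleCandidate]]:
    """Detect the hole lattice in a hole-magnification image.

    For each candidate hole radius (a small scan over
    ``nominal_radius_range``): (1) a zero-mean disk matched filter locates
    hole-like blobs in the response magnitude, so contrast polarity does
    not matter; (2) the two lattice vectors come from the dominant
    non-collinear clusters of nearest-neighbour difference vectors between
    blob centres, Lagrange-reduced to the shortest basis; (3) origin and
    basis are refined by least squares against the blob centres with
    outlier rejection.  The radius whose fitted lattice has the most
    coherent signed response at its points wins (an oversized kernel
    aliases onto the interstitial lattice, where the signed response
    cancels).  One candidate is emitted per lattice point whose disk
    intersects the image, including truncated border holes.

    Raises :class:`NoLatticeError` when no periodic structure is found.
    """
    img = np.asarray(image.pixels, dtype=np.float64)
    h, w = img.shape
    r_lo, r_hi = nominal_radius_range
    if min(h, w) < 4 * r_hi:
        r_hi = min(h, w) / 4.0
    if img.std() < 1e-12:
        raise NoLatticeError("blank image: no periodic structure")
    norm = (img - img.mean()) / img.std()

    radii = np.unique(np.clip(np.round(np.geomspace(max(2, min(r_lo, r_hi)),
                                                    max(2, r_hi), 6)), 2, None))
    best = None
    for r in radii:
        signed = _disk_response(norm, float(r))
        response = np.abs(signed)
        centers, strengths = _find_blobs(response, float(r))
        # truncated border holes give asymmetric responses whose peaks are
        # biased inward; fit the lattice on interior blobs only
        interior = (
            (centers[:, 0] >= r) & (centers[:, 0] <= w - 1 - r)
            & (centers[:, 1] >= r) & (centers[:, 1] <= h - 1 - r)
        ) if len(centers) else np.zeros(0, dtype=bool)
        if interior.sum() >= 4:
            centers, strengths = centers[interior], strengths[interior]
        if len(centers) < 4:
            continue
        try:
            v1, v2 = _basis_from_points(centers, strengths)
            v1, v2 = _gauss_reduce(v1, v2)
            origin, basis = _refine_lattice(centers, strengths, v1, v2)
            b1, b2 = _gauss_reduce(basis[:, 0], basis[:, 1])
            basis = np.column_stack([b1, b2])
        except (NoLatticeError, np.linalg.LinAlgError):
            continue
        # physical feasibility: holes cannot touch, so the kernel radius
        # must fit inside the fitted lattice cell (an oversized kernel
        # aliases onto the interstitial lattice with the same spacing)
        s_fit = min(np.hypot(*basis[:, 0]), np.hypot(*basis[:, 1]))
        if r > 0.48 * s_fit:
            continue
        score = _lattice_score(origin, basis, float(r), norm, (h, w))
        if score is not None and (best is None or score > best[0]):
            best = (score, float(r), origin, basis, s_fit)
    if best is None:
        raise NoLatticeError("no periodic hole structure found")
    _, radius, origin, basis, s_fit = best
    radius, response = _refine_radius(norm, origin, basis, radius, s_fit, (h, w))
    origin, basis = _polish_lattice(origin, basis, response, radius, (h, w))
    b1, b2 = _gauss_reduce(basis[:, 0], basis[:, 1])
    basis = np.column_stack([b1, b2])

    lattice_pts, candidates = _enumerate_lattice(
        origin, basis, radius, (h, w), image, response, patch_halfwidth
    )
    if len(lattice_pts) == 0:
        raise NoLatticeError("fitted lattice has no points inside the image")
    lattice = Lattice(
        origin=(float(origin[0]), float(origin[1])),
        basis=(
            (float(basis[0, 0]), float(basis[1, 0])),
            (float(basis[0, 1]), float(basis[1, 1])),
        ),
        points_in_image=tuple((float(p[0]), float(p[1])) for p in lattice_pts),
    )
    return lattice, candidates


def _basis_from_points(
    centers: np.ndarray, strengths: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Two dominant non-collinear lattice vectors from blob centres.

    Each interior lattice point's nearest neighbours sit at +-v1 and +-v2,
    so the difference vectors to the 4 nearest neighbours cluster at the
    basis vectors (sign-canonicalised).  Clusters are formed on a coarse
    grid and scored by membership, which makes the estimate robust to a
    minority of spurious blobs.
    """
    from scipy.spatial import cKDTree

    # strongest blobs only: spurious responses are weak
    if len(centers) > 120:
        keep = np.argsort(strengths)[::-1][:120]
        centers = centers[keep]
    k = min(5, len(centers))
    tree = cKDTree(centers)
    _, idx = tree.query(centers, k=k)
    diffs = []
    for i in range(len(centers)):
        for j in idx[i][1:]:
            d = centers[j] - centers[i]
            if d[0] < 0 or (d[0] == 0 and d[1] < 0):
                d = -d
            n = np.hypot(*d)
            if n >= 8.0:
                diffs.append(d)
    if not diffs:
        raise NoLatticeError("blob centres show no repeated offsets")
    diffs = np.asarray(diffs)
    bins: dict[tuple[int, int], list[int]] = {}
    for i, d in enumerate(diffs):
        bins.setdefault((int(round(d[0] / 4.0)), int(round(d[1] / 4.0))), []).append(i)
    ranked = sorted(bins.values(), key=len, reverse=True)

    def _mean_vec(members: list[int]) -> np.ndarray:
        seedv = diffs[members].mean(axis=0)
        close = diffs[np.hypot(*(diffs - seedv).T) < 4.0]
        return close.mean(axis=0) if len(close) else seedv

    v1 = None
    for members in ranked:
        v = _mean_vec(members)
        if np.hypot(*v) >= 8.0:
            v1 = v
            break
    if v1 is None:
        raise NoLatticeError("no dominant lattice vector found")
    n1 = np.hypot(*v1)
    for members in ranked:
        v = _mean_vec(members)
        n = np.hypot(*v)
        if n < 8.0 or not 0.5 * n1 <= n <= 2.0 * n1:
            continue
        sin = abs(v1[0] * v[1] - v1[1] * v[0]) / (n1 * n)
        if sin > 0.5:
            return v1, v
    raise NoLatticeError("only one lattice direction found")


def _disk_response(norm: np.ndarray, r: float) -> np.ndarray:
    """Signed correlation of the image with a unit-norm, zero-mean disk."""
    k = int(r) + 2
    yy, xx = np.mgrid[-k:k + 1, -k:k + 1]
    kern = (xx * xx + yy * yy <= r * r).astype(np.float64)
    kern -= kern.mean()
    kern /= np.linalg.norm(kern)
    return fftconvolve(norm, kern[::-1, ::-1], mode="same")


def _gauss_reduce(b1: np.ndarray, b2: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Lagrange-reduce a 2D lattice basis to its two shortest vectors."""
    b1, b2 = np.asarray(b1, float).copy(), np.asarray(b2, float).copy()
    if np.hypot(*b1) > np.hypot(*b2):
        b1, b2 = b2, b1
    for _ in range(32):
        m = round(float(b1 @ b2) / float(b1 @ b1))
        b2 = b2 - m * b1
        if np.hypot(*b2) >= np.hypot(*b1):
            break
        b1, b2 = b2, b1
    return b1, b2


def _lattice_score(
    origin: np.ndarray,
    basis: np.ndarray,
    radius: float,
    norm: np.ndarray,
    shape: tuple[int, int],
) -> float | None:
    """Quality of a fitted lattice for one candidate hole radius.

    Median absolute contrast between the disk of ``radius`` and its
    surrounding annulus at each interior lattice point, weighted by the
    square root of the number of points explained.  A lattice shifted off
    the holes mixes hole and film in both regions (contrast ~ 0), and a
    wrong radius either leaves the annulus inside the hole (too small) or
    dilutes the disk with film (too large) — so the same score drives both
    phase and radius selection, for either contrast polarity.
    """
    h, w = shape
    corners = np.array([[0, 0], [w, 0], [0, h], [w, h]], dtype=float)
    try:
        ij = np.linalg.solve(basis, (corners - origin).T).T
    except np.linalg.LinAlgError:
        return None
    i0, j0 = np.floor(ij.min(axis=0)).astype(int) - 1
    i1, j1 = np.ceil(ij.max(axis=0)).astype(int) + 1
    r_out = 1.35 * radius
    margin = int(math.ceil(r_out)) + 1
    pts = []
    for i in range(i0, i1 + 1):
        for j in range(j0, j1 + 1):
            x, y = origin + basis @ np.array([i, j], dtype=float)
            if margin <= x <= w - 1 - margin and margin <= y <= h - 1 - margin:
                pts.append((int(round(x)), int(round(y))))
    if len(pts) < 4:
        return None
    k = int(math.ceil(r_out))
    yy, xx = np.mgrid[-k:k + 1, -k:k + 1]
    d2 = xx * xx + yy * yy
    disk = d2 <= radius * radius
    annulus = (d2 > radius * radius) & (d2 <= r_out * r_out)
    px = np.array([p[0] for p in pts])
    py = np.array([p[1] for p in pts])
    dy, dx = np.nonzero(disk)
    ay, ax = np.nonzero(annulus)
    disk_means = norm[(py[:, None] + dy[None, :] - k), (px[:, None] + dx[None, :] - k)].mean(axis=1)
    ann_means = norm[(py[:, None] + ay[None, :] - k), (px[:, None] + ax[None, :] - k)].mean(axis=1)
    contrast = float(np.median(np.abs(disk_means - ann_means)))
    return contrast * math.sqrt(len(pts))


def _refine_radius(
    norm: np.ndarray,
    origin: np.ndarray,
    basis: np.ndarray,
    r0: float,
    s_fit: float,
    shape: tuple[int, int],
) -> tuple[float, np.ndarray]:
    """Fine radius scan around the winning coarse radius.

    The disk/annulus contrast at the (fixed) lattice points peaks when the
    radius matches the true hole radius; an accurate radius matters for
    the inside-image fraction of truncated border holes.
    """
    r_max = min(1.6 * r0, 0.48 * s_fit)
    candidates = np.unique(np.round(np.linspace(max(2.0, 0.6 * r0), max(2.0, r_max), 10)))
    best = None
    for r in candidates:
        score = _lattice_score(origin, basis, float(r), norm, shape)
        if score is not None and (best is None or score > best[0]):
            best = (score, float(r))
    radius = r0 if best is None else best[1]
    return radius, np.abs(_disk_response(norm, radius))


def _find_blobs(response: np.ndarray, radius: float) -> tuple[np.ndarray, np.ndarray]:
    # holes are at least ~2 radii apart (radius < spacing / 2)
    min_dist = max(3, int(1.5 * radius))
    peaks = peak_local_max(
        response, min_distance=min_dist, threshold_rel=0.15, exclude_border=False
    )
    strengths = response[peaks[:, 0], peaks[:, 1]]
    # quadratic subpixel refinement along each axis
    h, w = response.shape
    centers = []
    for py, px in peaks:
        x, y = float(px), float(py)
        if 0 < px < w - 1:
            denom = 2 * response[py, px] - response[py, px - 1] - response[py, px + 1]
            if denom > 1e-12:
                x += float((response[py, px + 1] - response[py, px - 1]) / (2 * denom))
        if 0 < py < h - 1:
            denom = 2 * response[py, px] - response[py - 1, px] - response[py + 1, px]
            if denom > 1e-12:
                y += float((response[py + 1, px] - response[py - 1, px]) / (2 * denom))
        centers.append((x, y))
    return np.asarray(centers, dtype=float).reshape(-1, 2), strengths


def _refine_lattice(
    centers: np.ndarray,
    strengths: np.ndarray,
    v1: np.ndarray,
    v2: np.ndarray,
) -> tuple[np.ndarray, np.ndarray]:
    """Least-squares fit of origin and basis to detected blob centres."""
    basis = np.column_stack([v1, v2]).astype(float)
    origin = centers[int(np.argmax(strengths))].copy()
    spacing = min(np.hypot(*v1), np.hypot(*v2))
    pts = centers
    weights = np.ones(len(pts))
    # IRLS with Cauchy weights: centres biased by contamination or cracks
    # inside individual holes are down-weighted, not hard-rejected, so the
    # fit stays anchored across the whole image
    c = max(2.0, 0.05 * spacing)
    for _ in range(5):
        idx = np.rint(np.linalg.solve(basis, (pts - origin).T)).T
        # design matrix for params (ox, oy, b00, b10, b01, b11)
        a = np.zeros((2 * len(pts), 6))
        a[0::2, 0] = 1
        a[1::2, 1] = 1
        a[0::2, 2] = idx[:, 0]
        a[1::2, 3] = idx[:, 0]
        a[0::2, 4] = idx[:, 1]
        a[1::2, 5] = idx[:, 1]
        sw = np.repeat(np.sqrt(weights), 2)
        params, *_ = np.linalg.lstsq(a * sw[:, None], pts.ravel() * sw, rcond=None)
        origin = params[:2]
        basis = np.array([[params[2], params[4]], [params[3], params[5]]])
        pred = origin + (basis @ idx.T).T
        resid = np.hypot(*(pred - pts).T)
        weights = 1.0 / (1.0 + (resid / c) ** 2)
    return origin, basis


def _polish_lattice(
    origin: np.ndarray,
    basis: np.ndarray,
    response: np.ndarray,
    radius: float,
    shape: tuple[int, int],
) -> tuple[np.ndarray, np.ndarray]:
    """Snap predicted lattice points to local response maxima and re-fit.

    Uses every interior hole in the image — many more constraints than the
    initial blob set — so basis errors shrink well below what border-hole
    matching tolerances require.
    """
    h, w = shape
    spacing = min(np.hypot(*basis[:, 0]), np.hypot(*basis[:, 1]))
    half = max(2, int(0.25 * spacing))
    for _ in range(2):
        corners = np.array([[0, 0], [w, 0], [0, h], [w, h]], dtype=float)
        ij = np.linalg.solve(basis, (corners - origin).T).T
        i0, j0 = np.floor(ij.min(axis=0)).astype(int) - 1
        i1, j1 = np.ceil(ij.max(axis=0)).astype(int) + 1
        matches, indices, weights = [], [], []
        for i in range(i0, i1 + 1):
            for j in range(j0, j1 + 1):
                x, y = origin + basis @ np.array([i, j], dtype=float)
                # interior points only: border responses are biased
                if not (radius + half <= x <= w - 1 - radius - half
                        and radius + half <= y <= h - 1 - radius - half):
                    continue
                cx, cy = int(round(x)), int(round(y))
                win = response[cy - half:cy + half + 1, cx - half:cx + half + 1]
                dy, dx = np.unravel_index(int(np.argmax(win)), win.shape)
                px, py = cx - half + dx, cy - half + dy
                sx, sy = float(px), float(py)
                if 0 < px < w - 1:
                    den = 2 * response[py, px] - response[py, px - 1] - response[py, px + 1]
                    if den > 1e-12:
                        sx += float((response[py, px + 1] - response[py, px - 1]) / (2 * den))
                if 0 < py < h - 1:
                    den = 2 * response[py, px] - response[py - 1, px] - response[py + 1, px]
                    if den > 1e-12:
                        sy += float((response[py + 1, px] - response[py - 1, px]) / (2 * den))
                matches.append((sx, sy))
                indices.append((i, j))
                weights.append(response[py, px])
        if len(matches) < 4:
            return origin, basis
        pts = np.asarray(matches)
        idx = np.asarray(indices, dtype=float)
        wts = np.asarray(weights)
        wts = wts / (wts.max() or 1.0)
        # one reweighting pass against the current prediction
        pred = origin + (basis @ idx.T).T
        resid = np.hypot(*(pred - pts).T)
        c = max(2.0, 0.05 * spacing)
        wts = wts / (1.0 + (resid / c) ** 2)
        a = np.zeros((2 * len(pts), 6))
        a[0::2, 0] = 1
        a[1::2, 1] = 1
        a[0::2, 2] = idx[:, 0]
        a[1::2, 3] = idx[:, 0]
        a[0::2, 4] = idx[:, 1]
        a[1::2, 5] = idx[:, 1]
        sw = np.repeat(np.sqrt(wts), 2)
        params, *_ = np.linalg.lstsq(a * sw[:, None], pts.ravel() * sw, rcond=None)
        origin = params[:2]
        basis = np.array([[params[2], params[4]], [params[3], params[5]]])
    return origin, basis


def _enumerate_lattice(
    origin: np.ndarray,
    basis: np.ndarray,
    radius: float,
    shape: tuple[int, int],
    image: ImageGrid,
    response: np.ndarray,
    patch_halfwidth: int,
) -> tuple[list[np.ndarray], list[HoleCandidate]]:
    h, w = shape
    # a small margin keeps grazing border holes despite radius-estimate error
    margin = 1.15 * radius + 2.0
    corners = np.array([[-margin, -margin], [w + margin, -margin],
                        [-margin, h + margin], [w + margin, h + margin]])
    ij = np.linalg.solve(basis, (corners - origin).T).T
    i0, j0 = np.floor(ij.min(axis=0)).astype(int) - 1
    i1, j1 = np.ceil(ij.max(axis=0)).astype(int) + 1
    resp_max = float(response.max()) or 1.0
    lattice_pts: list[np.ndarray] = []
    candidates: list[HoleCandidate] = []
    for i in range(i0, i1 + 1):
        for j in range(j0, j1 + 1):
            p = origin + basis @ np.array([i, j], dtype=float)
            x, y = p
            if not (-margin <= x <= w - 1 + margin and -margin <= y <= h - 1 + margin):
                continue
            frac = disk_inside_fraction((x, y), radius, shape)
            if frac <= 0.0 and disk_inside_fraction((x, y), margin, shape) <= 0.0:
                continue
            if 0 <= x <= w - 1 and 0 <= y <= h - 1:
                lattice_pts.append(p)
                ice = relative_ice_thickness(
                    image,
                    HoleCandidate(center=(x, y), radius=radius, inside_fraction=frac,
                                  relative_ice_thickness=0.0, score=0.0),
                    patch_halfwidth,
                )
                score = float(
                    np.clip(response[int(round(y)), int(round(x))] / resp_max, 0.0, 1.0)
                )
            else:
                # centre outside the image: no patch statistics available
                ice = float("nan")
                score = 0.0
            candidates.append(
                HoleCandidate(
                    center=(float(x), float(y)),
                    radius=float(radius),
                    inside_fraction=frac,
                    relative_ice_thickness=ice,
                    score=score,
                )
            )
    return lattice_pts, candidates
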