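"""Hole lattice detection, ice stratification and focus placement."""

import numpy as np
import pytest
from scipy.spatial import cKDTree

from gridscreen.errors import FocusPlacementError, NoLatticeError
from gridscreen.holes import (
    HoleCandidate,
    Lattice,
    apply_exclusion_border,
    detect_hole_lattice,
    place_focus,
    relative_ice_thickness,
    sample_holes,
)
from gridscreen.image_io import ImageGrid
from gridscreen.synthetic import HoleImageSpec, generate_hole_image


def _hole(center, ice, score=0.9, frac=1.0, radius=10.0):
    return HoleCandidate(
        center=center, radius=radius, inside_fraction=frac,
        relative_ice_thickness=ice, score=score,
    )


class TestDetectHoleLattice:
    def test_recovers_rotated_lattice(self, hole_bundle):
        spec, image, lattice_gt, holes_gt = hole_bundle
        lattice, candidates = detect_hole_lattice(image, nominal_radius_range=(4, 25))
        assert lattice.spacing == pytest.approx(spec.lattice_spacing, rel=0.02)
        gt = np.array([h.center for h in holes_gt])
        det = np.array([c.center for c in candidates])
        d, _ = cKDTree(det).query(gt)
        assert (d <= 5.0).mean() >= 0.95
        b1, b2 = np.asarray(lattice.basis)
        assert abs(np.hypot(*b1) - np.hypot(*b2)) <= 0.1 * np.hypot(*b1)

    def test_polarity_inversion_invariance(self, hole_bundle):
        """Detection on -I recovers the same lattice parameters within 1%."""
        _, image, _, _ = hole_bundle
        lat_pos, _ = detect_hole_lattice(image, nominal_radius_range=(4, 25))
        inverted = ImageGrid(pixels=-image.pixels)
        lat_neg, _ = detect_hole_lattice(inverted, nominal_radius_range=(4, 25))
        assert lat_neg.spacing == pytest.approx(lat_pos.spacing, rel=0.01)

    def test_blank_image_raises(self):
        with pytest.raises(NoLatticeError):
            detect_hole_lattice(ImageGrid(pixels=np.full((300, 300), 2.0)))

    def test_darker_polarity_image(self):
        spec = HoleImageSpec(lattice_spacing=60.0, lattice_angle=25.0,
                             hole_radius=14.0, polarity="holes_darker", seed=12)
        image, _, holes_gt = generate_hole_image(spec)
        lattice, candidates = detect_hole_lattice(image)
        assert lattice.spacing == pytest.approx(60.0, rel=0.02)
        gt = np.array([h.center for h in holes_gt])
        det = np.array([c.center for c in candidates])
        d, _ = cKDTree(det).query(gt)
        assert (d <= 5.0).mean() >= 0.95

    def test_truncated_border_holes_reported(self, hole_bundle):
        _, image, _, _ = hole_bundle
        _, candidates = detect_hole_lattice(image, nominal_radius_range=(4, 25))
        assert any(c.inside_fraction < 1.0 for c in candidates)


class TestRelativeIceThickness:
    def test_constant_field(self):
        image = ImageGrid(pixels=np.full((50, 50), 3.25))
        assert relative_ice_thickness(image, _hole((25.0, 25.0), 0.0)) == pytest.approx(3.25)

    def test_matches_brute_force_patch_mean(self, rng):
        image = ImageGrid(pixels=rng.random((60, 60)))
        hole = _hole((31.0, 17.0), 0.0)
        expected = image.pixels[15:20, 29:34].sum() / 25.0
        assert relative_ice_thickness(image, hole, patch_halfwidth=2) == pytest.approx(expected)

    def test_edge_clipping(self, rng):
        image = ImageGrid(pixels=rng.random((40, 40)))
        hole = _hole((1.0, 20.0), 0.0)  # 1 px from the left edge
        expected = image.pixels[18:23, 0:4].mean()
        assert relative_ice_thickness(image, hole, patch_halfwidth=2) == pytest.approx(expected)


class TestExclusionBorder:
    def test_thresholding_conventions(self):
        holes = [_hole((10, 10), 0.5, frac=1.0),
                 _hole((0, 10), 0.5, frac=0.70),
                 _hole((10, 0), 0.5, frac=0.80)]
        kept = apply_exclusion_border(holes, (40, 40), min_inside_fraction=0.80)
        assert holes[0] in kept          # fully inside: kept at any threshold
        assert holes[1] not in kept      # 0.70 < 0.80: removed
        assert holes[2] in kept          # boundary: >= convention keeps it

    def test_monotone_in_threshold(self, rng):
        holes = [_hole((i, i), 0.5, frac=float(f))
                 for i, f in enumerate(rng.random(30))]
        sizes = [len(apply_exclusion_border(holes, (40, 40), t))
                 for t in np.linspace(0, 1, 11)]
        assert sizes == sorted(sizes, reverse=True)


class TestSampleHoles:
    def test_one_per_class_brute_force(self):
        """10 distinct intensities, N_h=5: one hole from each pair class."""
        holes = [_hole((i, 0), float(i)) for i in range(10)]
        out = sample_holes(holes, N_h=5, seed=3)
        assert len(out) == 5
        classes = [holes[2 * k:2 * k + 2] for k in range(5)]  # sorted order = index
        for cls, pick in zip(classes, out):
            assert pick in cls

    def test_all_selected_when_classes_are_singletons(self):
        holes = [_hole((i, 0), float(i)) for i in range(4)]
        out = sample_holes(holes, N_h=9, seed=0)
        assert sorted(h.center for h in out) == [h.center for h in holes]

    def test_filter_then_stratify(self):
        """ice_max removing the 3 thickest of 10: classes built on the rest."""
        holes = [_hole((i, 0), float(i)) for i in range(10)]
        out = sample_holes(holes, N_h=7, filters={"ice_max": 6.5}, seed=1)
        survivors = holes[:7]
        assert len(out) == 7
        assert all(h in survivors for h in out)

    def test_no_survivors_empty(self):
        holes = [_hole((0, 0), 5.0)]
        assert sample_holes(holes, N_h=3, filters={"ice_min": 100.0}) == []

    def test_seeded_determinism_and_class_stability(self, rng):
        holes = [_hole((float(i), 0.0), float(v))
                 for i, v in enumerate(rng.random(23))]
        a = sample_holes(holes, N_h=5, seed=42)
        b = sample_holes(holes, N_h=5, seed=42)
        assert a == b
        c = sample_holes(holes, N_h=5, seed=43)
        # different seed: picks may change, class boundaries may not
        ordered = sorted(holes, key=lambda h: (h.relative_ice_thickness,
                                               h.center[1], h.center[0]))
        classes = [list(cls) for cls in np.array_split(np.arange(len(holes)), 5)]
        for k, (pa, pc) in enumerate(zip(a, c)):
            members = [ordered[i] for i in classes[k]]
            assert pa in members and pc in members


class TestPlaceFocus:
    def test_two_point_midpoint(self):
        lattice = Lattice(origin=(0, 0), basis=((0.0, 10.0), (10.0, 0.0)),
                          points_in_image=((0.0, 0.0), (0.0, 10.0)))
        # image of shape (9, 5): centre (2, 4)
        assert place_focus(lattice, (9, 5)) == pytest.approx((0.0, 5.0))

    def test_full_lattice_brute_force_distance(self):
        """400x400 image, spacing 50: focus is >= 25 px from every point."""
        spacing = 50.0
        pts = tuple(
            (x, y)
            for x in np.arange(5.0, 400, spacing)
            for y in np.arange(5.0, 400, spacing)
        )
        lattice = Lattice(origin=(5.0, 5.0),
                          basis=((spacing, 0.0), (0.0, spacing)),
                          points_in_image=pts)
        fx, fy = place_focus(lattice, (400, 400))
        dists = [np.hypot(fx - x, fy - y) for x, y in pts]
        assert min(dists) >= spacing / 2 - 1e-9

    def test_center_on_lattice_point_degenerate(self):
        """Image centre on a point: midpoint with its nearest neighbour,
        at half the spacing."""
        s = 20.0
        pts = tuple((x, y) for x in np.arange(10.0, 91, s) for y in np.arange(10.0, 91, s))
        lattice = Lattice(origin=(10.0, 10.0), basis=((s, 0.0), (0.0, s)),
                          points_in_image=pts)
        # shape (101, 101): centre (50, 50) is the middle lattice point
        fx, fy = place_focus(lattice, (101, 101))
        d = min(np.hypot(fx - x, fy - y) for x, y in pts)
        assert d == pytest.approx(s / 2)

    def test_too_few_points_raises(self):
        lattice = Lattice(origin=(0, 0), basis=((1.0, 0.0), (0.0, 1.0)),
                          points_in_image=((5.0, 5.0),))
        with pytest.raises(FocusPlacementError):
            place_focus(lattice, (10, 10))
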