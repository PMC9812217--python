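"""Square detection on tiles and the seam-merge arithmetic."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.spatial import cKDTree

from gridscreen.image_io import ImageGrid
from gridscreen.squares import SquareCandidate, detect_squares, merge_tile_squares
from gridscreen.synthetic import AtlasSpec, generate_atlas
from gridscreen.targets import TileTransform


def _identity_transform(tile_id="t0", shape=(512, 512)):
    return TileTransform(tile_id=tile_id, offset=(0.0, 0.0), tile_shape=shape)


class TestDetectSquares:
    def test_well_separated_squares_match_ground_truth(self):
        """Single clean tile: every ground-truth square is recovered with
        area within 5% and centroid within 3 px."""
        spec = AtlasSpec(n_tiles_x=1, n_tiles_y=1, mesh_pitch=160.0,
                         crack_prob=0.0, dry_prob=0.0, seed=17)
        tiles, transforms, gt = generate_atlas(spec)
        candidates = detect_squares(tiles[0], transforms[0])
        assert len(candidates) == len(gt.targets) == 9
        det = np.array([c.centroid for c in candidates])
        tree = cKDTree(det)
        for t in gt.targets:
            d, i = tree.query(t.center)
            assert d < 3.0
            assert candidates[i].area == pytest.approx(t.area, rel=0.05)
            assert candidates[i].mean_intensity == pytest.approx(t.mean_intensity, abs=0.05)
            assert 0.0 <= candidates[i].score <= 1.0

    def test_blank_tile_yields_nothing(self):
        tile = ImageGrid(pixels=np.full((256, 256), 3.0))
        assert detect_squares(tile, _identity_transform(shape=(256, 256))) == []

    def test_dry_square_still_detected(self):
        """Dry (film-bright) squares are returned with their high mean
        intensity — filtering is the selection stage's job."""
        spec = AtlasSpec(n_tiles_x=1, n_tiles_y=1, mesh_pitch=160.0,
                         crack_prob=0.0, dry_prob=1.0, seed=23)
        tiles, transforms, gt = generate_atlas(spec)
        candidates = detect_squares(tiles[0], transforms[0])
        assert len(candidates) == len(gt.targets)
        for c in candidates:
            assert c.mean_intensity == pytest.approx(spec.dry_intensity, abs=0.05)


def _partial(area, centroid, intensity, score, tile, bbox):
    return SquareCandidate(
        centroid=centroid, area=area, mean_intensity=intensity, score=score,
        source_tiles=frozenset({tile}), bbox=bbox,
    )


def _two_tile_transforms(boundary=25.0, width=50, height=30):
    """Two side-by-side tiles whose shared boundary is x=boundary."""
    return [
        TileTransform(tile_id="A", offset=(0.0, 0.0), tile_shape=(height, int(boundary))),
        TileTransform(tile_id="B", offset=(boundary, 0.0),
                      tile_shape=(height, int(width - boundary))),
    ]


class TestMergeTileSquares:
    def test_weighted_merge_arithmetic(self):
        """Area sums; centroid and intensity are area-weighted; score is max."""
        p1 = _partial(100.0, (10.0, 10.0), 10.0, 0.3, "A", (5.0, 5.0, 25.0, 15.0))
        p2 = _partial(200.0, (40.0, 10.0), 40.0, 0.8, "B", (25.0, 5.0, 55.0, 15.0))
        merged = merge_tile_squares([p1, p2], _two_tile_transforms(), match_tolerance=1.0)
        assert len(merged) == 1
        m = merged[0]
        assert m.area == pytest.approx(300.0)
        assert m.centroid == pytest.approx((30.0, 10.0))
        assert m.mean_intensity == pytest.approx(30.0)
        assert m.score == pytest.approx(0.8)
        assert m.source_tiles == frozenset({"A", "B"}) and m.merged

    def test_unmatched_candidate_passes_through(self):
        lone = _partial(100.0, (10.0, 10.0), 5.0, 0.4, "A", (5.0, 5.0, 15.0, 15.0))
        out = merge_tile_squares([lone], _two_tile_transforms(), match_tolerance=1.0)
        assert len(out) == 1
        assert out[0].area == lone.area and not out[0].merged

    def test_equal_partials_symmetry(self):
        a, b = 4.0, 10.0
        p1 = _partial(150.0, (20.0, 10.0), a, 0.5, "A", (15.0, 5.0, 25.0, 15.0))
        p2 = _partial(150.0, (30.0, 10.0), b, 0.5, "B", (25.0, 5.0, 35.0, 15.0))
        (m,) = merge_tile_squares([p1, p2], _two_tile_transforms(), match_tolerance=1.0)
        assert m.mean_intensity == pytest.approx((a + b) / 2)
        assert m.centroid == pytest.approx((25.0, 10.0))

    def test_nonpositive_area_rejected(self):
        with pytest.raises(ValueError):
            SquareCandidate(centroid=(0, 0), area=0.0, mean_intensity=1.0, score=0.5)

    @settings(deadline=None, max_examples=60)
    @given(data=st.data())
    def test_conservation_and_bounds_random_sets(self, data):
        """Total area is conserved; merged intensity lies within the member
        range and merged score is the member max — whatever merges."""
        n = data.draw(st.integers(1, 8))
        transforms = _two_tile_transforms()
        cands = []
        for i in range(n):
            tile = data.draw(st.sampled_from(["A", "B"]))
            area = data.draw(st.floats(1.0, 500.0))
            y0 = data.draw(st.floats(0.0, 25.0))
            touches = data.draw(st.booleans())
            if tile == "A":
                x1 = 25.0 if touches else data.draw(st.floats(5.0, 20.0))
                bbox = (0.0, y0, x1, y0 + 5.0)
            else:
                x0 = 25.0 if touches else data.draw(st.floats(30.0, 45.0))
                bbox = (x0, y0, 50.0, y0 + 5.0)
            cands.append(_partial(
                area, ((bbox[0] + bbox[2]) / 2, y0 + 2.5),
                data.draw(st.floats(0.0, 100.0)), data.draw(st.floats(0.0, 1.0)),
                tile, bbox,
            ))
        merged = merge_tile_squares(cands, transforms, match_tolerance=0.5)
        assert sum(m.area for m in merged) == pytest.approx(sum(c.area for c in cands))
        for m in merged:
            members = [cands[i] for i in m.member_indices]
            assert m.area == pytest.approx(sum(c.area for c in members))
            assert m.score == pytest.approx(max(c.score for c in members))
            lo = min(c.mean_intensity for c in members)
            hi = max(c.mean_intensity for c in members)
            assert lo - 1e-9 <= m.mean_intensity <= hi + 1e-9
            assert m.merged == (len(m.source_tiles) > 1)

    def test_idempotent(self, atlas_bundle):
        _, tiles, transforms, _ = atlas_bundle
        cands = []
        for tile, tr in zip(tiles, transforms):
            cands.extend(detect_squares(tile, tr))
        once = merge_tile_squares(cands, transforms)
        twice = merge_tile_squares(once, transforms)
        key = lambda c: (round(c.centroid[0], 6), round(c.centroid[1], 6))
        assert sorted(map(key, once)) == sorted(map(key, twice))
        assert sum(c.area for c in once) == pytest.approx(sum(c.area for c in twice))

    def test_generator_oracle_seam_merge(self):
        """On a 2x1 mosaic the merged candidates match atlas ground truth:
        area within 5%, centroid within 3 px, split squares merged once."""
        spec = AtlasSpec(n_tiles_x=2, n_tiles_y=1, seed=31)
        tiles, transforms, gt = generate_atlas(spec)
        cands = []
        for tile, tr in zip(tiles, transforms):
            cands.extend(detect_squares(tile, tr))
        merged = merge_tile_squares(cands, transforms)
        assert len(merged) == len(gt.targets)
        tree = cKDTree(np.array([c.centroid for c in merged]))
        for t in gt.targets:
            d, i = tree.query(t.center)
            assert d < 3.0
            assert merged[i].area == pytest.approx(t.area, rel=0.05)
            assert merged[i].merged == t.extra["split"]
            if t.extra["split"]:
                assert merged[i].source_tiles == frozenset(t.extra["source_tiles"])
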