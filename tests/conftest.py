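"""Shared fixtures: synthetic atlases and hole images with ground truth."""

import numpy as np
import pytest

from gridscreen.synthetic import AtlasSpec, HoleImageSpec, generate_atlas, generate_hole_image


@pytest.fixture(scope="session")
def atlas_bundle():
    """A 2x2-tile atlas with seam-straddling squares and exact ground truth."""
    spec = AtlasSpec(seed=3)
    tiles, transforms, ground_truth = generate_atlas(spec)
    return spec, tiles, transforms, ground_truth


@pytest.fixture(scope="session")
def hole_bundle():
    """A rotated hole image, lighter-than-film polarity."""
    spec = HoleImageSpec(lattice_spacing=50.0, lattice_angle=10.0, hole_radius=10.0, seed=7)
    image, lattice, holes = generate_hole_image(spec)
    return spec, image, lattice, holes


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
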