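import math

import numpy as np
import pytest

from hippoaxis.core import VoxelGrid
from hippoaxis.synthetic import (
    CohortConfig,
    arc_centerline,
    generate_cohort,
    generate_mask,
    straight_centerline,
)


@pytest.fixture(scope="session")
def straight_tube():
    """A straight 12-mm tube of radius 1.5 mm on the fine anisotropic grid."""
    # tube center deliberately off the slice-center/boundary special
    # alignments of the 0.5-mm grid (the generic placement)
    grid = VoxelGrid((110, 44, 30), (0.15, 0.15, 0.5))
    line = straight_centerline([2.0, 3.3, 7.4], [1.0, 0.0, 0.0], 12.0)
    mask, centerline = generate_mask(grid, line, 1.5)
    return {"grid": grid, "mask": mask, "centerline": centerline,
            "axis_y": 3.3, "axis_z": 7.4, "x0": 2.0, "length": 12.0,
            "radius": 1.5}


@pytest.fixture(scope="session")
def c_arc_tube():
    """A C-shaped 12-mm tube with tapering radius (cohort geometry)."""
    R = 12.0 / math.radians(150)
    grid = VoxelGrid((60, 90, 14), (0.15, 0.15, 0.5))
    center = np.array([2.5 - R * math.cos(math.radians(75)),
                       grid.extent[1] / 2, 2.5])
    line = arc_centerline(center, R, -75, 150, 2.0)
    radius_profile = lambda s: 0.8 + 0.05 * np.asarray(s)  # noqa: E731
    mask, centerline = generate_mask(grid, line, radius_profile)
    return {"grid": grid, "mask": mask, "centerline": centerline,
            "radius_profile": radius_profile, "length": 12.0}


@pytest.fixture(scope="session")
def tiny_cohort():
    """A small coarse-grid cohort for fast end-to-end checks."""
    cfg = CohortConfig(n_sham=6, n_tbi=12, seed=11,
                       voxel_dims=(0.30, 0.30, 0.50))
    records, labels = generate_cohort(cfg)
    return records, labels


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
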