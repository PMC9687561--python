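"""Skeletonize a curved mask and profile a parameter map along its axis.

Builds a C-shaped hippocampus-like tube, estimates its septotemporal
midline from the mask alone, projects every voxel to arc length, and
computes the Gaussian-weighted (FWHM 1.5 mm) mean/SD profile of a
synthetic T2 map carrying a +10 ms lesion between 2 and 5 mm from the
temporal end.
"""

import math

import numpy as np

from hippoaxis.axis import exclude_surface, project_voxels, skeletonize_mask, weighted_profile
from hippoaxis.core import VoxelGrid
from hippoaxis.synthetic import arc_centerline, generate_mask

grid = VoxelGrid((60, 90, 14), (0.15, 0.15, 0.5))
R = 12.0 / math.radians(150)
center = np.array([2.5 - R * math.cos(math.radians(75)), grid.extent[1] / 2, 2.5])
line = arc_centerline(center, R, -75, 150, z_rise=2.0)
mask, _ = generate_mask(grid, line, lambda s: 0.8 + 0.05 * np.asarray(s))

skel = skeletonize_mask(mask, grid)
print(f"estimated axis length: {skel.length:.2f} mm (true 12.00 mm)")

interior = exclude_surface(mask)           # drop the partial-volume shell
proj = project_voxels(interior, grid, skel)

rng = np.random.default_rng(3)
t2 = 55.0 + 10.0 * ((proj.s > 2.0) & (proj.s < 5.0)) + rng.normal(0, 2.0, proj.s.shape)
profile = weighted_profile(t2, proj, np.arange(0.0, 12.1, 1.0), fwhm=1.5)

for p, m, sd in zip(profile.positions, profile.wmean, profile.wsd):
    marker = " <- lesion window" if 2.0 <= p <= 5.0 else ""
    print(f"  s = {p:5.1f} mm   T2 = {m:5.1f} +- {sd:4.1f} ms{marker}")
# The weighted mean rises by ~10 ms inside the 2-5 mm window and decays
# over ~2 kernel widths outside it.
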