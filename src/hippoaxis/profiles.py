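"""Cohort-level profiling: from animal records to tidy profile tables.

Each animal/side/day mask is surface-eroded (partial-volume guard),
its axis obtained either by skeletonizing the mask or from the
generator's analytic centerline (``axis="true"``; exact and fast, used
for statistical calibration where the skeletonization step is not under
test), voxels are projected to arc length, and every parameter map is
reduced to weighted mean/SD profiles on a common position grid.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .axis import (
    AxisProfile,
    VoxelProjection,
    drop_caudal_slices,
    exclude_surface,
    mask_volume,
    project_voxels,
    skeletonize_mask,
    weighted_profile,
)
from .core import DTI_DAYS, DTI_PARAMS, RELAXOMETRY_DAYS, RELAXOMETRY_PARAMS, SIDES
from .synthetic import AnimalRecord


def profiles_to_frame(profiles: list[AxisProfile]) -> pd.DataFrame:
    """Tidy table: animal_id, side, day, parameter, position_mm, wmean, wsd, n_eff."""
    rows = []
    for pr in profiles:
        for p, m, s, ne in zip(pr.positions, pr.wmean, pr.wsd, pr.n_eff):
            rows.append((pr.animal_id, pr.side, pr.day, pr.parameter,
                         float(p), float(m), float(s), float(ne)))
    return pd.DataFrame(rows, columns=["animal_id", "side", "day", "parameter",
                                       "position_mm", "wmean", "wsd", "n_eff"])


def _animal_projection(rec: AnimalRecord, side: str, day: str, axis_mode: str,
                       erode: bool, caudal_drop: int):
    """Projection (s per usable voxel) plus the usable-voxel selector."""
    mask = rec.masks[(side, day)]
    work = drop_caudal_slices(mask, caudal_drop) if caudal_drop else mask
    if erode:
        work = exclude_surface(work)
    sel = work[mask]  # usable voxels, in stored-value order
    if axis_mode == "true":
        line = rec.centerlines[side]
        s, dist = line.project(rec.grid.voxel_centers(work))
        proj = VoxelProjection(s=s, distance=dist, length=line.length)
    elif axis_mode == "skeleton":
        skel = skeletonize_mask(mask, rec.grid)
        proj = project_voxels(work, rec.grid, skel)
    else:
        raise ValueError("axis_mode must be 'true' or 'skeleton'")
    return proj, sel


def cohort_profiles(
    records: list[AnimalRecord],
    positions: np.ndarray | None = None,
    fwhm: float = 1.5,
    spacing: float = 0.5,
    axis_mode: str = "true",
    erode: bool = True,
    caudal_drop: int = 0,
    parameters=None,
) -> pd.DataFrame:
    """Weighted mean/SD profiles of every map of every animal.

    The default position grid spans the nominal axis length at
    ``spacing`` mm so every animal is evaluated on identical positions.
    ``parameters`` restricts the profiled maps (default: all).
    """
    if positions is None:
        length = min(rec.centerlines[s].length for rec in records for s in SIDES)
        positions = np.arange(0.0, length + 1e-9, spacing)
    all_profiles: list[AxisProfile] = []
    for rec in records:
        for side in SIDES:
            for day in RELAXOMETRY_DAYS:
                params = list(RELAXOMETRY_PARAMS) + (
                    list(DTI_PARAMS) if day in DTI_DAYS else [])
                if parameters is not None:
                    params = [p for p in params if p in parameters]
                if not params:
                    continue
                proj, sel = _animal_projection(rec, side, day, axis_mode,
                                               erode, caudal_drop)
                for param in params:
                    vals = rec.values[(side, param, day)][sel]
                    all_profiles.append(weighted_profile(
                        vals, proj, positions, fwhm,
                        animal_id=rec.animal_id, parameter=param,
                        day=day, side=side))
    return profiles_to_frame(all_profiles)


def cohort_volumes(records: list[AnimalRecord]) -> pd.DataFrame:
    """Per-animal hippocampal volumes: columns vol_{side}_{day}, mm^3."""
    rows = {}
    for rec in records:
        rows[rec.animal_id] = {
            f"vol_{side}_{day}": mask_volume(rec.masks[(side, day)], rec.grid)
            for side in SIDES for day in RELAXOMETRY_DAYS
        }
    return pd.DataFrame.from_dict(rows, orient="index").rename_axis("animal_id")
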