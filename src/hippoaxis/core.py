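"""Core containers shared across the pipeline.

Quantitative maps live on anisotropic voxel grids (fine in-plane
resolution, thicker slices, as is typical for rodent multi-slice
acquisitions).  Voxels outside the tissue mask carry NaN as the
undefined-value marker; every consumer in the package treats NaN as
"no measurement here".
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: Days at which spin-echo / gradient-echo relaxometry is acquired.
RELAXOMETRY_DAYS = ("D2", "D7", "D21")
#: Days at which diffusion data is acquired (no diffusion scan at D2).
DTI_DAYS = ("D7", "D21")

RELAXOMETRY_PARAMS = ("T2", "T2star")
DTI_PARAMS = ("FA", "MD", "RD", "lambda1", "lambda2", "lambda3",
              "cl", "cp", "cs")

SIDES = ("ipsi", "contra")

#: Canonical (parameter, day) acquisition design: relaxometry on all
#: three days, tensor scalars only on D7/D21.  24 parameter-days in all.
PARAMETER_DAYS = tuple(
    [(p, d) for p in RELAXOMETRY_PARAMS for d in RELAXOMETRY_DAYS]
    + [(p, d) for p in DTI_PARAMS for d in DTI_DAYS]
)


@dataclass(frozen=True)
class VoxelGrid:
    """A 3D voxel lattice with physical voxel dimensions in mm."""

    shape: tuple[int, int, int]
    voxel_dims: tuple[float, float, float] = (0.15, 0.15, 0.50)

    def __post_init__(self) -> None:
        if len(self.shape) != 3 or any(int(s) < 1 for s in self.shape):
            raise ValueError(f"grid shape must be three counts >= 1, got {self.shape}")
        if len(self.voxel_dims) != 3 or any(d <= 0 for d in self.voxel_dims):
            raise ValueError(f"voxel dims must be positive, got {self.voxel_dims}")
        object.__setattr__(self, "shape", tuple(int(s) for s in self.shape))
        object.__setattr__(self, "voxel_dims", tuple(float(d) for d in self.voxel_dims))

    @property
    def voxel_volume(self) -> float:
        """Volume of one voxel in mm^3."""
        return float(np.prod(self.voxel_dims))

    @property
    def extent(self) -> np.ndarray:
        """Physical size of the grid in mm along each axis."""
        return np.asarray(self.shape) * np.asarray(self.voxel_dims)

    def voxel_centers(self, mask: np.ndarray | None = None) -> np.ndarray:
        """Physical coordinates (mm) of voxel centers, (N, 3).

        With a mask, only in-mask voxel centers are returned, in C order.
        """
        if mask is None:
            idx = np.indices(self.shape).reshape(3, -1).T
        else:
            self.check_mask(mask)
            idx = np.argwhere(mask)
        return (idx + 0.5) * np.asarray(self.voxel_dims)

    def check_mask(self, mask: np.ndarray) -> np.ndarray:
        mask = np.asarray(mask)
        if mask.shape != self.shape:
            raise ValueError(f"mask shape {mask.shape} does not match grid {self.shape}")
        return mask.astype(bool)


@dataclass
class ParameterMap:
    """One scalar quantitative map (e.g. T2 at D7) on a voxel grid.

    ``data`` is NaN outside the mask.  Relaxation times are in ms,
    diffusivities in mm^2/s, FA and the Westin shape measures are
    dimensionless.
    """

    data: np.ndarray
    grid: VoxelGrid
    parameter: str
    units: str = ""
    day: str | None = None
    side: str | None = None
    flags: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.shape != self.grid.shape:
            raise ValueError(
                f"map shape {self.data.shape} does not match grid {self.grid.shape}")

    @property
    def mask(self) -> np.ndarray:
        """Boolean mask of defined voxels."""
        return np.isfinite(self.data)

    def values_in(self, mask: np.ndarray) -> np.ndarray:
        """Values at in-mask voxels, C order (matches ``voxel_centers``)."""
        return self.data[self.grid.check_mask(mask)]


def spawn_rngs(seed: int, n: int) -> list[np.random.Generator]:
    """Split one master seed into ``n`` independent generators."""
    return [np.random.default_rng(s) for s in np.random.SeedSequence(seed).spawn(n)]
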