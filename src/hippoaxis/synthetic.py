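"""Synthetic rat-brain cohort generator.

Builds complete cohorts — curved hippocampus-like masks on anisotropic
voxel grids, per-day quantitative parameter maps with group-dependent
effects localized along the septotemporal axis, raw multi-echo and
diffusion-weighted signals, and outcome labels (sham/TBI, epilepsy,
cognitive impairment) — so the downstream profiling and modelling
stages can be exercised and calibrated without any animal data.

The geometry is a C-shaped circular arc with a tapering tube radius;
the generator returns the analytic centerline of every mask, which the
tests use as an oracle for skeletonization and arc-length projection.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .core import (
    DTI_DAYS,
    DTI_PARAMS,
    RELAXOMETRY_DAYS,
    RELAXOMETRY_PARAMS,
    SIDES,
    ParameterMap,
    VoxelGrid,
)

# --------------------------------------------------------------------------
# Centerlines and masks
# --------------------------------------------------------------------------


class Centerline:
    """A space curve densely sampled at fixed arc-length steps.

    Provides exact arc-length parameterization and nearest-point
    projection; used both to carve tube masks and as the ground-truth
    axis against which skeleton estimates are checked.
    """

    def __init__(self, points: np.ndarray):
        points = np.asarray(points, dtype=float)
        if points.ndim != 2 or points.shape[1] != 3 or len(points) < 2:
            raise ValueError("centerline needs at least two 3D points")
        self.points = points
        seg = np.linalg.norm(np.diff(points, axis=0), axis=1)
        self.arclength = np.concatenate([[0.0], np.cumsum(seg)])
        self._tree: cKDTree | None = None

    @property
    def length(self) -> float:
        return float(self.arclength[-1])

    def point_at(self, s: np.ndarray | float) -> np.ndarray:
        """Interpolate curve coordinates at arc length ``s`` (mm)."""
        s = np.atleast_1d(np.asarray(s, dtype=float))
        out = np.stack(
            [np.interp(s, self.arclength, self.points[:, k]) for k in range(3)],
            axis=-1,
        )
        return out

    def project(self, coords: np.ndarray, return_index: bool = False):
        """Nearest arc-length position and distance for each point.

        Nearest-sample search on the dense polyline; with the default
        sampling step (0.01 mm) the positional error is below the step.
        Ties inherent to nearest-neighbour search resolve toward the
        first (smaller-s) sample.
        """
        if self._tree is None:
            self._tree = cKDTree(self.points)
        dist, idx = self._tree.query(np.atleast_2d(coords))
        if return_index:
            return self.arclength[idx], dist, idx
        return self.arclength[idx], dist

    def tangent_at_ends(self) -> tuple[np.ndarray, np.ndarray]:
        """Unit tangents pointing outward at the two curve ends."""
        t0 = self.points[0] - self.points[1]
        t1 = self.points[-1] - self.points[-2]
        return t0 / np.linalg.norm(t0), t1 / np.linalg.norm(t1)


def _resample(points: np.ndarray, step: float) -> np.ndarray:
    """Resample a polyline at a uniform arc-length step."""
    seg = np.linalg.norm(np.diff(points, axis=0), axis=1)
    s = np.concatenate([[0.0], np.cumsum(seg)])
    grid = np.arange(0.0, s[-1] + step / 2, step)
    return np.stack([np.interp(grid, s, points[:, k]) for k in range(3)], axis=-1)


def straight_centerline(start, direction, length: float, step: float = 0.01) -> Centerline:
    """A straight-tube axis from ``start`` along ``direction``."""
    start = np.asarray(start, dtype=float)
    d = np.asarray(direction, dtype=float)
    d = d / np.linalg.norm(d)
    s = np.arange(0.0, length + step / 2, step)
    return Centerline(start[None, :] + s[:, None] * d[None, :])


def arc_centerline(
    center,
    radius: float,
    angle_start_deg: float,
    angle_span_deg: float,
    z_rise: float = 0.0,
    step: float = 0.01,
) -> Centerline:
    """A C-shaped circular arc in the x-y plane with a linear z drift.

    The curve starts (arc length 0, the temporal end) at
    ``angle_start_deg`` and the z coordinate rises by ``z_rise`` mm
    from start to end, so the temporal end is the most ventral point.
    """
    center = np.asarray(center, dtype=float)
    arc_len = abs(math.radians(angle_span_deg)) * radius
    n = max(int(arc_len / step) * 4, 64)
    phi = np.radians(angle_start_deg + np.linspace(0.0, angle_span_deg, n))
    pts = np.stack(
        [
            center[0] + radius * np.cos(phi),
            center[1] + radius * np.sin(phi),
            center[2] + np.linspace(0.0, z_rise, n),
        ],
        axis=-1,
    )
    return Centerline(_resample(pts, step))


def generate_mask(
    grid: VoxelGrid,
    centerline: Centerline,
    radius_profile,
    seed: int | None = None,
) -> tuple[np.ndarray, Centerline]:
    """Carve a tube mask around a centerline.

    ``radius_profile`` maps arc length (mm) to tube radius (mm); a
    scalar gives a constant radius.  Returns the boolean mask and the
    analytic centerline (for oracle use).  ``seed`` is accepted for
    interface uniformity; the construction is deterministic.
    """
    if np.isscalar(radius_profile):
        r_const = float(radius_profile)
        radius_profile = lambda s: np.full_like(np.asarray(s, dtype=float), r_const)
    radii = np.asarray(radius_profile(centerline.arclength), dtype=float)
    r_max, r_min = float(radii.max()), float(radii.min())
    if r_min < 2.0 * max(grid.voxel_dims[0], grid.voxel_dims[1]):
        raise ValueError(
            f"tube radius {r_min:.3f} mm is below the resolvable size "
            f"(2 in-plane voxels = {2 * max(grid.voxel_dims[:2]):.3f} mm)")
    lo = centerline.points.min(axis=0) - r_max
    hi = centerline.points.max(axis=0) + r_max
    if np.any(lo < 0) or np.any(hi > grid.extent):
        raise ValueError("centerline (plus max radius) exits the voxel grid")

    centers = grid.voxel_centers()
    s, dist, idx = centerline.project(centers, return_index=True)
    inside = dist <= radius_profile(s)
    # flat end caps: drop voxels that project onto a curve endpoint with
    # outward axial overshoot (otherwise the tube grows hemispherical caps)
    t0, t1 = centerline.tangent_at_ends()
    last = len(centerline.points) - 1
    for end_idx, tang, pt in ((0, t0, centerline.points[0]),
                              (last, t1, centerline.points[-1])):
        at_end = idx == end_idx
        if np.any(at_end):
            overshoot = (centers[at_end] - pt) @ tang
            inside[at_end] &= overshoot <= 0.0
    mask = inside.reshape(grid.shape)
    return mask, centerline


# --------------------------------------------------------------------------
# Effects and parameter maps
# --------------------------------------------------------------------------

#: Ramp half-width (mm) over which effect windows fade to zero.
EFFECT_RAMP_MM = 0.5


@dataclass(frozen=True)
class EffectSpec:
    """A group-dependent alteration of one parameter in one axis window.

    ``condition`` selects the affected animals: ``"TBI"`` (all injured),
    ``"CI+"`` (cognitively impaired), or ``"TBI+"`` (epileptic).
    ``amplitude`` adds to the mean inside the window; ``sd_scale``
    multiplies the voxel noise SD there (1 = unchanged).  Window edges
    fade with a 0.5-mm half-cosine ramp extending outward.
    """

    parameter: str
    day: str
    side: str
    condition: str
    window: tuple[float, float]
    amplitude: float = 0.0
    sd_scale: float = 1.0

    def applies_to(self, labels: "AnimalLabels") -> bool:
        if self.condition == "TBI":
            return labels.group == "TBI"
        if self.condition == "sham":
            return labels.group == "sham"
        if self.condition in ("CI+", "CI-"):
            return labels.cognition == self.condition
        if self.condition in ("TBI+", "TBI-"):
            return labels.epilepsy == self.condition
        raise ValueError(f"unknown effect condition {self.condition!r}")

    def window_weight(self, s: np.ndarray) -> np.ndarray:
        """1 inside [a, b], half-cosine ramp to 0 over 0.5 mm outside."""
        a, b = self.window
        if not (np.isfinite(self.amplitude) and a <= b):
            raise ValueError(f"invalid effect window/amplitude: {self}")
        s = np.asarray(s, dtype=float)
        d = np.maximum(np.maximum(a - s, s - b), 0.0)  # distance outside window
        w = np.where(d >= EFFECT_RAMP_MM, 0.0,
                     0.5 * (1.0 + np.cos(np.pi * d / EFFECT_RAMP_MM)))
        w[d == 0.0] = 1.0
        return w


#: Rodent-plausible baseline values for each quantitative parameter.
#: These are generator defaults chosen within physiological ranges; they
#: are knobs of the phantom, not measured reference values.
BASELINES_DEFAULT: dict[str, float] = {
    "T2": 55.0,            # ms
    "T2star": 40.0,        # ms
    "FA": 0.25,
    "MD": 0.70e-3,         # mm^2/s
    "RD": 0.60e-3,
    "lambda1": 0.90e-3,
    "lambda2": 0.65e-3,
    "lambda3": 0.55e-3,
    "cl": 0.15,
    "cp": 0.15,
    "cs": 0.70,
}

#: Voxel-noise SDs per parameter (same units as the parameter).
NOISE_SDS_DEFAULT: dict[str, float] = {
    "T2": 2.0,
    "T2star": 2.0,
    "FA": 0.03,
    "MD": 0.04e-3,
    "RD": 0.04e-3,
    "lambda1": 0.05e-3,
    "lambda2": 0.04e-3,
    "lambda3": 0.04e-3,
    "cl": 0.03,
    "cp": 0.03,
    "cs": 0.04,
}


def default_effects() -> list[EffectSpec]:
    """Injury and cognition effects emulating the expected lesion pattern.

    TBI raises T2/T2* everywhere ipsilaterally early (edema), then
    lowers them septally at later days; diffusion abnormalities sit in
    the septal half, with milder septal-end changes contralaterally.
    The cognition effect is a focal contralateral alteration 2.5-4.5 mm
    from the temporal end.  Epilepsy carries no injected effect, so the
    epilepsy contrast is a true null.  Amplitudes are generator knobs.
    """
    L = 12.0
    e = EffectSpec
    return [
        e("T2", "D2", "ipsi", "TBI", (0.0, L), +8.0, 1.4),
        e("T2star", "D2", "ipsi", "TBI", (0.0, L), +5.0, 1.4),
        e("T2", "D7", "ipsi", "TBI", (6.0, L), -4.0, 1.2),
        e("T2star", "D7", "ipsi", "TBI", (6.0, L), -3.0, 1.2),
        e("T2", "D21", "ipsi", "TBI", (2.0, L), -4.0, 1.2),
        e("MD", "D7", "ipsi", "TBI", (0.0, L), +0.08e-3, 1.2),
        e("FA", "D7", "ipsi", "TBI", (7.0, L), -0.05, 1.3),
        e("FA", "D21", "ipsi", "TBI", (7.0, L), -0.04, 1.2),
        e("cl", "D21", "ipsi", "TBI", (7.0, L), -0.05),
        e("cp", "D21", "ipsi", "TBI", (7.0, L), +0.05),
        e("T2", "D7", "contra", "TBI", (8.0, L), -2.0),
        e("FA", "D21", "contra", "TBI", (8.0, L), -0.03),
        e("cl", "D21", "contra", "TBI", (8.0, L), -0.03),
        e("cs", "D21", "contra", "TBI", (8.0, L), +0.03),
        e("cp", "D7", "contra", "CI+", (2.5, 4.5), +0.04),
        e("T2", "D7", "contra", "CI+", (2.5, 4.5), +2.5),
    ]


def generate_parameter_values(
    arc: np.ndarray,
    labels: "AnimalLabels",
    side: str,
    day: str,
    parameters: list[str],
    effects: list[EffectSpec],
    baselines: dict[str, float],
    noise_sds: dict[str, float],
    rng: np.random.Generator,
    return_truth: bool = False,
):
    """Per-voxel parameter values for one animal/side/day.

    ``arc`` holds the true arc-length coordinate of each in-mask voxel.
    Value = baseline + sum of applicable windowed effect amplitudes +
    Gaussian noise (SD possibly inflated inside effect windows).
    """
    known = set(BASELINES_DEFAULT)
    for eff in effects:
        if eff.parameter not in known:
            raise ValueError(f"effect references unknown parameter {eff.parameter!r}")
        if eff.day not in RELAXOMETRY_DAYS:
            raise ValueError(f"effect references unknown day {eff.day!r}")
    out, truth_out = {}, {}
    for param in parameters:
        base = baselines[param]
        if base <= 0 and param in ("T2", "T2star"):
            raise ValueError("relaxation baselines must be positive")
        truth = np.full(arc.shape, float(base))
        sd = np.full(arc.shape, float(noise_sds.get(param, 0.0)))
        for eff in effects:
            if (eff.parameter == param and eff.day == day and eff.side == side
                    and eff.applies_to(labels)):
                w = eff.window_weight(arc)
                truth = truth + eff.amplitude * w
                sd = sd * (1.0 + (eff.sd_scale - 1.0) * w)
        out[param] = truth + rng.standard_normal(arc.shape) * sd
        if return_truth:
            truth_out[param] = truth
    return (out, truth_out) if return_truth else out


# --------------------------------------------------------------------------
# Raw signal synthesis
# --------------------------------------------------------------------------

#: Spin-echo TE grid: six echoes, 14.6-87.6 ms.
T2_ECHO_TIMES = tuple(np.linspace(14.6, 87.6, 6))
#: Gradient-echo TE grid: twelve equally spaced echoes, 4-59 ms.
T2STAR_ECHO_TIMES = tuple(np.linspace(4.0, 59.0, 12))
#: Diffusion weighting of the acquisition protocol (s/mm^2).
DEFAULT_BVALUE = 2000.0


def synthesize_echo_series(
    s0: np.ndarray,
    relax: np.ndarray,
    echo_times,
    noise_sd: float = 0.0,
    seed: int | None = None,
    rician: bool = False,
) -> np.ndarray:
    """Monoexponential multi-echo signals S0*exp(-TE/T) + noise.

    ``s0`` and ``relax`` are broadcast-compatible arrays (NaN = outside
    mask); the result gains a trailing echo axis.  Noise is Gaussian by
    default; ``rician=True`` applies magnitude (Rician) noise instead.
    """
    te = np.asarray(echo_times, dtype=float)
    if te.ndim != 1 or len(te) < 2 or te[0] <= 0 or np.any(np.diff(te) <= 0):
        raise ValueError("echo times must be >= 2 strictly increasing positive values")
    relax = np.asarray(relax, dtype=float)
    s0 = np.asarray(s0, dtype=float)
    if np.any(relax[np.isfinite(relax)] <= 0):
        raise ValueError("relaxation times must be positive inside the mask")
    clean = s0[..., None] * np.exp(-te / relax[..., None])
    if noise_sd == 0:
        return clean
    rng = np.random.default_rng(seed)
    if rician:
        re = clean + rng.standard_normal(clean.shape) * noise_sd
        im = rng.standard_normal(clean.shape) * noise_sd
        return np.hypot(re, im)
    return clean + rng.standard_normal(clean.shape) * noise_sd


def default_dwi_protocol(seed: int = 20_000) -> tuple[np.ndarray, np.ndarray]:
    """60 quasi-uniform unit directions at b = 2000 plus 4 b = 0 volumes.

    Directions come from a Fibonacci sphere (deterministic), matching
    the acquisition design in volume counts and b-value.
    """
    n = 60
    i = np.arange(n) + 0.5
    phi = np.arccos(1 - 2 * i / n)
    theta = np.pi * (1 + 5**0.5) * i
    dirs = np.stack(
        [np.sin(phi) * np.cos(theta), np.sin(phi) * np.sin(theta), np.cos(phi)],
        axis=-1,
    )
    bvals = np.concatenate([np.zeros(4), np.full(n, DEFAULT_BVALUE)])
    bvecs = np.concatenate([np.zeros((4, 3)), dirs])
    return bvals, bvecs


def tensor_from_eigenvalues(evals, axis=(1.0, 0.0, 0.0)) -> np.ndarray:
    """A symmetric tensor with given eigenvalues, principal axis ``axis``.

    Returns the 6 unique components (xx, yy, zz, xy, xz, yz).
    """
    evals = np.asarray(evals, dtype=float)
    v1 = np.asarray(axis, dtype=float)
    v1 = v1 / np.linalg.norm(v1)
    helper = np.array([0.0, 0.0, 1.0]) if abs(v1[2]) < 0.9 else np.array([1.0, 0.0, 0.0])
    v2 = np.cross(v1, helper)
    v2 /= np.linalg.norm(v2)
    v3 = np.cross(v1, v2)
    R = np.stack([v1, v2, v3], axis=-1)
    D = R @ np.diag(evals) @ R.T
    return np.array([D[0, 0], D[1, 1], D[2, 2], D[0, 1], D[0, 2], D[1, 2]])


def synthesize_dwi(
    tensors: np.ndarray,
    s0: np.ndarray,
    b_values,
    b_vectors,
    noise_sd: float = 0.0,
    seed: int | None = None,
    rician: bool = False,
) -> np.ndarray:
    """Single-tensor DWI signals S0*exp(-b g^T D g) + noise.

    ``tensors`` holds 6 unique components (xx, yy, zz, xy, xz, yz) on a
    trailing axis; the result gains a trailing volume axis.
    """
    bvals = np.asarray(b_values, dtype=float)
    bvecs = np.asarray(b_vectors, dtype=float)
    if bvecs.shape != (len(bvals), 3):
        raise ValueError("b_vectors must be (n_volumes, 3)")
    norms = np.linalg.norm(bvecs, axis=1)
    if np.any(np.abs(norms[bvals > 0] - 1.0) > 1e-6):
        raise ValueError("gradient directions must be unit norm where b > 0")
    tensors = np.asarray(tensors, dtype=float)
    gx, gy, gz = bvecs[:, 0], bvecs[:, 1], bvecs[:, 2]
    design = np.stack(
        [gx * gx, gy * gy, gz * gz, 2 * gx * gy, 2 * gx * gz, 2 * gy * gz], axis=-1
    )  # (n_vol, 6)
    quad = tensors @ design.T  # (..., n_vol)
    clean = np.asarray(s0, dtype=float)[..., None] * np.exp(-bvals * quad)
    if noise_sd == 0:
        return clean
    rng = np.random.default_rng(seed)
    if rician:
        re = clean + rng.standard_normal(clean.shape) * noise_sd
        im = rng.standard_normal(clean.shape) * noise_sd
        return np.hypot(re, im)
    return clean + rng.standard_normal(clean.shape) * noise_sd


# --------------------------------------------------------------------------
# Cohort generation
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class AnimalLabels:
    animal_id: str
    group: str                      # "sham" | "TBI"
    epilepsy: str | None = None     # "TBI+" | "TBI-" (TBI animals only)
    cognition: str | None = None    # "CI+" | "CI-" (TBI animals only)


@dataclass(frozen=True)
class GeometrySpec:
    """Shape of one hippocampus tube: C-arc with tapering radius."""

    length: float = 12.0              # septotemporal extent, mm
    angular_span_deg: float = 150.0
    radius_temporal: float = 0.8      # tube radius at the temporal end, mm
    radius_septal: float = 1.4        # tube radius at the septal end, mm
    z_rise: float = 2.0               # dorsal rise from temporal to septal end, mm

    def radius_profile(self, scale: float = 1.0):
        r0, r1, L = self.radius_temporal, self.radius_septal, self.length
        return lambda s: scale * (r0 + (r1 - r0) * np.clip(np.asarray(s) / L, 0, 1))


@dataclass(frozen=True)
class CohortConfig:
    """Study-condition defaults: 16 sham + 68 TBI, CI prevalence 0.81 and
    epilepsy prevalence 0.22 among the injured, fine in-plane resolution
    with 0.5-mm slices."""

    n_sham: int = 16
    n_tbi: int = 68
    ci_prevalence: float = 0.81
    epilepsy_prevalence: float = 0.22
    seed: int = 0
    voxel_dims: tuple[float, float, float] = (0.15, 0.15, 0.50)
    geometry: GeometrySpec = field(default_factory=GeometrySpec)
    effects: tuple[EffectSpec, ...] = field(default_factory=lambda: tuple(default_effects()))
    baselines: dict[str, float] = field(default_factory=lambda: dict(BASELINES_DEFAULT))
    noise_sds: dict[str, float] = field(default_factory=lambda: dict(NOISE_SDS_DEFAULT))
    #: TBI ipsilateral tube-radius shrinkage per day (volumetric atrophy).
    atrophy: dict[str, float] = field(
        default_factory=lambda: {"D2": 0.05, "D7": 0.12, "D21": 0.20})
    #: SD of the per-animal multiplicative size jitter.
    size_jitter_sd: float = 0.03
    store_truth: bool = True

    def __post_init__(self):
        if not (0 <= self.ci_prevalence <= 1 and 0 <= self.epilepsy_prevalence <= 1):
            raise ValueError("prevalences must lie in [0, 1]")
        if self.n_sham < 0 or self.n_tbi < 0:
            raise ValueError("cohort counts must be nonnegative")
        if self.n_tbi == 0 and (self.ci_prevalence > 0 or self.epilepsy_prevalence > 0):
            raise ValueError("nonzero prevalence requires TBI animals")


@dataclass
class AnimalRecord:
    """All synthetic data of one animal: labels, masks, maps, truth.

    Masks are keyed by (side, day); parameter values by
    (side, parameter, day) and aligned with ``np.argwhere(mask)`` order.
    ``centerlines`` holds the analytic axis per side (oracle).
    """

    labels: AnimalLabels
    grid: VoxelGrid
    masks: dict = field(default_factory=dict)
    values: dict = field(default_factory=dict)
    truth: dict = field(default_factory=dict)
    arc: dict = field(default_factory=dict)       # (side, day) -> s per voxel
    centerlines: dict = field(default_factory=dict)

    @property
    def animal_id(self) -> str:
        return self.labels.animal_id

    def parameter_map(self, side: str, parameter: str, day: str) -> ParameterMap:
        """Materialize a full 3D map (NaN outside the mask)."""
        mask = self.masks[(side, day)]
        data = np.full(self.grid.shape, np.nan)
        data[mask] = self.values[(side, parameter, day)]
        units = "ms" if parameter in ("T2", "T2star") else (
            "mm^2/s" if parameter in ("MD", "RD", "lambda1", "lambda2", "lambda3") else "")
        return ParameterMap(data, self.grid, parameter, units, day, side)


def _grid_for_geometry(geom: GeometrySpec, voxel_dims) -> tuple[VoxelGrid, np.ndarray]:
    """A grid that contains the arc with margin, and the arc center."""
    R = geom.length / math.radians(geom.angular_span_deg)
    r_max = max(geom.radius_temporal, geom.radius_septal) * 1.2
    margin = r_max + 1.0
    half = geom.angular_span_deg / 2.0
    x_span = R - R * math.cos(math.radians(half))
    y_span = 2 * R * math.sin(math.radians(half))
    extent = np.array([x_span + 2 * margin, y_span + 2 * margin,
                       geom.z_rise + 2 * margin])
    shape = tuple(int(np.ceil(e / d)) for e, d in zip(extent, voxel_dims))
    grid = VoxelGrid(shape, tuple(voxel_dims))
    # place the arc center so the arc (which bulges toward +x) is inside
    center = np.array([margin - R * math.cos(math.radians(half)),
                       grid.extent[1] / 2.0, margin])
    return grid, center


def _draw_labels(cfg: CohortConfig, rng: np.random.Generator) -> list[AnimalLabels]:
    """Sham/TBI labels with deterministically rounded positive counts."""
    n_ci = int(math.floor(cfg.ci_prevalence * cfg.n_tbi + 0.5))
    n_ep = int(math.floor(cfg.epilepsy_prevalence * cfg.n_tbi + 0.5))
    ci = np.array(["CI-"] * cfg.n_tbi, dtype=object)
    ep = np.array(["TBI-"] * cfg.n_tbi, dtype=object)
    if cfg.n_tbi:
        ci[rng.choice(cfg.n_tbi, size=n_ci, replace=False)] = "CI+"
        ep[rng.choice(cfg.n_tbi, size=n_ep, replace=False)] = "TBI+"
    labels = [AnimalLabels(f"sham{i + 1:03d}", "sham") for i in range(cfg.n_sham)]
    labels += [
        AnimalLabels(f"tbi{i + 1:03d}", "TBI", epilepsy=ep[i], cognition=ci[i])
        for i in range(cfg.n_tbi)
    ]
    return labels


def labels_frame(labels: list[AnimalLabels]) -> pd.DataFrame:
    """Cohort label table (animal_id, group, epilepsy, cognition)."""
    return pd.DataFrame(
        {
            "animal_id": [l.animal_id for l in labels],
            "group": [l.group for l in labels],
            "epilepsy": [l.epilepsy or "" for l in labels],
            "cognition": [l.cognition or "" for l in labels],
        }
    )


def generate_cohort(config: CohortConfig) -> tuple[list[AnimalRecord], pd.DataFrame]:
    """Generate the full cohort: masks, maps, truth, labels.

    Relaxometry maps exist for D2/D7/D21, tensor-scalar maps for D7/D21
    only, both hippocampi per animal.  Identical config (including seed)
    reproduces the cohort bit for bit.
    """
    cfg = config
    master = np.random.SeedSequence(cfg.seed)
    ss_labels, ss_animals = master.spawn(2)
    labels = _draw_labels(cfg, np.random.default_rng(ss_labels))
    geom = cfg.geometry
    grid, center = _grid_for_geometry(geom, cfg.voxel_dims)
    R = geom.length / math.radians(geom.angular_span_deg)
    half = geom.angular_span_deg / 2.0

    # contralateral arc mirrored in y, slightly slimmer
    base_lines = {
        "ipsi": arc_centerline(center, R, -half, geom.angular_span_deg, geom.z_rise),
        "contra": arc_centerline(center + [0, 0, 0.0], R, half, -geom.angular_span_deg,
                                 geom.z_rise),
    }
    side_scale = {"ipsi": 1.0, "contra": 0.97}

    records: list[AnimalRecord] = []
    centers_flat = grid.voxel_centers()
    # the base centerlines are shared across animals: project voxel
    # centers once per side, not once per animal
    projections = {}
    for side in SIDES:
        line = base_lines[side]
        s_all, dist_all, nearest = line.project(centers_flat, return_index=True)
        # same flat end caps as generate_mask: no outward axial overshoot
        axial_ok = np.ones(len(centers_flat), dtype=bool)
        t0, t1 = line.tangent_at_ends()
        for end_idx, tang, pt in ((0, t0, line.points[0]),
                                  (len(line.points) - 1, t1, line.points[-1])):
            at_end = nearest == end_idx
            if np.any(at_end):
                axial_ok[at_end] = (centers_flat[at_end] - pt) @ tang <= 0.0
        projections[side] = (s_all, dist_all, axial_ok)
    for lab, ss in zip(labels, ss_animals.spawn(len(labels))):
        rng = np.random.default_rng(ss)
        jitter = float(np.exp(rng.normal(0.0, cfg.size_jitter_sd)))
        rec = AnimalRecord(labels=lab, grid=grid)
        for side in SIDES:
            line = base_lines[side]
            rec.centerlines[side] = line
            s_all, dist_all, axial_ok = projections[side]
            for day in RELAXOMETRY_DAYS:
                scale = jitter * side_scale[side]
                if lab.group == "TBI" and side == "ipsi":
                    scale *= math.sqrt(max(1.0 - cfg.atrophy.get(day, 0.0), 0.0))
                rprof = geom.radius_profile(scale)
                inside = axial_ok & (dist_all <= rprof(s_all))
                mask = inside.reshape(grid.shape)
                rec.masks[(side, day)] = mask
                rec.arc[(side, day)] = s_all[inside]
                params = list(RELAXOMETRY_PARAMS) + (
                    list(DTI_PARAMS) if day in DTI_DAYS else [])
                vals, truth = generate_parameter_values(
                    rec.arc[(side, day)], lab, side, day, params,
                    list(cfg.effects), cfg.baselines, cfg.noise_sds, rng,
                    return_truth=True,
                )
                for p, v in vals.items():
                    rec.values[(side, p, day)] = v
                if cfg.store_truth:
                    for p, t in truth.items():
                        rec.truth[(side, p, day)] = t
        records.append(rec)
    return records, labels_frame(labels)
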