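"""Single diffusion-tensor fitting and scalar tensor metrics.

The tensor is estimated per voxel by ordinary least squares on the
log-signals (log-linear fit); scalars are the eigenvalues, FA, MD, RD,
and the Westin shape measures.  The Westin measures use the
trace-normalized convention, so c_l + c_p + c_s = 1 for every defined
voxel:

    c_l = (l1 - l2) / tr,  c_p = 2 (l2 - l3) / tr,  c_s = 3 l3 / tr.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core import ParameterMap, VoxelGrid

SCALAR_NAMES = ("FA", "MD", "RD", "lambda1", "lambda2", "lambda3", "cl", "cp", "cs")


@dataclass
class DWISeries:
    """A 4D diffusion acquisition with per-volume b-values and directions."""

    data: np.ndarray
    b_values: np.ndarray
    b_vectors: np.ndarray
    grid: VoxelGrid

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        self.b_values = np.asarray(self.b_values, dtype=float)
        self.b_vectors = np.asarray(self.b_vectors, dtype=float)
        n = len(self.b_values)
        if self.data.ndim != 4 or self.data.shape[:3] != self.grid.shape:
            raise ValueError("DWI series must be 4D on the declared grid")
        if self.data.shape[3] != n or self.b_vectors.shape != (n, 3):
            raise ValueError("b-value/b-vector tables do not match the volume count")
        if n < 7 or not np.any(self.b_values == 0):
            raise ValueError("need >= 7 volumes including >= 1 b=0 volume")
        norms = np.linalg.norm(self.b_vectors, axis=1)
        if np.any(np.abs(norms[self.b_values > 0] - 1.0) > 1e-6):
            raise ValueError("gradient directions must be unit norm where b > 0")


@dataclass
class TensorField:
    """Per-voxel symmetric tensors as 6 components (xx, yy, zz, xy, xz, yz)."""

    components: np.ndarray          # (..., 6), mm^2/s; NaN where undefined
    grid: VoxelGrid | None = None
    clamped: np.ndarray | None = None   # True where eigenvalues were clamped at 0
    flags: dict = field(default_factory=dict)

    def matrices(self) -> np.ndarray:
        c = self.components
        m = np.empty(c.shape[:-1] + (3, 3))
        m[..., 0, 0] = c[..., 0]
        m[..., 1, 1] = c[..., 1]
        m[..., 2, 2] = c[..., 2]
        m[..., 0, 1] = m[..., 1, 0] = c[..., 3]
        m[..., 0, 2] = m[..., 2, 0] = c[..., 4]
        m[..., 1, 2] = m[..., 2, 1] = c[..., 5]
        return m

    def eigenvalues(self, clamp: bool = True) -> np.ndarray:
        """Sorted (descending) eigenvalues; optionally clamped at zero."""
        m = self.matrices()
        ok = np.all(np.isfinite(m.reshape(m.shape[:-2] + (9,))), axis=-1)
        safe = np.where(ok[..., None, None], m, np.eye(3))
        evals = np.linalg.eigvalsh(safe)[..., ::-1]
        evals = np.where(ok[..., None], evals, np.nan)
        if clamp:
            clamped = np.any(evals < 0, axis=-1) & ok
            evals = np.clip(evals, 0.0, None)
            self.clamped = clamped
        return evals


def _design_matrix(b_values: np.ndarray, b_vectors: np.ndarray) -> np.ndarray:
    """Columns: log S0, then -b * (gx^2, gy^2, gz^2, 2gxgy, 2gxgz, 2gygz)."""
    g = b_vectors
    quad = np.stack(
        [g[:, 0] ** 2, g[:, 1] ** 2, g[:, 2] ** 2,
         2 * g[:, 0] * g[:, 1], 2 * g[:, 0] * g[:, 2], 2 * g[:, 1] * g[:, 2]],
        axis=-1,
    )
    return np.concatenate([np.ones((len(b_values), 1)), -b_values[:, None] * quad],
                          axis=1)


def fit_tensor_loglinear(series: DWISeries, mask: np.ndarray) -> TensorField:
    """OLS log-linear tensor fit in every in-mask voxel.

    Nonpositive signals are excluded per voxel; voxels with fewer than 7
    usable volumes (or a nonpositive mean b=0 signal) are left undefined
    and counted in the QC flags.
    """
    bvecs_dw = series.b_vectors[series.b_values > 0]
    # rank of the quadratic-form design over distinct directions
    quad = _design_matrix(series.b_values[series.b_values > 0], bvecs_dw)[:, 1:]
    if np.linalg.matrix_rank(quad) < 6:
        raise ValueError("insufficient directions: need >= 6 non-collinear gradients")
    mask = series.grid.check_mask(mask)
    comps = np.full(series.grid.shape + (6,), np.nan)
    n_rejected = 0
    if np.any(mask):
        sig = series.data[mask]                      # (n_vox, n_vol)
        X = _design_matrix(series.b_values, series.b_vectors)
        b0_mean = sig[:, series.b_values == 0].mean(axis=1)
        usable = sig > 0
        n_usable = usable.sum(axis=1)
        ok = (n_usable >= 7) & (b0_mean > 0)
        n_rejected = int((~ok).sum())
        out = np.full((sig.shape[0], 6), np.nan)
        full = usable.all(axis=1) & ok
        if np.any(full):  # common case: one shared pseudo-inverse
            logs = np.log(sig[full])
            beta = np.linalg.pinv(X) @ logs.T
            out[full] = beta[1:].T
        partial = ok & ~full
        for i in np.where(partial)[0]:
            u = usable[i]
            beta, *_ = np.linalg.lstsq(X[u], np.log(sig[i, u]), rcond=None)
            out[i] = beta[1:]
        comps[mask] = out
    field_ = TensorField(comps, series.grid, flags={"n_rejected_voxels": n_rejected})
    return field_


def tensor_scalars(eigenvalues: np.ndarray) -> dict[str, np.ndarray]:
    """Scalar maps from sorted nonnegative eigenvalue triples.

    Accepts (..., 3) arrays with l1 >= l2 >= l3 >= 0.  All-zero triples
    yield NaN scalars.  FA = sqrt(3/2) ||l - MD|| / ||l||; the Westin
    components are trace-normalized and sum to one.
    """
    ev = np.asarray(eigenvalues, dtype=float)
    if ev.shape[-1] != 3:
        raise ValueError("eigenvalues must have a trailing axis of length 3")
    finite = np.all(np.isfinite(ev), axis=-1)
    if np.any(finite[..., None] & (np.diff(ev, axis=-1)
                                   > 1e-12 * np.abs(ev[..., :1]) + 1e-30)):
        raise ValueError("eigenvalues must be sorted in descending order")
    if np.any(finite & (ev[..., 2] < -1e-30)):
        raise ValueError("eigenvalues must be nonnegative (clamp before calling)")
    l1, l2, l3 = ev[..., 0], ev[..., 1], ev[..., 2]
    tr = l1 + l2 + l3
    defined = finite & (tr > 0)
    tr_safe = np.where(defined, tr, 1.0)
    md = tr / 3.0
    norm = np.sqrt(l1**2 + l2**2 + l3**2)
    norm_safe = np.where(defined & (norm > 0), norm, 1.0)
    dev = np.sqrt((l1 - md) ** 2 + (l2 - md) ** 2 + (l3 - md) ** 2)
    fa = np.sqrt(1.5) * dev / norm_safe
    out = {
        "FA": fa,
        "MD": md,
        "RD": (l2 + l3) / 2.0,
        "lambda1": l1,
        "lambda2": l2,
        "lambda3": l3,
        "cl": (l1 - l2) / tr_safe,
        "cp": 2.0 * (l2 - l3) / tr_safe,
        "cs": 3.0 * l3 / tr_safe,
    }
    for k in out:
        out[k] = np.where(defined, out[k], np.nan)
    return out


def tensor_scalar_maps(field_: TensorField, day: str | None = None,
                       side: str | None = None) -> dict[str, ParameterMap]:
    """All scalar maps of a fitted tensor field as ParameterMaps."""
    evals = field_.eigenvalues(clamp=True)
    scalars = tensor_scalars(evals)
    units = {"MD": "mm^2/s", "RD": "mm^2/s", "lambda1": "mm^2/s",
             "lambda2": "mm^2/s", "lambda3": "mm^2/s"}
    return {
        name: ParameterMap(arr, field_.grid, name, units.get(name, ""), day, side,
                           flags={"n_clamped": int(np.nansum(field_.clamped))})
        for name, arr in scalars.items()
    }
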