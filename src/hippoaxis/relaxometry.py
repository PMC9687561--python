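"""T2 / T2* map estimation from multi-echo series.

Each voxel is fitted with the two-parameter monoexponential decay
S(TE) = S0 * exp(-TE / T) by nonlinear least squares, initialized from
the log-linear regression of the positive signals.  The solver is a
Levenberg-Marquardt iteration vectorized over voxels, so whole maps fit
in a single call; steps are only accepted when they reduce the residual,
which guarantees the NLLS solution never falls behind its log-linear
start.

Relaxation times are bounded to (0, T_max] with T_max = 2x the last
echo time: decay slower than that is not identifiable from the sampled
window, and such voxels are clipped and flagged rather than left to
drift.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple

import numpy as np

from .core import ParameterMap, VoxelGrid

#: Fit status codes.
FLAG_OK = 0
FLAG_UNDEFINED = 1      # no positive signals; result is NaN
FLAG_CLIPPED = 2        # T hit its bound (e.g. no measurable decay)
FLAG_FALLBACK = 3       # NLLS did not improve; log-linear estimate kept


@dataclass
class EchoSeries:
    """A 4D multi-echo acquisition with its echo-time grid (ms)."""

    data: np.ndarray
    echo_times: np.ndarray
    grid: VoxelGrid

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        self.echo_times = np.asarray(self.echo_times, dtype=float)
        if self.data.ndim != 4 or self.data.shape[:3] != self.grid.shape:
            raise ValueError("echo series must be 4D on the declared grid")
        te = self.echo_times
        if len(te) < 2 or te[0] <= 0 or np.any(np.diff(te) <= 0):
            raise ValueError("need >= 2 strictly increasing positive echo times")
        if self.data.shape[3] != len(te):
            raise ValueError("echo axis does not match the echo-time grid")


class MonoExpFit(NamedTuple):
    s0: float
    t: float
    flag: int


def _loglinear_init(signals: np.ndarray, te: np.ndarray, t_max: float):
    """Log-linear (S0, T) estimates per voxel; nonpositive echoes ignored."""
    pos = signals > 0
    w = pos.astype(float)
    y = np.where(pos, np.log(np.where(pos, signals, 1.0)), 0.0)
    n = w.sum(axis=-1)
    sx = (w * te).sum(axis=-1)
    sy = (w * y).sum(axis=-1)
    sxx = (w * te * te).sum(axis=-1)
    sxy = (w * te * y).sum(axis=-1)
    denom = n * sxx - sx * sx
    ok = (n >= 2) & (denom > 0)
    slope = np.where(ok, (n * sxy - sx * sy) / np.where(denom == 0, 1.0, denom), 0.0)
    intercept = np.where(ok, (sy - slope * sx) / np.where(n == 0, 1.0, n), 0.0)
    t0 = np.where(slope < 0, -1.0 / np.where(slope == 0, -1.0, slope), t_max)
    t0 = np.clip(t0, 1e-6, t_max)
    s0 = np.exp(intercept)
    # single positive echo: flat extrapolation at that amplitude
    one = n == 1
    if np.any(one):
        s0 = np.where(one, (w * signals).sum(axis=-1), s0)
        t0 = np.where(one, t_max, t0)
    return s0, t0, n


def _sse(signals, te, s0, t):
    model = s0[..., None] * np.exp(-te / t[..., None])
    return ((signals - model) ** 2).sum(axis=-1)


def fit_monoexponential_bulk(signals: np.ndarray, echo_times, max_iter: int = 60):
    """Vectorized monoexponential NLLS over the leading axes of ``signals``.

    Returns (s0, t, flags) arrays with the echo axis reduced away.
    """
    te = np.asarray(echo_times, dtype=float)
    if len(te) < 2 or te[0] <= 0 or np.any(np.diff(te) <= 0):
        raise ValueError("need >= 2 strictly increasing positive echo times")
    signals = np.asarray(signals, dtype=float)
    if signals.shape[-1] != len(te):
        raise ValueError("signal echo axis does not match echo times")
    t_max = 2.0 * te[-1]
    shape = signals.shape[:-1]
    flat = signals.reshape(-1, len(te))

    s0, t, n_pos = _loglinear_init(flat, te, t_max)
    undefined = n_pos == 0
    sse = _sse(flat, te, s0, t)
    sse_init = sse.copy()
    lam = np.full(s0.shape, 1e-3)

    active = ~undefined
    for _ in range(max_iter):
        if not np.any(active):
            break
        e = np.exp(-te / t[..., None])
        model = s0[..., None] * e
        r = flat - model
        j1 = e
        j2 = model * te / (t[..., None] ** 2)
        a11 = (j1 * j1).sum(axis=-1)
        a22 = (j2 * j2).sum(axis=-1)
        a12 = (j1 * j2).sum(axis=-1)
        b1 = (j1 * r).sum(axis=-1)
        b2 = (j2 * r).sum(axis=-1)
        d11 = a11 * (1 + lam)
        d22 = a22 * (1 + lam)
        det = d11 * d22 - a12 * a12
        det = np.where(np.abs(det) < 1e-300, 1e-300, det)
        ds0 = (b1 * d22 - b2 * a12) / det
        dt = (b2 * d11 - b1 * a12) / det
        s0_new = np.clip(s0 + ds0, 1e-300, None)
        t_new = np.clip(t + dt, 1e-6, t_max)
        sse_new = _sse(flat, te, s0_new, t_new)
        improved = active & (sse_new < sse)
        s0 = np.where(improved, s0_new, s0)
        t = np.where(improved, t_new, t)
        sse = np.where(improved, sse_new, sse)
        lam = np.where(improved, lam / 3.0, lam * 2.0)
        small = improved & (np.abs(ds0) <= 1e-10 * np.maximum(s0, 1.0)) & (
            np.abs(dt) <= 1e-10 * t)
        active = active & ~small & (lam < 1e12)

    flags = np.zeros(s0.shape, dtype=np.int8)
    flags[sse > sse_init + 1e-12] = FLAG_FALLBACK  # cannot happen by construction
    flags[t >= t_max * (1 - 1e-12)] = FLAG_CLIPPED
    flags[undefined] = FLAG_UNDEFINED
    s0 = np.where(undefined, np.nan, s0)
    t = np.where(undefined, np.nan, t)
    return s0.reshape(shape), t.reshape(shape), flags.reshape(shape)


def fit_monoexponential(signals, times) -> MonoExpFit:
    """Fit one voxel's decay; returns (S0, T, flag).

    All-nonpositive signals yield a NaN result flagged as undefined.
    """
    s0, t, flag = fit_monoexponential_bulk(np.asarray(signals, dtype=float)[None, :],
                                           times)
    return MonoExpFit(float(s0[0]), float(t[0]), int(flag[0]))


def fit_relaxation_map(series: EchoSeries, mask: np.ndarray,
                       parameter: str = "T2", day: str | None = None,
                       side: str | None = None) -> ParameterMap:
    """Per-voxel relaxation map over a mask; NaN outside.

    QC counts of clipped/fallback/undefined voxels are stored in the
    map's ``flags``.
    """
    mask = series.grid.check_mask(mask)
    data = np.full(series.grid.shape, np.nan)
    qc = {"n_clipped": 0, "n_fallback": 0, "n_undefined": 0}
    if np.any(mask):
        sig = series.data[mask]
        _, t, flags = fit_monoexponential_bulk(sig, series.echo_times)
        t = np.where(flags == FLAG_UNDEFINED, np.nan, t)
        data[mask] = t
        qc = {
            "n_clipped": int((flags == FLAG_CLIPPED).sum()),
            "n_fallback": int((flags == FLAG_FALLBACK).sum()),
            "n_undefined": int((flags == FLAG_UNDEFINED).sum()),
        }
    return ParameterMap(data, series.grid, parameter, "ms", day, side, flags=qc)
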