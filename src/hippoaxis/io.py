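"""File interfaces: NIfTI maps and masks, sidecars, tables, configs.

Maps are written one NIfTI per animal/side/day/parameter with the voxel
dimensions carried in the affine; masks as uint8; labels, profiles,
statistics grids and AUC curves as CSV; echo times as a JSON sidecar;
diffusion tables in the two-file plain-text bval/bvec dialect; run
configuration as YAML.
"""

from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd
import yaml

from .core import ParameterMap, VoxelGrid


def _affine(grid: VoxelGrid) -> np.ndarray:
    return np.diag(list(grid.voxel_dims) + [1.0])


def save_map(pmap: ParameterMap, path) -> None:
    img = nib.Nifti1Image(pmap.data.astype(np.float32), _affine(pmap.grid))
    img.header.set_zooms(pmap.grid.voxel_dims)
    nib.save(img, str(path))


def load_map(path, parameter: str = "", day: str | None = None,
             side: str | None = None) -> ParameterMap:
    img = nib.load(str(path))
    data = np.asarray(img.dataobj, dtype=float)
    grid = VoxelGrid(data.shape, tuple(float(z) for z in img.header.get_zooms()[:3]))
    return ParameterMap(data, grid, parameter, day=day, side=side)


def save_mask(mask: np.ndarray, grid: VoxelGrid, path) -> None:
    img = nib.Nifti1Image(np.asarray(mask, dtype=np.uint8), _affine(grid))
    img.header.set_zooms(grid.voxel_dims)
    nib.save(img, str(path))


def load_mask(path) -> tuple[np.ndarray, VoxelGrid]:
    img = nib.load(str(path))
    data = np.asarray(img.dataobj)
    grid = VoxelGrid(data.shape, tuple(float(z) for z in img.header.get_zooms()[:3]))
    return data > 0, grid


def save_series(data: np.ndarray, grid: VoxelGrid, path) -> None:
    """A 4D series (echo or diffusion volumes on the last axis)."""
    img = nib.Nifti1Image(np.asarray(data, dtype=np.float32), _affine(grid))
    nib.save(img, str(path))


def load_series(path) -> tuple[np.ndarray, VoxelGrid]:
    img = nib.load(str(path))
    data = np.asarray(img.dataobj, dtype=float)
    grid = VoxelGrid(data.shape[:3], tuple(float(z) for z in img.header.get_zooms()[:3]))
    return data, grid


def save_echo_times(echo_times, path) -> None:
    Path(path).write_text(json.dumps({"echo_times_ms": list(map(float, echo_times))}))


def load_echo_times(path) -> np.ndarray:
    return np.asarray(json.loads(Path(path).read_text())["echo_times_ms"], dtype=float)


def save_bvals_bvecs(b_values, b_vectors, bval_path, bvec_path) -> None:
    """FSL-style: one row of b-values; three rows of gradient components."""
    np.savetxt(bval_path, np.asarray(b_values)[None, :], fmt="%.6g")
    np.savetxt(bvec_path, np.asarray(b_vectors).T, fmt="%.8f")


def load_bvals_bvecs(bval_path, bvec_path) -> tuple[np.ndarray, np.ndarray]:
    bvals = np.loadtxt(bval_path).reshape(-1)
    bvecs = np.loadtxt(bvec_path)
    if bvecs.shape[0] == 3:
        bvecs = bvecs.T
    return bvals, bvecs


def save_labels(labels: pd.DataFrame, path) -> None:
    labels.to_csv(path, index=False)


def load_labels(path) -> pd.DataFrame:
    df = pd.read_csv(path, keep_default_na=False)
    required = {"animal_id", "group", "epilepsy", "cognition"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"label table is missing columns: {sorted(missing)}")
    return df


def save_profiles(table: pd.DataFrame, path) -> None:
    table.to_csv(path, index=False)


def load_profiles(path) -> pd.DataFrame:
    return pd.read_csv(path)


def load_yaml(path) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh) or {}


def dump_yaml(obj: dict, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(obj, fh, sort_keys=False)
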