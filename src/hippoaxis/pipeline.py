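"""End-to-end orchestration: generate -> profile -> compare -> model.

One seeded, logged run over a synthetic cohort (or pre-computed profile
tables) producing profile CSVs, statistics grids, AUC-versus-position
curves, coefficient importance tables, volume models, and a provenance
record sufficient to reproduce every number.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io
from .core import SIDES
from .model import (
    coefficient_importance,
    model_auc_with_ci,
    position_sweep,
    volume_model,
)
from .profiles import cohort_profiles, cohort_volumes
from .stats import contrast_labels, profile_group_comparison
from .synthetic import CohortConfig, generate_cohort

log = logging.getLogger("hippoaxis")


@dataclass
class RunConfig:
    """Configuration of one pipeline run (YAML-serializable)."""

    cohort: dict = field(default_factory=dict)   # CohortConfig overrides
    fwhm: float = 1.5                            # axis smoothing kernel, mm
    spacing: float = 0.5                         # profile position spacing, mm
    axis_mode: str = "skeleton"                  # "skeleton" | "true"
    erode: bool = True
    caudal_drop: int = 0
    contrasts: tuple = ("sham_tbi", "epilepsy", "cognition")
    q_level: float = 0.05
    family: str = "per_panel"
    n_boot: int = 10_000
    model_positions: list | None = None          # default: full profile grid
    inner: str = "loo"
    n_inner: int = 10
    n_lambda: int = 100
    lambda_min_ratio: float = 1e-4
    stat_auc_ci: bool = False                    # per-cell CIs in the stats grid
    seed: int = 0
    outdir: str = "hippoaxis_run"

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = io.load_yaml(path)
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**raw)
        cfg.contrasts = tuple(cfg.contrasts)
        return cfg


def _config_hash(cfg: RunConfig) -> str:
    blob = json.dumps(asdict(cfg), sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def run_pipeline(config: RunConfig) -> dict:
    """Execute all stages; returns the report bundle (also written to disk).

    Any stage failure aborts with that stage's message after writing a
    partial-results manifest.  Re-running the same config reproduces all
    numbers exactly: every source of randomness derives from the master
    seed.
    """
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    seeds = np.random.SeedSequence(config.seed).generate_state(4) % (2**31 - 1)
    manifest = {"completed_stages": [], "failed_stage": None}
    report: dict = {"config_hash": _config_hash(config), "seeds": seeds.tolist()}

    def fail(stage: str, err: Exception):
        manifest["failed_stage"] = {"stage": stage, "error": str(err)}
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
        raise RuntimeError(f"pipeline stage {stage!r} failed: {err}") from err

    # -- generate ----------------------------------------------------------
    try:
        cohort_cfg = CohortConfig(**{"seed": int(seeds[0]), **config.cohort})
        records, labels = generate_cohort(cohort_cfg)
        io.save_labels(labels, out / "labels.csv")
        qc = {"n_animals": len(records)}
        log.info("generate: %d animals", len(records))
    except Exception as err:  # noqa: BLE001 - stage boundary
        fail("generate", err)
    manifest["completed_stages"].append("generate")

    # -- profile -----------------------------------------------------------
    try:
        profile_table = cohort_profiles(
            records, fwhm=config.fwhm, spacing=config.spacing,
            axis_mode=config.axis_mode, erode=config.erode,
            caudal_drop=config.caudal_drop)
        io.save_profiles(profile_table, out / "profiles.csv")
        volumes = cohort_volumes(records)
        volumes.to_csv(out / "volumes.csv")
        qc["n_profile_rows"] = len(profile_table)
        log.info("profile: %d rows", len(profile_table))
    except Exception as err:  # noqa: BLE001
        fail("profile", err)
    manifest["completed_stages"].append("profile")

    # -- compare -----------------------------------------------------------
    stats_tables = {}
    try:
        for contrast in config.contrasts:
            grid = profile_group_comparison(
                profile_table, labels, contrast, q_level=config.q_level,
                family=config.family, auc_ci=config.stat_auc_ci,
                n_boot=config.n_boot, seed=int(seeds[1]))
            grid.to_csv(out / f"stats_{contrast}.csv", index=False)
            stats_tables[contrast] = grid
            log.info("compare[%s]: %d cells, %d rejected", contrast,
                     len(grid), int(grid["reject"].sum()))
    except Exception as err:  # noqa: BLE001
        fail("compare", err)
    manifest["completed_stages"].append("compare")

    # -- model -------------------------------------------------------------
    curves, importances = {}, {}
    try:
        for contrast in config.contrasts:
            results, curve = position_sweep(
                profile_table, labels, contrast,
                positions=config.model_positions, seed=int(seeds[2]),
                n_boot=config.n_boot, inner=config.inner,
                n_inner=config.n_inner, n_lambda=config.n_lambda,
                lambda_min_ratio=config.lambda_min_ratio)
            curve.to_csv(out / f"auc_curve_{contrast}.csv", index=False)
            curves[contrast] = curve
            for side in SIDES:
                side_res = [r for r in results if r.side == side]
                imp = coefficient_importance(side_res)
                imp.to_csv(out / f"importance_{contrast}_{side}.csv")
                importances[(contrast, side)] = imp
            log.info("model[%s]: %d positions", contrast, len(curve))
    except Exception as err:  # noqa: BLE001
        fail("model", err)
    manifest["completed_stages"].append("model")

    # -- volume models -----------------------------------------------------
    try:
        vol_report = {}
        for contrast in config.contrasts:
            y = contrast_labels(labels, contrast)
            vols = volumes.loc[[a for a in volumes.index if a in y.index]]
            res = volume_model(vols, y.loc[vols.index].to_numpy(),
                               seed=int(seeds[3]), inner=config.inner,
                               n_inner=config.n_inner, n_lambda=config.n_lambda,
                               lambda_min_ratio=config.lambda_min_ratio)
            auc, lo, hi = model_auc_with_ci(res, n_boot=config.n_boot,
                                            seed=int(seeds[3]))
            vol_report[contrast] = {"auc": auc, "ci_lo": lo, "ci_hi": hi}
        (out / "volume_models.json").write_text(json.dumps(vol_report, indent=2))
    except Exception as err:  # noqa: BLE001
        fail("volume", err)
    manifest["completed_stages"].append("volume")

    # -- provenance --------------------------------------------------------
    import scipy

    provenance = {
        "config": asdict(config),
        "config_hash": report["config_hash"],
        "stage_seeds": seeds.tolist(),
        "versions": {"hippoaxis": "0.1.0", "numpy": np.__version__,
                     "scipy": scipy.__version__, "pandas": pd.__version__},
        "qc": qc,
    }
    (out / "provenance.json").write_text(json.dumps(provenance, indent=2))
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))

    report.update({
        "labels": labels, "profiles": profile_table, "volumes": volumes,
        "stats": stats_tables, "auc_curves": curves, "importance": importances,
        "volume_models": vol_report, "provenance": provenance,
    })
    return report
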