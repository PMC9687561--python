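"""Position-wise group statistics for axis profiles.

Two-group comparison of every (parameter, day, statistic, position,
side) cell with the Mann-Whitney U test, Benjamini-Hochberg FDR control
within configurable families, and single-parameter discrimination as
the empirical AUC with a bias-corrected and accelerated (BCa) bootstrap
confidence interval.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats as sps
from scipy.stats import rankdata
from statsmodels.stats.multitest import multipletests

#: Contrast name -> (label column, negative class, positive class).
CONTRASTS = {
    "sham_tbi": ("group", "sham", "TBI"),
    "epilepsy": ("epilepsy", "TBI-", "TBI+"),
    "cognition": ("cognition", "CI-", "CI+"),
}


def contrast_labels(labels: pd.DataFrame, contrast: str) -> pd.Series:
    """Binary outcome (0/1) per animal id for one contrast.

    Animals outside the contrast (e.g. sham animals for the epilepsy
    contrast) are omitted.
    """
    if contrast not in CONTRASTS:
        raise ValueError(f"unknown contrast {contrast!r}; choose from {list(CONTRASTS)}")
    col, neg, pos = CONTRASTS[contrast]
    sub = labels[labels[col].isin([neg, pos])]
    y = (sub[col] == pos).astype(int)
    y.index = sub["animal_id"].values
    return y


def mann_whitney_u(a, b) -> tuple[float, float]:
    """Two-sided Mann-Whitney U test; returns (U of sample a, p).

    Exact null distribution when the combined sample has <= 20
    observations and no ties; otherwise the normal approximation with
    tie and continuity corrections.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both groups must be nonempty")
    combined = np.concatenate([a, b])
    no_ties = len(np.unique(combined)) == len(combined)
    method = "exact" if (len(combined) <= 20 and no_ties) else "asymptotic"
    res = sps.mannwhitneyu(a, b, alternative="two-sided", method=method,
                           use_continuity=True)
    return float(res.statistic), float(min(res.pvalue, 1.0))


def bh_fdr(pvals, q_level: float = 0.05) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini-Hochberg step-up; returns (adjusted p, reject flags)."""
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        return np.array([]), np.array([], dtype=bool)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    reject, p_adj, *_ = multipletests(p, alpha=q_level, method="fdr_bh")
    return p_adj, reject


def empirical_auc(scores, labels) -> float:
    """Rank-based AUC: fraction of positive-negative pairs correctly
    ordered, ties counting one half."""
    scores = np.asarray(scores, dtype=float)
    y = np.asarray(labels).astype(int)
    n1 = int(y.sum())
    n0 = len(y) - n1
    if n1 == 0 or n0 == 0:
        raise ValueError("both classes must be present")
    r = rankdata(scores)
    u1 = r[y == 1].sum() - n1 * (n1 + 1) / 2.0
    return float(u1 / (n1 * n0))


def _auc_rows(pos: np.ndarray, neg: np.ndarray) -> np.ndarray:
    """AUC per row for (B, n1) positive and (B, n0) negative score blocks."""
    n1, n0 = pos.shape[1], neg.shape[1]
    r = rankdata(np.concatenate([pos, neg], axis=1), axis=1)
    u1 = r[:, :n1].sum(axis=1) - n1 * (n1 + 1) / 2.0
    return u1 / (n1 * n0)


def _jackknife_auc(pos: np.ndarray, neg: np.ndarray) -> np.ndarray:
    """Leave-one-animal-out AUC values (length n1 + n0)."""
    wins = (pos[:, None] > neg[None, :]) + 0.5 * (pos[:, None] == neg[None, :])
    n1, n0 = len(pos), len(neg)
    total = wins.sum()
    out = np.empty(n1 + n0)
    out[:n1] = (total - wins.sum(axis=1)) / ((n1 - 1) * n0) if n1 > 1 else np.nan
    out[n1:] = (total - wins.sum(axis=0)) / (n1 * (n0 - 1)) if n0 > 1 else np.nan
    return out


def bootstrap_auc_ci(scores, labels, n_boot: int = 10_000, level: float = 0.95,
                     seed: int | np.random.Generator = 0) -> tuple[float, float, dict]:
    """BCa bootstrap confidence interval for the empirical AUC.

    Resampling is stratified by class (class sizes fixed); the bias
    correction comes from the bootstrap distribution's position relative
    to the point estimate, the acceleration from jackknife skewness.  A
    degenerate bootstrap distribution falls back to the percentile
    interval and is flagged.
    """
    scores = np.asarray(scores, dtype=float)
    y = np.asarray(labels).astype(int)
    if len(y) < 5:
        raise ValueError("need at least 5 observations for a bootstrap CI")
    pos, neg = scores[y == 1], scores[y == 0]
    if len(pos) == 0 or len(neg) == 0:
        raise ValueError("both classes must be present")
    theta = empirical_auc(scores, y)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    bpos = pos[rng.integers(0, len(pos), size=(n_boot, len(pos)))]
    bneg = neg[rng.integers(0, len(neg), size=(n_boot, len(neg)))]
    boots = _auc_rows(bpos, bneg)
    info = {"degenerate": False, "theta": theta}
    alpha = 1.0 - level
    if np.all(boots == boots[0]):
        info["degenerate"] = True
        return float(boots[0]), float(boots[0]), info
    # canonical bias correction: fraction of the bootstrap distribution
    # strictly below the point estimate
    frac = np.sum(boots < theta) / n_boot
    frac = np.clip(frac, 1.0 / (2 * n_boot), 1 - 1.0 / (2 * n_boot))
    z0 = sps.norm.ppf(frac)
    jack = _jackknife_auc(pos, neg)
    jack = jack[np.isfinite(jack)]
    d = jack.mean() - jack
    denom = (d**2).sum() ** 1.5
    a = (d**3).sum() / (6.0 * denom) if denom > 0 else 0.0
    z = sps.norm.ppf([alpha / 2, 1 - alpha / 2])
    adj = sps.norm.cdf(z0 + (z0 + z) / (1 - a * (z0 + z)))
    lo, hi = np.quantile(boots, adj)
    return float(lo), float(hi), info


def profile_group_comparison(
    profile_table: pd.DataFrame,
    labels: pd.DataFrame,
    contrast: str,
    q_level: float = 0.05,
    family: str = "per_panel",
    auc_ci: bool = True,
    n_boot: int = 10_000,
    seed: int = 0,
) -> pd.DataFrame:
    """Position-wise two-group comparison over a tidy profile table.

    ``profile_table`` columns: animal_id, side, day, parameter,
    position_mm, wmean, wsd.  Returns the tidy statistics grid with one
    row per (side, day, parameter, statistic, position): U, p, BH q,
    reject flag, single-parameter AUC (positive class scored by the raw
    value) and, optionally, its BCa CI.

    ``family="per_panel"`` applies BH within each (side, day, statistic)
    family spanning positions x parameters; ``family="global"`` adjusts
    all cells of the contrast jointly.
    """
    y = contrast_labels(labels, contrast)
    long = profile_table.melt(
        id_vars=["animal_id", "side", "day", "parameter", "position_mm"],
        value_vars=["wmean", "wsd"], var_name="statistic", value_name="value")
    long["statistic"] = long["statistic"].map({"wmean": "mean", "wsd": "SD"})
    long = long[long["animal_id"].isin(y.index)]
    # dropna=True removes the empty cells of the acquisition design
    # (no diffusion at D2); partially missing cells are caught below
    wide = long.pivot_table(
        index="animal_id",
        columns=["side", "day", "parameter", "statistic", "position_mm"],
        values="value", dropna=True)
    yv = y.loc[wide.index].to_numpy()
    if (yv == 1).sum() < 2 or (yv == 0).sum() < 2:
        raise ValueError("need >= 2 animals per group")
    X = wide.to_numpy()
    if np.any(~np.isfinite(X)):
        raise ValueError("profiles do not share a common position grid "
                         "(cells missing for some animals)")
    keep = np.ones(X.shape[1], dtype=bool)
    cells = wide.columns.to_frame(index=False).loc[keep].reset_index(drop=True)
    Xa, Xb = X[:, keep][yv == 0], X[:, keep][yv == 1]

    if len(yv) <= 20:
        stats_p = np.array([mann_whitney_u(Xa[:, j], Xb[:, j])
                            for j in range(Xa.shape[1])])
        U, p = stats_p[:, 0], stats_p[:, 1]
    else:
        res = sps.mannwhitneyu(Xa, Xb, axis=0, alternative="two-sided",
                               method="asymptotic", use_continuity=True)
        U, p = np.asarray(res.statistic, float), np.minimum(res.pvalue, 1.0)

    out = cells.copy()
    out["n_neg"], out["n_pos"] = int((yv == 0).sum()), int((yv == 1).sum())
    out["U"], out["p"] = U, p
    out["q"] = np.nan
    out["reject"] = False
    if family == "global":
        fams = [np.ones(len(out), dtype=bool)]
    elif family == "per_panel":
        fams = [(
            (out["side"] == s) & (out["day"] == d) & (out["statistic"] == st)
        ).to_numpy() for s, d, st in
            out[["side", "day", "statistic"]].drop_duplicates().itertuples(index=False)]
    else:
        raise ValueError("family must be 'per_panel' or 'global'")
    for f in fams:
        q_adj, rej = bh_fdr(out.loc[f, "p"].to_numpy(), q_level)
        out.loc[f, "q"] = q_adj
        out.loc[f, "reject"] = rej

    pos_block, neg_block = X[:, keep][yv == 1], X[:, keep][yv == 0]
    out["auc"] = _auc_rows(pos_block.T, neg_block.T)
    if auc_ci:
        rng = np.random.default_rng(seed)
        los, his = np.empty(len(out)), np.empty(len(out))
        for j in range(len(out)):
            los[j], his[j], _ = bootstrap_auc_ci(
                X[:, keep][:, j], yv, n_boot=n_boot, seed=rng)
        out["auc_lo"], out["auc_hi"] = los, his
    else:
        out["auc_lo"] = out["auc_hi"] = np.nan
    return out
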