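"""Elastic-net prognostic models with nested leave-one-out cross-validation.

At each axis position all 48 MRI predictors (mean and SD of every
parameter at every acquisition day) enter a class-weighted elastic-net
logistic regression (equal LASSO/ridge mixing).  The outer loop is
leave-one-out over animals; inside each outer training set the
predictors are standardized, a regularization path is fitted, and the
inner cross-validation picks the strength minimizing binomial deviance.
Held-out probabilities are pooled over the outer folds into one
cross-validated AUC with a BCa bootstrap confidence interval, and
fold-averaged standardized coefficients rank predictor importance.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import PARAMETER_DAYS, SIDES
from .enet import binomial_deviance_path, enet_logistic_path, lambda_path, predict_proba
from .stats import bootstrap_auc_ci, contrast_labels, empirical_auc

#: Canonical predictor order: every (parameter, day) x {mean, SD}.
FEATURE_NAMES = tuple(f"{p}_{d}_{stat}" for p, d in PARAMETER_DAYS
                      for stat in ("mean", "SD"))


def assemble_features(profile_table: pd.DataFrame, position: float,
                      side: str) -> pd.DataFrame:
    """The animals x 48-predictor matrix at one axis position.

    Animals missing any cell are dropped (recorded in
    ``df.attrs["dropped"]``); fewer than 3 complete animals is an error.
    Column order is identical at every position.
    """
    sel = profile_table[
        (profile_table["side"] == side)
        & np.isclose(profile_table["position_mm"].to_numpy(dtype=float), position)
    ]
    if sel.empty:
        raise ValueError(f"no profile rows at side={side!r}, position={position}")
    long = sel.melt(id_vars=["animal_id", "day", "parameter"],
                    value_vars=["wmean", "wsd"], var_name="stat", value_name="value")
    long["stat"] = long["stat"].map({"wmean": "mean", "wsd": "SD"})
    long["feature"] = (long["parameter"] + "_" + long["day"] + "_" + long["stat"])
    wide = long.pivot_table(index="animal_id", columns="feature", values="value",
                            dropna=False)
    wide = wide.reindex(columns=list(FEATURE_NAMES))
    complete = wide.notna().all(axis=1)
    dropped = list(wide.index[~complete])
    wide = wide.loc[complete]
    if len(wide) < 3:
        raise ValueError(f"fewer than 3 animals with complete features "
                         f"(dropped: {dropped})")
    wide.attrs["dropped"] = dropped
    return wide


def class_weights(labels) -> np.ndarray:
    """Inverse-class-frequency observation weights, normalized to sum n."""
    y = np.asarray(labels).astype(int)
    n = len(y)
    n1 = int(y.sum())
    if n1 == 0 or n1 == n:
        raise ValueError("both classes must be present")
    w = np.where(y == 1, n / (2.0 * n1), n / (2.0 * (n - n1)))
    return w


@dataclass
class ModelResult:
    """Pooled LOOCV output of one classification task at one position."""

    probs: np.ndarray                  # one out-of-fold probability per animal
    y: np.ndarray
    animal_ids: list
    auc: float
    feature_names: list
    coefs: np.ndarray                  # (n_outer_folds, p) standardized coefficients
    fold_lambdas: np.ndarray
    ci_lo: float = np.nan
    ci_hi: float = np.nan
    position: float | None = None
    side: str | None = None
    contrast: str | None = None
    flags: dict = field(default_factory=dict)


def _inner_folds(y: np.ndarray, inner: str, n_inner: int,
                 rng: np.random.Generator) -> np.ndarray:
    n = len(y)
    if inner == "loo":
        return np.arange(n)
    if inner != "kfold":
        raise ValueError("inner must be 'loo' or 'kfold'")
    # stratified assignment: shuffle within class, deal round-robin
    fold_id = np.empty(n, dtype=np.int64)
    for cls in (0, 1):
        idx = np.where(y == cls)[0]
        rng.shuffle(idx)
        fold_id[idx] = np.arange(len(idx)) % n_inner
    return fold_id


def nested_loocv_elastic_net(
    X,
    y,
    mixing: float = 0.5,
    seed: int = 0,
    inner: str = "loo",
    n_inner: int = 10,
    n_lambda: int = 100,
    lambda_min_ratio: float = 1e-4,
    standardize: str = "per_fold",
    animal_ids=None,
) -> ModelResult:
    """Nested (externally validated) LOOCV elastic-net logistic regression.

    Outer loop: leave-one-animal-out.  Within each outer training set:
    class weights and standardization statistics are recomputed (no
    leakage into the held-out animal; ``standardize="global"`` exists
    only for leakage-differential testing), the lambda path is fitted
    with equal LASSO/ridge mixing by default, and the inner CV (LOO by
    default, seeded stratified k-fold optionally) selects the strength
    minimizing weighted binomial deviance, ties resolving to the
    strongest regularization.  Zero-variance training columns are
    dropped for that fold.  The random seed affects only the optional
    inner fold assignment; LOO itself is deterministic.
    """
    if isinstance(X, pd.DataFrame):
        feature_names = list(X.columns)
        if animal_ids is None:
            animal_ids = list(X.index)
        X = X.to_numpy(dtype=float)
    else:
        X = np.asarray(X, dtype=float)
        feature_names = [f"x{j}" for j in range(X.shape[1])]
    y = np.asarray(y).astype(np.float64)
    n, p = X.shape
    if animal_ids is None:
        animal_ids = list(range(n))
    if n < 6:
        raise ValueError("need at least 6 animals")
    if (y == 1).sum() < 2 or (y == 0).sum() < 2:
        raise ValueError("need at least 2 animals per class")

    if standardize == "global":
        mu_g, sd_g = X.mean(axis=0), X.std(axis=0)
    elif standardize != "per_fold":
        raise ValueError("standardize must be 'per_fold' or 'global'")

    rng = np.random.default_rng(seed)
    probs = np.empty(n)
    coefs = np.zeros((n, p))
    fold_lambdas = np.full(n, np.nan)
    n_skipped_inner = 0
    for i in range(n):
        tr = np.ones(n, dtype=bool)
        tr[i] = False
        Xtr, ytr = X[tr], y[tr]
        w = class_weights(ytr)
        if standardize == "per_fold":
            mu, sd = Xtr.mean(axis=0), Xtr.std(axis=0)
        else:
            mu, sd = mu_g, sd_g
        keep = sd > 0
        if not np.any(keep):
            # no informative columns: intercept-only model at the
            # weighted training prevalence (exactly 1/2 under
            # inverse-frequency class weights)
            probs[i] = round(float(np.sum(w * ytr) / np.sum(w)), 12)
            continue
        Xs = (Xtr[:, keep] - mu[keep]) / sd[keep]
        xi = (X[i, keep] - mu[keep]) / sd[keep]
        lambdas = lambda_path(Xs, ytr, w, mixing, n_lambda, lambda_min_ratio)

        fold_id = _inner_folds(ytr.astype(int), inner, n_inner, rng)
        dev = np.zeros(len(lambdas))
        used = 0
        for f in np.unique(fold_id):
            it = fold_id != f
            yt = ytr[it]
            if yt.min() == yt.max():
                n_skipped_inner += 1
                continue
            wt = w[it] * (it.sum() / w[it].sum())
            b0s, betas = enet_logistic_path(np.ascontiguousarray(Xs[it]), yt, wt,
                                            mixing, lambdas)
            dev += binomial_deviance_path(b0s, betas,
                                          np.ascontiguousarray(Xs[~it]),
                                          ytr[~it], w[~it])
            used += 1
        if used == 0:
            raise ValueError("every inner fold was single-class; cohort too small")
        k = int(np.argmin(dev))  # first minimum = largest lambda among ties
        b0s, betas = enet_logistic_path(np.ascontiguousarray(Xs), ytr, w,
                                        mixing, lambdas)
        probs[i] = float(predict_proba(b0s[k], betas[k], xi[None, :])[0])
        coefs[i, keep] = betas[k]
        fold_lambdas[i] = lambdas[k]

    # report probabilities to 6 decimals: mathematically tied predictions
    # (e.g. the intercept-only limit at strong regularization) must rank
    # as ties rather than in the order of optimizer round-off
    probs = np.round(probs, 6)
    auc = empirical_auc(probs, y.astype(int))
    return ModelResult(
        probs=probs, y=y.astype(int), animal_ids=animal_ids, auc=auc,
        feature_names=feature_names, coefs=coefs, fold_lambdas=fold_lambdas,
        flags={"n_skipped_inner_folds": n_skipped_inner},
    )


def model_auc_with_ci(result: ModelResult, n_boot: int = 10_000,
                      seed: int = 0) -> tuple[float, float, float]:
    """Pooled AUC with BCa CI by resampling (label, probability) pairs."""
    lo, hi, info = bootstrap_auc_ci(result.probs, result.y, n_boot=n_boot, seed=seed)
    result.ci_lo, result.ci_hi = lo, hi
    if info.get("degenerate"):
        result.flags["bootstrap_degenerate"] = True
    return result.auc, lo, hi


def format_auc(result: ModelResult) -> str:
    """The reporting format 'AUC (95% confidence interval lo-hi)'."""
    return (f"AUC {result.auc:.2f} "
            f"(95% confidence interval {result.ci_lo:.2f}-{result.ci_hi:.2f})")


def coefficient_importance(results, k: int = 5) -> pd.DataFrame:
    """Fold-averaged standardized coefficients, ranked by importance.

    ``results`` is one ModelResult or a list over positions.  Returns a
    predictors x positions table of fold-averaged coefficients whose
    ``attrs["top_predictors"]`` lists the k predictors with the largest
    absolute averaged coefficient at any position (all-zero predictors
    are never ranked; an entirely zero table is flagged).
    """
    if isinstance(results, ModelResult):
        results = [results]
    if not results:
        raise ValueError("no model results supplied")
    cols = {}
    for r in results:
        if r.coefs.size == 0:
            raise ValueError("model result has an empty coefficient matrix")
        cols[r.position if r.position is not None else 0.0] = r.coefs.mean(axis=0)
    table = pd.DataFrame(cols, index=list(results[0].feature_names))
    peak = table.abs().max(axis=1)
    nonzero = peak[peak > 0]
    top = list(nonzero.sort_values(ascending=False).index[:k])
    table.attrs["top_predictors"] = top
    table.attrs["all_zero"] = len(nonzero) == 0
    return table


def volume_model(volumes: pd.DataFrame, labels, seed: int = 0,
                 **kwargs) -> ModelResult:
    """Elastic-net LOOCV on the 6 hippocampal volumes (2 sides x 3 days)."""
    if volumes.isna().any().any():
        raise ValueError("volume table must be complete")
    y = np.asarray(labels).astype(int)
    res = nested_loocv_elastic_net(volumes, y, seed=seed, **kwargs)
    res.contrast = "volume"
    return res


def position_sweep(
    profile_table: pd.DataFrame,
    labels: pd.DataFrame,
    contrast: str,
    positions=None,
    sides=SIDES,
    seed: int = 0,
    n_boot: int = 10_000,
    **model_kwargs,
) -> tuple[list[ModelResult], pd.DataFrame]:
    """One nested-LOOCV model per (side, position), with the
    CI-lower-bound > 0.5 discriminability flag per position."""
    y_all = contrast_labels(labels, contrast)
    if positions is None:
        positions = np.unique(profile_table["position_mm"].to_numpy(dtype=float))
    rng = np.random.default_rng(seed)
    results, rows = [], []
    for side in sides:
        for pos in positions:
            feats = assemble_features(profile_table, float(pos), side)
            ids = [a for a in feats.index if a in y_all.index]
            Xdf = feats.loc[ids]
            y = y_all.loc[ids].to_numpy()
            res = nested_loocv_elastic_net(
                Xdf, y, seed=int(rng.integers(2**31 - 1)), **model_kwargs)
            res.position, res.side, res.contrast = float(pos), side, contrast
            model_auc_with_ci(res, n_boot=n_boot, seed=int(rng.integers(2**31 - 1)))
            results.append(res)
            rows.append({
                "contrast": contrast, "side": side, "position_mm": float(pos),
                "auc": res.auc, "auc_lo": res.ci_lo, "auc_hi": res.ci_hi,
                "discriminates": bool(res.ci_lo > 0.5),
            })
    return results, pd.DataFrame(rows)
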