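"""Elastic-net prognostic modelling with nested LOOCV."""

import numpy as np
import pandas as pd
import pytest

from hippoaxis.enet import enet_logistic_path, lambda_path
from hippoaxis.model import (
    FEATURE_NAMES,
    assemble_features,
    class_weights,
    coefficient_importance,
    model_auc_with_ci,
    nested_loocv_elastic_net,
    position_sweep,
    volume_model,
)
from hippoaxis.profiles import cohort_profiles
from hippoaxis.stats import contrast_labels, empirical_auc

FAST = dict(inner="kfold", n_inner=4, n_lambda=20, lambda_min_ratio=1e-2)


class TestFeatures:
    def test_full_cohort_gives_48_canonical_columns(self, tiny_cohort):
        records, _ = tiny_cohort
        table = cohort_profiles(records, axis_mode="true", spacing=2.0)
        feats = assemble_features(table, 6.0, "ipsi")
        assert list(feats.columns) == list(FEATURE_NAMES)
        assert len(feats.columns) == 48
        assert len(feats) == len(records)
        assert feats.notna().all().all()

    def test_column_order_identical_across_positions(self, tiny_cohort):
        records, _ = tiny_cohort
        table = cohort_profiles(records, axis_mode="true", spacing=2.0)
        cols = [tuple(assemble_features(table, p, "contra").columns)
                for p in (2.0, 6.0, 10.0)]
        assert cols[0] == cols[1] == cols[2]

    def test_animal_with_missing_cell_dropped(self, tiny_cohort):
        records, _ = tiny_cohort
        table = cohort_profiles(records, axis_mode="true", spacing=2.0)
        drop_id = records[0].animal_id
        broken = table[~((table["animal_id"] == drop_id)
                         & (table["parameter"] == "T2")
                         & (table["day"] == "D2"))]
        feats = assemble_features(broken, 6.0, "ipsi")
        assert drop_id not in feats.index
        assert feats.attrs["dropped"] == [drop_id]

    def test_too_few_animals_rejected(self, tiny_cohort):
        records, _ = tiny_cohort
        table = cohort_profiles(records[:2], axis_mode="true", spacing=2.0)
        with pytest.raises(ValueError, match="fewer than 3"):
            assemble_features(table, 6.0, "ipsi")


class TestClassWeights:
    def test_balanced_groups_unit_weights(self):
        assert np.allclose(class_weights([0] * 10 + [1] * 10), 1.0)

    def test_imbalanced_cohort_ratio_and_total(self):
        y = np.array([0] * 16 + [1] * 68)
        w = class_weights(y)
        assert w.sum() == pytest.approx(84.0)
        assert w[0] / w[-1] == pytest.approx(68 / 16)

    def test_row_order_invariance(self, rng):
        y = rng.integers(0, 2, 30)
        y[:2] = [0, 1]
        perm = rng.permutation(30)
        assert np.allclose(class_weights(y)[perm], class_weights(y[perm]))

    def test_single_class_rejected(self):
        with pytest.raises(ValueError, match="classes"):
            class_weights([1, 1, 1])


class TestSolver:
    def test_matches_sklearn_at_matched_penalty(self, rng):
        from sklearn.linear_model import LogisticRegression
        n, p = 60, 10
        X = rng.standard_normal((n, p))
        y = (rng.random(n) < 0.5).astype(float)
        y[:3] = [0, 1, 1]
        w = class_weights(y.astype(int))
        lams = lambda_path(X, y, w, 0.5, 30)
        b0s, betas = enet_logistic_path(X, y, w, 0.5, lams)
        k = 15
        clf = LogisticRegression(solver="saga", l1_ratio=0.5,
                                 C=1.0 / (n * lams[k]), max_iter=100000,
                                 tol=1e-10)
        clf.fit(X, y, sample_weight=w)
        assert np.abs(clf.coef_[0] - betas[k]).max() < 1e-3
        assert abs(clf.intercept_[0] - b0s[k]) < 1e-3

    def test_weight_rescaling_is_a_no_op(self, rng):
        n, p = 40, 8
        X = rng.standard_normal((n, p))
        y = (rng.random(n) < 0.5).astype(float)
        y[:2] = [0, 1]
        w = class_weights(y.astype(int))
        lams = lambda_path(X, y, w, 0.5, 20)
        assert np.allclose(lams, lambda_path(X, y, 2 * w, 0.5, 20))
        b0a, ba = enet_logistic_path(X, y, w, 0.5, lams)
        b0b, bb = enet_logistic_path(X, y, 2 * w, 0.5, lams)
        assert np.allclose(ba, bb) and np.allclose(b0a, b0b)

    def test_lambda_max_zeroes_all_coefficients(self, rng):
        X = rng.standard_normal((50, 6))
        y = (rng.random(50) < 0.4).astype(float)
        y[:2] = [0, 1]
        w = class_weights(y.astype(int))
        lams = lambda_path(X, y, w, 0.5, 5)
        _, betas = enet_logistic_path(X, y, w, 0.5, lams[:1] * 1.0001)
        assert np.allclose(betas[0], 0.0)


class TestNestedLOOCV:
    def test_perfectly_separating_column_gives_auc_one(self, rng):
        n = 24
        y = np.array([0] * 10 + [1] * 14)
        X = rng.standard_normal((n, 6)) * 0.05
        X[:, 2] = y * 3.0 + rng.normal(0, 0.05, n)
        res = nested_loocv_elastic_net(X, y, seed=0, **FAST)
        assert res.auc == 1.0

    def test_constant_predictors_give_prevalence_probs_and_half_auc(self):
        X = np.ones((16, 5))
        y = np.array([0] * 6 + [1] * 10)
        res = nested_loocv_elastic_net(X, y, seed=0)
        assert np.allclose(res.probs, 0.5)
        assert res.auc == 0.5

    def test_one_probability_per_animal_and_coef_rows_per_fold(self, rng):
        n = 20
        X = rng.standard_normal((n, 4))
        y = np.array([0, 1] * 10)
        res = nested_loocv_elastic_net(X, y, seed=0, **FAST)
        assert res.probs.shape == (n,)
        assert res.coefs.shape == (n, 4)
        assert 0.0 <= res.auc <= 1.0

    def test_pooled_auc_invariant_to_monotone_transform(self, rng):
        n = 30
        X = rng.standard_normal((n, 6))
        y = np.array([0, 1] * 15)
        res = nested_loocv_elastic_net(X, y, seed=1, **FAST)
        transformed = 1.0 / (1.0 + np.exp(-(3.0 * res.probs + 1.0)))
        assert empirical_auc(transformed, y) == pytest.approx(res.auc)

    def test_per_fold_standardization_differs_from_global_leakage(self, rng):
        # deliberately leaking full-sample standardization must change
        # the out-of-fold probabilities
        n = 26
        X = rng.standard_normal((n, 8))
        y = np.array([0] * 13 + [1] * 13)
        X[:, 0] += y * 0.8
        res_fold = nested_loocv_elastic_net(X, y, seed=2, **FAST)
        res_leak = nested_loocv_elastic_net(X, y, seed=2, standardize="global",
                                            **FAST)
        assert not np.allclose(res_fold.probs, res_leak.probs)

    def test_injected_predictor_recovered_in_importance(self, rng):
        hits = 0
        for seed in range(10):
            r = np.random.default_rng(seed)
            n = 60
            y = np.array([0] * 30 + [1] * 30)
            X = r.standard_normal((n, 12))
            X[:, 7] += y * 1.5  # standardized effect size 1.5
            res = nested_loocv_elastic_net(X, y, seed=seed, **FAST)
            table = coefficient_importance(res, k=3)
            hits += "x7" in table.attrs["top_predictors"]
        assert hits >= 9

    def test_too_small_or_single_class_rejected(self, rng):
        with pytest.raises(ValueError, match="at least 6"):
            nested_loocv_elastic_net(rng.standard_normal((5, 3)),
                                     [0, 0, 1, 1, 1])
        with pytest.raises(ValueError, match="per class"):
            nested_loocv_elastic_net(rng.standard_normal((8, 3)),
                                     [0] + [1] * 7)


class TestReporting:
    def test_auc_ci_format_and_determinism(self, rng):
        from hippoaxis.model import format_auc
        n = 30
        X = rng.standard_normal((n, 5))
        y = np.array([0, 1] * 15)
        X[:, 0] += y
        res = nested_loocv_elastic_net(X, y, seed=0, **FAST)
        auc1, lo1, hi1 = model_auc_with_ci(res, n_boot=500, seed=42)
        auc2, lo2, hi2 = model_auc_with_ci(res, n_boot=500, seed=42)
        assert (auc1, lo1, hi1) == (auc2, lo2, hi2)
        assert lo1 <= auc1 <= hi1
        text = format_auc(res)
        assert "AUC" in text and "95% confidence interval" in text

    def test_importance_toy_average(self):
        from hippoaxis.model import ModelResult
        res = ModelResult(probs=np.zeros(2), y=np.array([0, 1]),
                          animal_ids=[0, 1], auc=0.5,
                          feature_names=["a", "b"],
                          coefs=np.array([[1.0, 0.0], [0.0, 1.0]]),
                          fold_lambdas=np.zeros(2))
        table = coefficient_importance(res)
        assert np.allclose(table.to_numpy().ravel(), [0.5, 0.5])

    def test_all_zero_coefficients_flagged(self):
        from hippoaxis.model import ModelResult
        res = ModelResult(probs=np.zeros(2), y=np.array([0, 1]),
                          animal_ids=[0, 1], auc=0.5,
                          feature_names=["a", "b"],
                          coefs=np.zeros((2, 2)), fold_lambdas=np.zeros(2))
        table = coefficient_importance(res)
        assert table.attrs["all_zero"]
        assert table.attrs["top_predictors"] == []


class TestVolumeModel:
    def test_atrophy_separates_groups(self, tiny_cohort):
        from hippoaxis.profiles import cohort_volumes
        records, labels = tiny_cohort  # 20% ipsilateral D21 atrophy in TBI
        vols = cohort_volumes(records)
        y = contrast_labels(labels, "sham_tbi")
        res = volume_model(vols.loc[y.index], y.to_numpy(), seed=0, **FAST)
        assert res.auc > 0.9

    def test_no_atrophy_null_ci_spans_half(self, rng):
        # size jitter only, no group effect: CI must straddle 0.5
        n = 24
        base = rng.lognormal(np.log(40.0), 0.05, n)
        vols = pd.DataFrame(
            {f"vol_{s}_{d}": base * rng.lognormal(0, 0.01, n)
             for s in ("ipsi", "contra") for d in ("D2", "D7", "D21")})
        y = np.array([0] * 10 + [1] * 14)
        res = volume_model(vols, y, seed=0, **FAST)
        model_auc_with_ci(res, n_boot=500, seed=1)
        assert res.ci_lo <= 0.5 <= res.ci_hi

    def test_constant_volumes_give_half(self):
        vols = pd.DataFrame(np.ones((12, 6)),
                            columns=[f"v{i}" for i in range(6)])
        y = np.array([0, 1] * 6)
        res = volume_model(vols, y, seed=0)
        assert res.auc == 0.5

    def test_incomplete_table_rejected(self):
        vols = pd.DataFrame(np.ones((8, 6)))
        vols.iloc[0, 0] = np.nan
        with pytest.raises(ValueError, match="complete"):
            volume_model(vols, np.array([0, 1] * 4))


class TestPositionSweep:
    def test_sweep_produces_curve_with_flags(self, tiny_cohort):
        records, labels = tiny_cohort
        table = cohort_profiles(records, axis_mode="true", spacing=2.0)
        results, curve = position_sweep(
            table, labels, "sham_tbi", positions=[4.0, 8.0], seed=0,
            n_boot=200, **FAST)
        assert len(results) == 4  # 2 sides x 2 positions
        assert set(curve.columns) >= {"side", "position_mm", "auc",
                                      "auc_lo", "auc_hi", "discriminates"}
        assert curve["discriminates"].dtype == bool
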