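"""Synthetic cohort generator: geometry, effects, signals, labels."""

import math

import numpy as np
import pytest

from hippoaxis.core import VoxelGrid
from hippoaxis.synthetic import (
    AnimalLabels,
    CohortConfig,
    EffectSpec,
    default_dwi_protocol,
    generate_cohort,
    generate_mask,
    generate_parameter_values,
    straight_centerline,
    synthesize_dwi,
    synthesize_echo_series,
    tensor_from_eigenvalues,
    BASELINES_DEFAULT,
    NOISE_SDS_DEFAULT,
)


class TestGenerateMask:
    def test_cylinder_volume_matches_analytic(self, straight_tube):
        vol = straight_tube["mask"].sum() * straight_tube["grid"].voxel_volume
        analytic = math.pi * 1.5**2 * 12.0
        assert abs(vol - analytic) / analytic < 0.05

    def test_deterministic(self, straight_tube):
        grid, line = straight_tube["grid"], straight_tube["centerline"]
        m1, _ = generate_mask(grid, line, 1.5, seed=7)
        m2, _ = generate_mask(grid, line, 1.5, seed=7)
        assert np.array_equal(m1, m2)

    def test_arc_voxels_lie_within_radius_of_centerline(self, c_arc_tube):
        grid, mask = c_arc_tube["grid"], c_arc_tube["mask"]
        line, rprof = c_arc_tube["centerline"], c_arc_tube["radius_profile"]
        centers = grid.voxel_centers(mask)
        # brute-force distance to a densely resampled copy of the curve
        s = np.linspace(0.0, line.length, 60_000)
        dense = line.point_at(s)
        from scipy.spatial import cKDTree
        dist, idx = cKDTree(dense).query(centers)
        half_diag = np.linalg.norm(np.asarray(grid.voxel_dims)) / 2
        assert np.all(dist <= rprof(s[idx]) + half_diag)

    def test_curve_exiting_grid_rejected(self):
        grid = VoxelGrid((20, 20, 10), (0.15, 0.15, 0.5))
        line = straight_centerline([0.5, 1.5, 2.5], [1, 0, 0], 12.0)
        with pytest.raises(ValueError, match="exits"):
            generate_mask(grid, line, 1.0)

    def test_subresolution_radius_rejected(self, straight_tube):
        with pytest.raises(ValueError, match="resolvable"):
            generate_mask(straight_tube["grid"], straight_tube["centerline"], 0.2)


class TestParameterValues:
    def _arc(self, n=500, length=12.0, seed=0):
        return np.random.default_rng(seed).uniform(0, length, n)

    def test_zero_noise_no_effects_is_constant_baseline(self):
        arc = self._arc()
        lab = AnimalLabels("a1", "TBI", "TBI-", "CI-")
        vals = generate_parameter_values(
            arc, lab, "ipsi", "D7", ["T2"], [], BASELINES_DEFAULT,
            {p: 0.0 for p in NOISE_SDS_DEFAULT}, np.random.default_rng(0))
        assert np.all(vals["T2"] == BASELINES_DEFAULT["T2"])

    def test_windowed_effect_applies_only_to_matching_animals(self):
        arc = self._arc()
        eff = [EffectSpec("T2", "D7", "ipsi", "TBI", (0.0, 3.0), +10.0)]
        zero_noise = {p: 0.0 for p in NOISE_SDS_DEFAULT}
        tbi = generate_parameter_values(
            arc, AnimalLabels("t", "TBI", "TBI-", "CI-"), "ipsi", "D7",
            ["T2"], eff, BASELINES_DEFAULT, zero_noise, np.random.default_rng(0))
        sham = generate_parameter_values(
            arc, AnimalLabels("s", "sham"), "ipsi", "D7",
            ["T2"], eff, BASELINES_DEFAULT, zero_noise, np.random.default_rng(0))
        base = BASELINES_DEFAULT["T2"]
        inside = arc < 3.0
        assert np.allclose(tbi["T2"][inside], base + 10.0)
        # beyond the window plus its 0.5-mm ramp the effect vanishes
        assert np.allclose(tbi["T2"][arc > 3.5], base)
        assert np.allclose(sham["T2"], base)

    def test_unknown_parameter_or_day_rejected(self):
        arc = self._arc(50)
        lab = AnimalLabels("t", "TBI", "TBI-", "CI-")
        with pytest.raises(ValueError, match="unknown parameter"):
            generate_parameter_values(
                arc, lab, "ipsi", "D7", ["T2"],
                [EffectSpec("bogus", "D7", "ipsi", "TBI", (0, 1), 1.0)],
                BASELINES_DEFAULT, NOISE_SDS_DEFAULT, np.random.default_rng(0))
        with pytest.raises(ValueError, match="unknown day"):
            generate_parameter_values(
                arc, lab, "ipsi", "D7", ["T2"],
                [EffectSpec("T2", "D99", "ipsi", "TBI", (0, 1), 1.0)],
                BASELINES_DEFAULT, NOISE_SDS_DEFAULT, np.random.default_rng(0))

    def test_seeds_differ_only_in_noise(self):
        arc = self._arc()
        lab = AnimalLabels("t", "TBI", "TBI-", "CI-")
        eff = [EffectSpec("T2", "D7", "ipsi", "TBI", (0.0, 3.0), +10.0)]
        out = []
        for seed in (1, 2):
            _, truth = generate_parameter_values(
                arc, lab, "ipsi", "D7", ["T2"], eff, BASELINES_DEFAULT,
                NOISE_SDS_DEFAULT, np.random.default_rng(seed), return_truth=True)
            out.append(truth["T2"])
        assert np.array_equal(out[0], out[1])

    def test_outside_window_values_distributed_identically(self):
        # two-sample test on values beyond the window+ramp must not reject
        from scipy.stats import mannwhitneyu
        arc = np.linspace(6.0, 12.0, 4000)
        eff = [EffectSpec("T2", "D7", "ipsi", "TBI", (0.0, 3.0), +10.0, 1.5)]
        tbi = generate_parameter_values(
            arc, AnimalLabels("t", "TBI", "TBI-", "CI-"), "ipsi", "D7",
            ["T2"], eff, BASELINES_DEFAULT, NOISE_SDS_DEFAULT,
            np.random.default_rng(3))
        sham = generate_parameter_values(
            arc, AnimalLabels("s", "sham"), "ipsi", "D7",
            ["T2"], eff, BASELINES_DEFAULT, NOISE_SDS_DEFAULT,
            np.random.default_rng(4))
        p = mannwhitneyu(tbi["T2"], sham["T2"]).pvalue
        assert p > 0.001


class TestEchoSeries:
    def test_closed_form_signal(self):
        s = synthesize_echo_series(np.array([100.0]), np.array([50.0]), [25.0, 50.0])
        assert s[0, 1] == pytest.approx(100.0 * math.exp(-1.0), rel=1e-12)

    def test_te_to_zero_limit_recovers_s0(self):
        te = np.array([1e-4, 1.0])
        s = synthesize_echo_series(np.array([100.0]), np.array([50.0]), te)
        assert s[0, 0] == pytest.approx(100.0, rel=1e-5)

    def test_nonpositive_relaxation_rejected(self):
        with pytest.raises(ValueError, match="positive"):
            synthesize_echo_series(np.array([100.0]), np.array([-5.0]), [10.0, 20.0])

    def test_bad_echo_times_rejected(self):
        with pytest.raises(ValueError):
            synthesize_echo_series(np.array([1.0]), np.array([50.0]), [20.0, 10.0])


class TestDWI:
    def test_isotropic_tensor_gives_direction_independent_signal(self):
        bvals, bvecs = default_dwi_protocol()
        D = np.array([1e-3, 1e-3, 1e-3, 0.0, 0.0, 0.0])
        sig = synthesize_dwi(D, np.array(100.0), bvals, bvecs)
        dw = sig[bvals > 0]
        assert np.allclose(dw, 100.0 * math.exp(-2.0), rtol=1e-12)
        assert np.allclose(sig[bvals == 0], 100.0)

    def test_non_unit_gradient_rejected(self):
        bvals = np.array([0.0, 2000.0] + [2000.0] * 6)
        bvecs = np.zeros((8, 3))
        bvecs[1:] = [1, 0, 0]
        bvecs[2] = [2, 0, 0]
        with pytest.raises(ValueError, match="unit norm"):
            synthesize_dwi(np.zeros(6), np.array(1.0), bvals, bvecs)

    def test_rician_option_changes_noise_model(self):
        bvals, bvecs = default_dwi_protocol()
        D = tensor_from_eigenvalues([1e-3, 1e-3, 1e-3])
        g = synthesize_dwi(D, np.array(0.0), bvals, bvecs, noise_sd=1.0, seed=0)
        r = synthesize_dwi(D, np.array(0.0), bvals, bvecs, noise_sd=1.0,
                           seed=0, rician=True)
        assert np.all(r >= 0)  # magnitude noise
        assert np.any(g < 0)


class TestCohort:
    def test_default_composition_counts(self):
        cfg = CohortConfig(n_sham=2, n_tbi=68, seed=5,
                           voxel_dims=(0.6, 0.6, 1.0), store_truth=False)
        _, labels = generate_cohort(cfg)
        tbi = labels[labels["group"] == "TBI"]
        assert (tbi["cognition"] == "CI+").sum() == 55
        assert (tbi["epilepsy"] == "TBI+").sum() == 15

    def test_zero_prevalence_all_negative(self):
        cfg = CohortConfig(n_sham=2, n_tbi=8, ci_prevalence=0.0,
                           epilepsy_prevalence=0.0, seed=1,
                           voxel_dims=(0.6, 0.6, 1.0), store_truth=False)
        _, labels = generate_cohort(cfg)
        tbi = labels[labels["group"] == "TBI"]
        assert (tbi["cognition"] == "CI-").all()
        assert (tbi["epilepsy"] == "TBI-").all()

    def test_prevalence_without_tbi_animals_rejected(self):
        with pytest.raises(ValueError, match="prevalence"):
            CohortConfig(n_sham=4, n_tbi=0)

    def test_label_counts_match_prevalence_across_seeds(self):
        for seed in range(8):
            cfg = CohortConfig(n_sham=2, n_tbi=20, ci_prevalence=0.65,
                               epilepsy_prevalence=0.3, seed=seed,
                               voxel_dims=(0.6, 0.6, 1.0), store_truth=False)
            _, labels = generate_cohort(cfg)
            tbi = labels[labels["group"] == "TBI"]
            assert (tbi["cognition"] == "CI+").sum() == 13  # round(0.65*20)
            assert (tbi["epilepsy"] == "TBI+").sum() == 6   # round(0.3*20)

    def test_acquisition_design_of_maps(self, tiny_cohort):
        records, _ = tiny_cohort
        rec = records[0]
        for side in ("ipsi", "contra"):
            for day in ("D2", "D7", "D21"):
                assert (side, day) in rec.masks
                assert (side, "T2", day) in rec.values
            assert (side, "FA", "D7") in rec.values
            assert (side, "FA", "D2") not in rec.values

    def test_sham_animals_carry_no_outcome_labels(self, tiny_cohort):
        _, labels = tiny_cohort
        sham = labels[labels["group"] == "sham"]
        assert (sham["epilepsy"] == "").all()
        assert (sham["cognition"] == "").all()

    def test_bit_identical_reproduction(self):
        cfg = CohortConfig(n_sham=2, n_tbi=3, seed=9, voxel_dims=(0.4, 0.4, 0.5))
        rec1, lab1 = generate_cohort(cfg)
        rec2, lab2 = generate_cohort(cfg)
        assert lab1.equals(lab2)
        for r1, r2 in zip(rec1, rec2):
            for key in r1.masks:
                assert np.array_equal(r1.masks[key], r2.masks[key])
            for key in r1.values:
                assert np.array_equal(r1.values[key], r2.values[key])

    def test_tbi_ipsilateral_atrophy_shrinks_masks(self, tiny_cohort):
        records, _ = tiny_cohort
        tbi = next(r for r in records if r.labels.group == "TBI")
        v2 = tbi.masks[("ipsi", "D2")].sum()
        v21 = tbi.masks[("ipsi", "D21")].sum()
        assert v21 < v2
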