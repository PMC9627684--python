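import itertools
import math

import numpy as np
import pandas as pd
import pytest

from upvs import (compare_groups_at_ga, lmm_trajectories, mwu_compare,
                  pca_characteristics, simulate_lmm_cohort, spearman_matrix,
                  synth_cohort)
from upvs.stats import CHARACTERISTICS, assign_scheduled_week


def brute_force_mwu_p(x, y):
    """Exact two-sided p by enumerating all group assignments of the pooled data."""
    pooled = np.concatenate([x, y])
    n1 = len(x)
    ranks = pd.Series(pooled).rank().to_numpy()
    u_obs = ranks[:n1].sum() - n1 * (n1 + 1) / 2
    n = len(pooled)
    mean_u = n1 * (n - n1) / 2
    dev_obs = abs(u_obs - mean_u)
    hits = total = 0
    for idx in itertools.combinations(range(n), n1):
        u = ranks[list(idx)].sum() - n1 * (n1 + 1) / 2
        total += 1
        if abs(u - mean_u) >= dev_obs - 1e-12:
            hits += 1
    return hits / total


class TestSpearman:
    def test_monotone_transform_gives_rho_one(self):
        df = pd.DataFrame({"x": np.arange(1.0, 11.0)})
        df["y"] = df["x"] ** 3
        rho, _ = spearman_matrix(df, ["x", "y"])
        assert rho.loc["x", "y"] == pytest.approx(1.0)

    def test_reversal_gives_rho_minus_one(self):
        df = pd.DataFrame({"x": np.arange(10.0), "y": -np.arange(10.0)})
        rho, _ = spearman_matrix(df, ["x", "y"])
        assert rho.loc["x", "y"] == pytest.approx(-1.0)

    def test_invariant_under_strictly_monotone_transforms(self):
        rng = np.random.default_rng(0)
        x = rng.random(30)
        y = rng.random(30)
        base, _ = spearman_matrix(pd.DataFrame({"x": x, "y": y}), ["x", "y"])
        warped, _ = spearman_matrix(
            pd.DataFrame({"x": np.exp(5 * x), "y": np.arctan(y)}), ["x", "y"])
        assert warped.loc["x", "y"] == pytest.approx(base.loc["x", "y"], abs=1e-12)

    @pytest.mark.parametrize("seed", range(4))
    def test_small_sample_p_matches_exact_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        x = rng.permutation(5).astype(float)
        y = rng.permutation(5).astype(float)
        from scipy.stats import spearmanr
        rho_obs = spearmanr(x, y).statistic
        hits = sum(abs(spearmanr(x, p).statistic) >= abs(rho_obs) - 1e-12
                   for p in itertools.permutations(y))
        expected = hits / math.factorial(5)
        _, p = spearman_matrix(pd.DataFrame({"x": x, "y": y}), ["x", "y"])
        assert p.loc["x", "y"] == pytest.approx(expected, abs=1e-12)

    def test_constant_variable_flagged_nan(self):
        df = pd.DataFrame({"x": np.arange(10.0), "y": np.ones(10)})
        rho, _ = spearman_matrix(df, ["x", "y"])
        assert math.isnan(rho.loc["x", "y"])

    def test_too_few_pairs_rejected(self):
        df = pd.DataFrame({"x": [1.0, 2.0], "y": [2.0, 1.0]})
        with pytest.raises(ValueError):
            spearman_matrix(df, ["x", "y"])


class TestPCA:
    def test_explained_fractions_sum_to_one_and_orthonormal(self):
        df = synth_cohort(n_subjects=80, seed=6)
        res = pca_characteristics(df)
        assert res.explained_fraction.sum() == pytest.approx(1.0, abs=1e-9)
        V = res.components.to_numpy()
        np.testing.assert_allclose(V.T @ V, np.eye(V.shape[1]), atol=1e-9)

    def test_duplicated_variable_block_loads_on_pc1(self):
        rng = np.random.default_rng(1)
        base = rng.random(200)
        df = pd.DataFrame({c: rng.random(200) for c in CHARACTERISTICS})
        df["n_end"] = base
        df["n_vessel"] = 3 * base + 5   # perfectly correlated pair
        res = pca_characteristics(df)
        top2 = set(res.components["PC1"].abs().nlargest(2).index)
        assert top2 == {"n_end", "n_vessel"}

    def test_isotropic_noise_spreads_variance_evenly(self):
        rng = np.random.default_rng(2)
        df = pd.DataFrame(rng.normal(size=(4000, 7)), columns=CHARACTERISTICS)
        res = pca_characteristics(df)
        assert np.all(np.abs(res.explained_fraction - 1 / 7) < 0.03)

    def test_sign_convention_largest_loading_positive(self):
        df = synth_cohort(n_subjects=60, seed=9)
        res = pca_characteristics(df)
        for col in res.components:
            v = res.components[col]
            assert v.iloc[int(np.argmax(np.abs(v.to_numpy())))] > 0

    def test_zero_variance_column_dropped_with_warning(self):
        df = synth_cohort(n_subjects=30, seed=0).copy()
        df["avg_vessel_length_mm"] = 1.0
        with pytest.warns(UserWarning, match="zero-variance"):
            res = pca_characteristics(df)
        assert "avg_vessel_length_mm" in res.dropped

    def test_single_row_rejected(self):
        df = synth_cohort(n_subjects=30, seed=0).iloc[:1]
        with pytest.raises(ValueError):
            pca_characteristics(df)


class TestMannWhitney:
    def test_worked_case_separated_groups(self):
        res = mwu_compare([1, 2, 3], [4, 5, 6])
        assert res.u == 0
        assert res.p == pytest.approx(0.1, abs=1e-12)
        assert res.method == "exact"

    def test_identical_groups_p_near_one(self):
        res = mwu_compare(np.arange(30) * 1.0 + 0.123,
                          np.arange(30) * 1.0 + 0.123)
        assert res.p >= 0.99

    @pytest.mark.parametrize("n1,n2", [(3, 3), (4, 4), (2, 6), (5, 5), (5, 7), (6, 6)])
    def test_exact_p_matches_brute_force_enumeration(self, n1, n2):
        rng = np.random.default_rng(n1 * 10 + n2)
        pooled = rng.permutation(n1 + n2).astype(float)  # no ties
        x, y = pooled[:n1], pooled[n1:]
        res = mwu_compare(x, y)
        assert res.method == "exact"
        assert res.p == pytest.approx(brute_force_mwu_p(x, y), abs=1e-12)

    def test_ties_fall_back_to_corrected_normal_approximation(self):
        res = mwu_compare([1, 1, 2, 3], [2, 4, 4, 5])
        assert res.method == "asymptotic"
        assert 0 < res.p <= 1

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            mwu_compare([], [1.0])


class TestLmmTrajectories:
    def test_recovers_generating_parameters(self):
        df = simulate_lmm_cohort(n_subjects=400, seed=12,
                                 beta=(10.0, 2.0, 0.5), sigma_subject=2.0)
        fit = lmm_trajectories(df, "value")
        assert fit.converged
        assert fit.params["Intercept"] == pytest.approx(10.0, abs=1.5)
        assert fit.params["ga_weeks"] == pytest.approx(2.0, abs=0.35)
        assert fit.params["_ga2"] == pytest.approx(0.5, abs=0.02)
        assert fit.random_intercept_var == pytest.approx(4.0, rel=0.35)

    def test_zero_random_intercept_variance_hits_boundary(self):
        df = simulate_lmm_cohort(n_subjects=150, seed=3, sigma_subject=0.0)
        fit = lmm_trajectories(df, "value")
        assert fit.random_intercept_var < 0.15

    def test_interaction_block_reports_lrt(self):
        df = simulate_lmm_cohort(n_subjects=100, seed=7)
        fit = lmm_trajectories(df, "value", interaction="complication")
        assert fit.lrt_df == 3
        assert 0 <= fit.lrt_p <= 1

    def test_missing_characteristic_rejected(self):
        df = simulate_lmm_cohort(n_subjects=20, seed=0)
        df["value"] = np.nan
        with pytest.raises(ValueError):
            lmm_trajectories(df, "value")


class TestCompareGroupsAtGa:
    def test_hand_computed_medians_on_six_rows(self):
        df = pd.DataFrame({
            "ga_weeks": [9.1, 8.8, 9.0, 9.2, 8.9, 9.0],
            "complication": [0, 0, 0, 1, 1, 1],
            "n_end": [10.0, 20.0, 30.0, 5.0, 15.0, 40.0],
        })
        out = compare_groups_at_ga(df, 9.0, ["n_end"])
        row = out.iloc[0]
        assert row["median_without"] == 20.0
        assert row["median_with"] == 15.0
        assert row["n_without"] == 3 and row["n_with"] == 3

    def test_visits_outside_window_are_excluded(self):
        assert assign_scheduled_week(9.4) == 9.0
        assert assign_scheduled_week(12.5) is None
        df = pd.DataFrame({
            "ga_weeks": [9.0, 9.0, 12.9, 9.0, 9.0],
            "complication": [0, 0, 0, 1, 1],
            "n_end": [1.0, 2.0, 99.0, 3.0, 4.0],
        })
        out = compare_groups_at_ga(df, 9.0, ["n_end"])
        assert out.iloc[0]["n_without"] == 2

    def test_empty_stratum_raises(self):
        df = pd.DataFrame({"ga_weeks": [9.0, 9.0], "complication": [0, 0],
                           "n_end": [1.0, 2.0]})
        with pytest.raises(ValueError, match="empty stratum"):
            compare_groups_at_ga(df, 9.0, ["n_end"])

    def test_generator_effect_detected_in_large_cohort(self):
        df = synth_cohort(n_subjects=600, seed=21, effect_characteristics=0.8)
        out = compare_groups_at_ga(df, 9.0, ["n_vessel"])
        row = out.iloc[0]
        assert row["median_with"] < row["median_without"]
        assert row["p"] < 0.05

    def test_null_effect_gives_similar_medians(self):
        df = synth_cohort(n_subjects=600, seed=22, effect_characteristics=1.0,
                          effect_upvv=1.0, effect_pv=1.0)
        out = compare_groups_at_ga(df, 9.0, ["n_vessel"])
        row = out.iloc[0]
        assert row["median_with"] == pytest.approx(row["median_without"], rel=0.15)
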