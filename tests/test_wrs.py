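"""Three-stage repeat-scan estimator: oracle equivalence and invariants."""

import dataclasses
import math

import numpy as np
import pandas as pd
import pytest

from conftest import random_pair_instance
from orbigrow.cohort import (
    POOLED_GROWTH_SCHEDULE,
    ScanRecord,
    simulate_cohort,
)
from orbigrow.panel import build_growth_pairs, build_panel
from orbigrow.wrs import (
    WRSFit,
    build_design_matrix,
    clustered_se,
    fit_stage1_ols,
    fit_stage2_variance,
    fit_stage3_wls,
    fit_wrs,
    fit_wrs_index,
    index_to_levels,
)


def _pairs(rows):
    return pd.DataFrame(rows, columns=["patient_id", "j", "k", "interval", "growth"])


class TestDesignMatrix:
    def test_interior_pair_has_plus_and_minus_one(self):
        pairs = _pairs([("P1", 8, 14, 6, 0.1), ("P1", 12, 14, 2, 0.1),
                        ("P2", 8, 12, 4, 0.1)])
        design = build_design_matrix(pairs, base_age=12)
        assert design.ages == [8, 14]
        np.testing.assert_array_equal(design.X[0], [-1.0, 1.0])

    def test_base_column_omitted(self):
        pairs = _pairs([("P1", 12, 15, 3, 0.1), ("P2", 9, 12, 3, 0.1)])
        design = build_design_matrix(pairs, base_age=12)
        assert design.ages == [9, 15]
        np.testing.assert_array_equal(design.X[0], [0.0, 1.0])   # k=15 only
        np.testing.assert_array_equal(design.X[1], [-1.0, 0.0])  # j=9 only

    def test_disconnected_age_raises_naming_the_orphans(self):
        pairs = _pairs([("P1", 12, 13, 1, 0.1), ("P2", 16, 17, 1, 0.1)])
        with pytest.raises(ValueError, match=r"\[16, 17\]"):
            build_design_matrix(pairs, base_age=12)

    def test_empty_pairs_rejected(self):
        with pytest.raises(ValueError, match="no growth pairs"):
            build_design_matrix(_pairs([]), base_age=12)


class TestStage1:
    def test_exact_chain(self):
        pairs = _pairs([("P1", 12, 13, 1, 0.02), ("P1", 13, 14, 1, 0.015)])
        design = build_design_matrix(pairs, base_age=12)
        gamma, resid = fit_stage1_ols(design, pairs["growth"])
        assert gamma[13] == pytest.approx(0.02, abs=1e-14)
        assert gamma[14] == pytest.approx(0.035, abs=1e-14)
        np.testing.assert_allclose(resid, 0.0, atol=1e-14)

    def test_schedule_generated_growth_recovered_exactly(self):
        sched = POOLED_GROWTH_SCHEDULE
        rows = []
        rng = np.random.default_rng(0)
        ages = sorted(sched)
        for p in range(20):
            j, k = sorted(rng.choice(ages, size=2, replace=False))
            rows.append((f"P{p}", int(j), int(k), int(k - j),
                         sched[int(k)] - sched[int(j)]))
        pairs = _pairs(rows)
        design = build_design_matrix(pairs, base_age=12)
        gamma, resid = fit_stage1_ols(design, pairs["growth"])
        for a in design.ages:
            assert gamma[a] == pytest.approx(sched[a], abs=1e-12)
        np.testing.assert_allclose(resid, 0.0, atol=1e-12)

    def test_matches_normal_equations_oracle(self):
        rng = np.random.default_rng(42)
        for _ in range(100):
            pairs = random_pair_instance(rng)
            design = build_design_matrix(pairs, base_age=12)
            y = pairs["growth"].to_numpy()
            gamma, _ = fit_stage1_ols(design, y)
            oracle = np.linalg.solve(design.X.T @ design.X, design.X.T @ y)
            np.testing.assert_allclose(
                [gamma[a] for a in design.ages], oracle, atol=1e-10
            )


class TestStage2:
    def test_zero_residuals_give_zero_model(self):
        a, b, fitted = fit_stage2_variance([0.0, 0.0, 0.0], [1, 2, 3])
        assert a == 0.0 and b == 0.0
        np.testing.assert_array_equal(fitted, 0.0)

    def test_exact_line(self):
        resid = np.sqrt([0.5, 1.0, 1.5])
        a, b, fitted = fit_stage2_variance(resid, [1, 2, 3])
        assert a == pytest.approx(0.0, abs=1e-12)
        assert b == pytest.approx(0.5, abs=1e-12)
        np.testing.assert_allclose(fitted, [0.5, 1.0, 1.5], atol=1e-12)

    def test_identical_intervals_degrade_to_intercept(self):
        with pytest.warns(UserWarning, match="intercept-only"):
            a, b, fitted = fit_stage2_variance([0.1, 0.3], [2, 2])
        assert b == 0.0
        assert a == pytest.approx((0.01 + 0.09) / 2)

    def test_too_short_input_rejected(self):
        with pytest.raises(ValueError):
            fit_stage2_variance([0.1], [1])


class TestStage3:
    def test_constant_weights_reproduce_stage1(self):
        rng = np.random.default_rng(7)
        pairs = random_pair_instance(rng)
        design = build_design_matrix(pairs, base_age=12)
        y = pairs["growth"].to_numpy()
        g1, _ = fit_stage1_ols(design, y)
        g3, *_ = fit_stage3_wls(design, y, np.full(len(pairs), 0.25))
        for a in design.ages:
            assert g3[a] == pytest.approx(g1[a], abs=1e-12)

    def test_noise_free_r_squared_is_one(self):
        pairs = _pairs([("P1", 12, 13, 1, 0.02), ("P1", 13, 14, 1, 0.015),
                        ("P2", 12, 14, 2, 0.035)])
        design = build_design_matrix(pairs, base_age=12)
        y = pairs["growth"].to_numpy()
        _, resid = fit_stage1_ols(design, y)
        _, _, _, _, r2 = fit_stage3_wls(design, y, np.full(3, 1e-4))
        assert r2 == pytest.approx(1.0, abs=1e-10)

    def test_matches_weighted_normal_equations_oracle(self):
        rng = np.random.default_rng(3)
        for _ in range(100):
            pairs = random_pair_instance(rng)
            design = build_design_matrix(pairs, base_age=12)
            y = pairs["growth"].to_numpy()
            fitted_sq = rng.uniform(0.5, 2.0, size=len(pairs))
            gamma, *_ = fit_stage3_wls(design, y, fitted_sq)
            W = np.diag(1.0 / fitted_sq)
            oracle = np.linalg.solve(
                design.X.T @ W @ design.X, design.X.T @ W @ y
            )
            np.testing.assert_allclose(
                [gamma[a] for a in design.ages], oracle, atol=1e-10
            )

    def test_variance_floor_keeps_weights_finite(self):
        pairs = _pairs([("P1", 12, 13, 1, 0.02), ("P2", 12, 14, 2, 0.05)])
        design = build_design_matrix(pairs, base_age=12)
        # negative fitted variance from an extrapolated stage-2 line
        _, weights, *_ = fit_stage3_wls(
            design, pairs["growth"].to_numpy(), np.array([-0.01, 0.02])
        )
        assert np.all(np.isfinite(weights)) and np.all(weights > 0)

    def test_literal_weighting_differs(self):
        rng = np.random.default_rng(11)
        pairs = random_pair_instance(rng)
        design = build_design_matrix(pairs, base_age=12)
        y = pairs["growth"].to_numpy()
        fitted_sq = rng.uniform(0.5, 2.0, size=len(pairs))
        g_inv, *_ = fit_stage3_wls(design, y, fitted_sq)
        g_lit, *_ = fit_stage3_wls(design, y, fitted_sq, weight_mode="literal")
        assert any(
            abs(g_inv[a] - g_lit[a]) > 1e-8 for a in design.ages
        )


class TestClusteredSE:
    def _hc1_oracle(self, X, u):
        n, k = X.shape
        bread = np.linalg.inv(X.T @ X)
        meat = X.T @ np.diag(u**2) @ X
        diag = np.clip(np.diag(bread @ meat @ bread) * n / (n - k), 0.0, None)
        return np.sqrt(diag)

    def test_singleton_clusters_equal_hc1(self):
        """With one pair per cluster the sandwich collapses to HC1."""
        rng = np.random.default_rng(19)
        for _ in range(50):
            pairs = random_pair_instance(rng)
            design = build_design_matrix(pairs, base_age=12)
            n, k = design.X.shape
            if n <= k + 1:
                continue
            y = pairs["growth"].to_numpy()
            beta = np.linalg.lstsq(design.X, y, rcond=None)[0]
            u = y - design.X @ beta
            ids = np.arange(n)  # every row its own cluster
            se, _, G = clustered_se(design.X, u, ids, small_sample="stata")
            oracle = self._hc1_oracle(design.X, u)
            np.testing.assert_allclose(se, oracle, rtol=1e-7, atol=1e-6)

    def test_matches_statsmodels_cluster_oracle(self):
        import statsmodels.api as sm

        rng = np.random.default_rng(23)
        for _ in range(20):
            pairs = random_pair_instance(rng)
            design = build_design_matrix(pairs, base_age=12)
            n, k = design.X.shape
            if n <= k + 1 or len(set(design.patient_ids)) < 2:
                continue
            y = pairs["growth"].to_numpy()
            beta = np.linalg.lstsq(design.X, y, rcond=None)[0]
            u = y - design.X @ beta
            se, _, _ = clustered_se(design.X, u, design.patient_ids)
            res = sm.OLS(y, design.X).fit(
                cov_type="cluster", cov_kwds={"groups": design.patient_ids}
            )
            # statsmodels reports nan where rounding makes its diagonal
            # negative; we clip those to zero
            np.testing.assert_allclose(
                se, np.nan_to_num(res.bse), rtol=1e-7, atol=1e-6
            )

    def test_duplicating_clusters_does_not_shrink_se(self):
        """Perfectly correlated duplicate rows leave the sandwich unchanged."""
        X = np.array([[1.0, 0.0], [0.0, 1.0], [1.0, -1.0],
                      [0.5, 0.5], [1.0, 1.0], [-1.0, 0.5]])
        u = np.array([0.3, -0.2, 0.15, -0.4, 0.25, 0.1])
        ids = np.array([0, 0, 1, 1, 2, 2])
        se1, _, _ = clustered_se(X, u, ids, small_sample="none")
        X2 = np.vstack([X, X])
        u2 = np.concatenate([u, u])
        ids2 = np.concatenate([ids, ids])
        se2, _, _ = clustered_se(X2, u2, ids2, small_sample="none")
        np.testing.assert_allclose(se2, se1, rtol=1e-12)

    def test_fewer_than_two_clusters_rejected(self):
        X = np.ones((3, 1))
        with pytest.raises(ValueError, match="2 clusters"):
            clustered_se(X, np.zeros(3), ["P1", "P1", "P1"])

    def test_confidence_interval_coverage(self):
        """~95% of nominal 95% CIs cover the truth under homoskedastic noise."""
        rng = np.random.default_rng(31)
        pairs = random_pair_instance(np.random.default_rng(1), max_pairs=10)
        design = build_design_matrix(pairs, base_age=12)
        n, k = design.X.shape
        truth = rng.normal(size=k)
        from scipy import stats

        hits = 0
        reps = 400
        for _ in range(reps):
            y = design.X @ truth + rng.normal(0, 0.1, size=n)
            beta = np.linalg.lstsq(design.X, y, rcond=None)[0]
            u = y - design.X @ beta
            ids = np.arange(n)
            se, _, G = clustered_se(design.X, u, ids, small_sample="stata")
            crit = stats.t.ppf(0.975, G - 1)
            hits += abs(beta[0] - truth[0]) <= crit * se[0]
        assert hits / reps == pytest.approx(0.95, abs=0.035)


class TestIndexToLevels:
    def _fit_with_gamma(self, gamma, base=12):
        ages = sorted(a for a in gamma if a != base)
        return WRSFit(
            base_age=base, ages=ages, gamma={**gamma, base: 0.0},
            se={}, p_values={}, t_stats={}, alpha=0.0, beta=0.0,
            stage1_gamma={}, stage1_residuals=np.array([]),
            fitted_variance=np.array([]), weights=np.array([]),
            r_squared=1.0, n_obs=0, n_clusters=0,
        )

    def test_flat_index(self):
        fit = self._fit_with_gamma({10: 0.0, 12: 0.0, 15: 0.0})
        index = index_to_levels(fit, 22000.0)
        assert all(v == 22000.0 for v in index.levels.values())

    def test_exponentiation_against_closed_form(self):
        fit = self._fit_with_gamma({8: -0.103, 12: 0.0, 18: 0.0820})
        index = index_to_levels(fit, 22000.0)
        assert index.levels[18] == pytest.approx(22000.0 * math.exp(0.0820))
        assert index.levels[8] / index.levels[12] == pytest.approx(
            math.exp(-0.103)
        )
        assert index.levels[12] == 22000.0

    def test_nonpositive_base_volume_rejected(self):
        with pytest.raises(ValueError):
            index_to_levels(self._fit_with_gamma({12: 0.0, 13: 0.1}), 0.0)


class TestFullPipeline:
    def test_noise_free_recovers_schedule_exactly(self, noise_free_config):
        result = fit_wrs_index(
            build_panel(simulate_cohort(noise_free_config, seed=5))
        )
        for a, g in result.fit.gamma.items():
            assert g == pytest.approx(POOLED_GROWTH_SCHEDULE[a], abs=1e-10)
        assert result.fit.r_squared == pytest.approx(1.0, abs=1e-10)
        assert result.index.base_mean_volume == pytest.approx(22000.0, rel=1e-12)

    def test_subgroup_pair_counts_match_study_tables(self, study_config):
        panel = build_panel(simulate_cohort(study_config, seed=6))
        assert fit_wrs_index(panel, subgroup="F").fit.n_obs == 54
        assert fit_wrs_index(panel, subgroup="M").fit.n_obs == 27
        assert fit_wrs_index(panel, subgroup="all").fit.n_obs == 81

    def test_base_normalization_holds_everywhere(self, study_config):
        result = fit_wrs_index(build_panel(simulate_cohort(study_config, seed=8)))
        assert result.fit.gamma[12] == 0.0
        assert result.index.levels[12] == result.index.base_mean_volume

    def test_scale_equivariance(self, study_config):
        recs = simulate_cohort(study_config, seed=9)
        scaled = [
            ScanRecord(r.patient_id, r.sex, r.age_days,
                       r.left_volume * 3.0, r.right_volume * 3.0)
            for r in recs
        ]
        r0 = fit_wrs_index(build_panel(recs))
        r1 = fit_wrs_index(build_panel(scaled))
        for a in r0.fit.gamma:
            assert r1.fit.gamma[a] == pytest.approx(r0.fit.gamma[a], abs=1e-9)
        for a in r0.fit.se:
            assert r1.fit.se[a] == pytest.approx(r0.fit.se[a], rel=1e-6)
        for a in r0.index.levels:
            assert r1.index.levels[a] == pytest.approx(
                3.0 * r0.index.levels[a], rel=1e-9
            )

    def test_permutation_invariance(self, study_config):
        panel = build_panel(simulate_cohort(study_config, seed=10))
        shuffled = panel.sample(frac=1.0, random_state=1)
        r0, r1 = fit_wrs_index(panel), fit_wrs_index(shuffled)
        for a in r0.fit.gamma:
            assert r1.fit.gamma[a] == pytest.approx(r0.fit.gamma[a], abs=1e-12)
        for a in r0.fit.se:
            assert r1.fit.se[a] == pytest.approx(r0.fit.se[a], rel=1e-9)

    def test_missing_base_age_raises(self):
        rows = [
            ScanRecord("P1", "F", 2922, 20000.0, 20000.0),
            ScanRecord("P1", "F", 3287, 20500.0, 20500.0),
        ]
        with pytest.raises(ValueError, match="base age"):
            fit_wrs_index(build_panel(rows), base_age=12)

    def test_p_values_use_cluster_degrees_of_freedom(self, study_config):
        from scipy import stats

        fit = fit_wrs_index(build_panel(simulate_cohort(study_config, seed=12))).fit
        a = fit.ages[0]
        expected = 2 * stats.t.sf(abs(fit.gamma[a] / fit.se[a]), fit.n_clusters - 1)
        assert fit.p_values[a] == pytest.approx(expected, rel=1e-12)

    def test_plot_helper_returns_axis(self, study_config, tmp_path):
        import matplotlib

        matplotlib.use("Agg")
        from orbigrow.wrs import plot_index_vs_average

        result = fit_wrs_index(build_panel(simulate_cohort(study_config, seed=13)))
        ax = plot_index_vs_average(result)
        ax.figure.savefig(tmp_path / "index.png")
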