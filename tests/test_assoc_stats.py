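import numpy as np
import pytest
from scipy import stats

from adipomets.assoc_stats import (
    anova_bonferroni, compare_correlated, correlation_matrix, fisher_z,
    lognormality_ks, partial_pearson, pearson, screen_outliers,
    standardized_beta, welch_t,
)


class TestPearson:
    def test_identity(self, rng):
        x = rng.normal(size=50)
        r, p = pearson(x, x)
        assert r == pytest.approx(1.0)
        assert p < 1e-10

    def test_zero_variance_rejected(self, rng):
        with pytest.raises(ValueError, match="variance"):
            pearson(np.ones(20), rng.normal(size=20))


class TestPartialPearson:
    def test_matches_residual_oracle(self, rng):
        """Partialling a covariate out of r equals the Pearson r of the two
        OLS residual vectors after regressing each variable on it."""
        for _ in range(20):
            n = 200
            c = rng.normal(size=n)
            x = 0.6 * c + rng.normal(size=n)
            y = -0.4 * c + 0.3 * x + rng.normal(size=n)
            r, _ = partial_pearson(x, y, c)
            design = np.column_stack([np.ones(n), c])
            rx = x - design @ np.linalg.lstsq(design, x, rcond=None)[0]
            ry = y - design @ np.linalg.lstsq(design, y, rcond=None)[0]
            oracle = np.corrcoef(rx, ry)[0, 1]
            assert r == pytest.approx(oracle, abs=1e-10)

    def test_constant_covariate_reduces_to_pearson(self, rng):
        x, y = rng.normal(size=(2, 60))
        r_plain, _ = pearson(x, y)
        r_partial, _ = partial_pearson(x, y, np.full(60, 3.0))
        assert r_partial == pytest.approx(r_plain, abs=1e-12)

    def test_recovers_known_partial_correlation(self):
        """Trivariate normal with partial corr(x,y|z) = 0.3 by construction."""
        rng = np.random.default_rng(2024)
        n = 10_000
        z = rng.normal(size=n)
        e1, e2 = rng.normal(size=(2, n))
        x = 0.7 * z + e1
        rho = 0.3
        y = 0.5 * z + rho * e1 + np.sqrt(1 - rho**2) * e2
        r, p = partial_pearson(x, y, z)
        assert r == pytest.approx(rho, abs=0.03)
        assert p < 1e-6

    def test_agrees_with_pingouin(self, rng):
        import pandas as pd
        import pingouin as pg
        n = 150
        c = rng.normal(size=n)
        x = 0.5 * c + rng.normal(size=n)
        y = 0.5 * c + 0.4 * x + rng.normal(size=n)
        r, p = partial_pearson(x, y, c)
        ref = pg.partial_corr(
            pd.DataFrame({"x": x, "y": y, "c": c}), x="x", y="y", covar="c")
        assert r == pytest.approx(float(ref["r"].iloc[0]), abs=1e-10)
        assert p == pytest.approx(float(ref["p_val"].iloc[0]), abs=1e-8)


class TestCorrelatedCorrelations:
    def test_fisher_z_closed_forms(self):
        assert fisher_z(0.0) == 0.0
        assert fisher_z(0.5) == pytest.approx(0.5493, abs=1e-4)
        with pytest.raises(ValueError):
            fisher_z(1.0)

    def test_equal_correlations_give_null(self):
        t = compare_correlated(0.4, 0.4, 0.6, 500)
        assert t.z == 0.0
        assert t.p == 1.0

    def test_antisymmetric_in_competitors(self):
        a = compare_correlated(0.55, 0.30, 0.62, 400)
        b = compare_correlated(0.30, 0.55, 0.62, 400)
        assert a.z == pytest.approx(-b.z, abs=1e-12)
        assert a.p == pytest.approx(b.p, abs=1e-12)

    def test_small_n_rejected(self):
        with pytest.raises(ValueError, match="n >= 10"):
            compare_correlated(0.3, 0.2, 0.5, 5)


class TestStandardizedBeta:
    def test_identity_regression(self, rng):
        x = rng.normal(size=100)
        beta, (lo, hi), r2 = standardized_beta(x, x)
        assert beta == pytest.approx(1.0, abs=1e-10)
        assert r2 == pytest.approx(1.0, abs=1e-10)
        assert lo <= 1.0 + 1e-9 and hi >= 1.0 - 1e-9

    def test_affine_invariance(self, rng):
        n = 200
        c = rng.normal(size=n)
        x = rng.normal(size=n)
        y = 0.2 * x + 0.5 * c + rng.normal(size=n)
        b1, _, _ = standardized_beta(y, x, c)
        b2, _, _ = standardized_beta(1000 * y - 3, 0.01 * x + 7, c)
        assert b1 == pytest.approx(b2, abs=1e-10)

    def test_ci_width_at_cohort_scale(self):
        """With β_std ≈ 0.19 at n = 1528 the 95% CI half-width should be a
        few hundredths (a 0.09-wide interval, like 0.14–0.23)."""
        rng = np.random.default_rng(99)
        n = 1528
        age = rng.normal(size=n)
        x = 0.3 * age + rng.normal(size=n)
        y = 0.19 * (x / np.std(x)) + 0.2 * age + 0.98 * rng.normal(size=n)
        beta, (lo, hi), _ = standardized_beta(y, x, age)
        assert beta == pytest.approx(0.19, abs=0.06)
        assert (hi - lo) == pytest.approx(0.09, abs=0.05)

    def test_collinear_covariate_rejected(self, rng):
        x = rng.normal(size=50)
        with pytest.raises(ValueError, match="collinear"):
            standardized_beta(rng.normal(size=50), x, x * 2.0)


class TestGroupComparisons:
    def test_identical_groups_are_null(self):
        g = np.arange(10.0)
        t, p = welch_t(g, g.copy())
        assert t == 0.0
        assert p == 1.0

    def test_welch_type_one_error_calibrated(self):
        """Two groups from the same normal: rejection rate at α=0.05 over
        2000 replicates should be 0.05 ± 0.015."""
        rng = np.random.default_rng(7)
        a = rng.normal(size=(2000, 40))
        b = rng.normal(size=(2000, 40))
        _, p = stats.ttest_ind(a, b, axis=1, equal_var=False)
        rate = np.mean(p < 0.05)
        assert rate == pytest.approx(0.05, abs=0.015)

    def test_anova_equal_means(self):
        g = np.arange(12.0)
        F, p, pairwise = anova_bonferroni([g, g.copy(), g.copy()])
        assert F == pytest.approx(0.0)
        assert (pairwise["p_bonferroni"] == 1.0).all()

    def test_bonferroni_caps_at_one(self, rng):
        groups = [rng.normal(size=15) for _ in range(3)]
        _, _, pairwise = anova_bonferroni(groups)
        assert len(pairwise) == 3
        assert (pairwise["p_bonferroni"] <= 1.0).all()
        assert (pairwise["p_bonferroni"] >= pairwise["p_raw"]).all()

    def test_small_group_rejected(self):
        with pytest.raises(ValueError, match="n >= 2"):
            anova_bonferroni([[1.0], [1.0, 2.0]])


class TestOutlierScreen:
    def test_planted_extreme_point_excluded(self, rng):
        v = rng.normal(size=500)
        v[123] = 10.0  # far beyond 4.5 SD
        kept, excluded = screen_outliers(v)
        assert excluded == [123]
        assert len(kept) == 499

    def test_clean_data_untouched(self, rng):
        v = np.clip(rng.normal(size=300), -2, 2)
        kept, excluded = screen_outliers(v)
        assert excluded == []
        assert len(kept) == 300

    def test_cohort_sized_screen_with_two_extremes(self, rng):
        """1530 subjects, two planted gross errors: the 4.5-SD screen should
        remove exactly those two."""
        v = rng.normal(43, 6, size=1530)
        ids = np.array([f"S{i:04d}" for i in range(1530)])
        v[17] = 43 + 6 * 8
        v[1200] = 43 - 6 * 7
        kept, excluded = screen_outliers(v, ids)
        assert sorted(excluded) == ["S0017", "S1200"]
        assert len(kept) == 1528

    def test_zero_sd_warns(self):
        with pytest.warns(UserWarning, match="zero standard deviation"):
            kept, excluded = screen_outliers(np.ones(10))
        assert excluded == []


class TestLognormality:
    def test_lognormal_samples_usually_pass(self):
        passes = 0
        for seed in range(40):
            rng = np.random.default_rng(seed)
            v = rng.lognormal(3.0, 0.4, size=1000)
            _, p = lognormality_ks(v)
            passes += p > 0.05
        assert passes >= 36  # ≥ 90% of replicates

    def test_bimodal_sample_fails(self, rng):
        v = np.concatenate([rng.lognormal(1.0, 0.05, 500),
                            rng.lognormal(4.0, 0.05, 500)])
        d, p = lognormality_ks(v)
        assert p < 0.01
        assert 0.0 <= d <= 1.0

    def test_nonpositive_rejected(self, rng):
        with pytest.raises(ValueError, match="positive"):
            lognormality_ks(np.concatenate([[-1.0], rng.lognormal(size=30)]))


class TestCorrelationMatrix:
    def test_symmetric_unit_diagonal(self, rng):
        import pandas as pd
        df = pd.DataFrame(rng.normal(size=(80, 4)), columns=list("abcd"))
        df["age"] = rng.uniform(20, 80, 80)
        r, p = correlation_matrix(df, partial_on="age")
        assert np.allclose(r.values, r.values.T)
        assert np.allclose(np.diag(r.values), 1.0)
        assert (np.abs(r.values) <= 1.0).all()
        assert "age" not in r.columns
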