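"""Statistics layer: correlations, standardized-beta OLS, t-tests, ANOVA."""

import math

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm
from scipy import stats as sps

from awvct.cohort_stats import (
    anova_across_gold,
    fit_standardized_ols,
    group_compare,
    pearson_correlation,
    pearson_matrix,
)
from awvct.errors import InsufficientDataError, SingularDesignError
from awvct.phantom import CohortSimSpec, simulate_cohort


def brute_force_pearson(x, y):
    """Independent oracle: textbook product-moment formula, element loops."""
    n = len(x)
    mx = sum(x) / n
    my = sum(y) / n
    sxy = sxx = syy = 0.0
    for xi, yi in zip(x, y):
        sxy += (xi - mx) * (yi - my)
        sxx += (xi - mx) ** 2
        syy += (yi - my) ** 2
    return sxy / math.sqrt(sxx * syy)


class TestPearson:
    def test_perfect_linear_relation(self):
        x = np.arange(10.0)
        r, p, n = pearson_correlation(x, 2.0 * x + 1.0)
        assert r == pytest.approx(1.0)
        assert p == pytest.approx(0.0, abs=1e-12)

    def test_perfect_negative(self):
        x = np.arange(10.0)
        r, _, _ = pearson_correlation(x, -x)
        assert r == pytest.approx(-1.0)

    def test_matches_brute_force_oracle_to_1e12(self):
        rng = np.random.default_rng(42)
        for _ in range(20):
            x = rng.normal(size=50)
            y = rng.normal(size=50) + 0.3 * x
            r, _, _ = pearson_correlation(x, y)
            assert abs(r - brute_force_pearson(list(x), list(y))) < 1e-12

    def test_p_value_matches_scipy(self):
        rng = np.random.default_rng(7)
        x = rng.normal(size=40)
        y = 0.4 * x + rng.normal(size=40)
        r, p, _ = pearson_correlation(x, y)
        ref = sps.pearsonr(x, y)
        assert r == pytest.approx(ref.statistic, abs=1e-12)
        assert p == pytest.approx(ref.pvalue, rel=1e-9)

    def test_simulated_generating_correlation_recovered(self):
        rng = np.random.default_rng(3)
        n = 5000
        x = rng.normal(size=n)
        y = 0.5 * x + math.sqrt(1 - 0.25) * rng.normal(size=n)
        r, _, _ = pearson_correlation(x, y)
        assert r == pytest.approx(0.5, abs=0.03)

    def test_zero_variance_flagged_not_raised(self):
        table = pd.DataFrame({"a": [1.0, 1.0, 1.0, 1.0], "b": [1.0, 2.0, 3.0, 4.0]})
        res = pearson_matrix(table, ["a", "b"])
        assert len(res) == 1
        assert not res[0].defined

    def test_too_few_pairs_rejected(self):
        with pytest.raises(InsufficientDataError):
            pearson_correlation(np.array([1.0, 2.0]), np.array([1.0, 2.0]))


class TestStandardizedOls:
    def test_single_predictor_beta_equals_pearson_r(self):
        rng = np.random.default_rng(5)
        x = rng.normal(size=200)
        y = 0.6 * x + rng.normal(size=200)
        table = pd.DataFrame({"x": x, "y": y})
        res = fit_standardized_ols(table, "y", ["x"])
        r, _, _ = pearson_correlation(x, y)
        assert res.beta("x") == pytest.approx(r, abs=1e-12)

    def test_orthogonal_predictors_have_unit_vif(self):
        n = 64
        t = np.arange(n)
        x1 = np.cos(2 * np.pi * t / n)
        x2 = np.sin(2 * np.pi * t / n)
        x3 = np.cos(4 * np.pi * t / n)
        y = x1 - x2 + 0.5 * x3
        table = pd.DataFrame({"x1": x1, "x2": x2, "x3": x3, "y": y})
        res = fit_standardized_ols(table, "y", ["x1", "x2", "x3"])
        for p in res.predictors:
            assert p.vif == pytest.approx(1.0, abs=1e-9)

    def test_known_coefficients_recovered_on_simulated_cohort(self):
        spec = CohortSimSpec(
            n=2000,
            coefficients={
                "pct_fev1": {"awv_percent": 0.35, "lav_percent": -0.50},
                "rv_tlc": {},
            },
            noise_sd=math.sqrt(1.0 - (0.35**2 + 0.50**2)),  # generating R^2 = 0.3725
            seed=17,
        )
        df = simulate_cohort(spec)
        res = fit_standardized_ols(df, "pct_fev1", ["awv_percent", "lav_percent"])
        assert res.beta("awv_percent") == pytest.approx(0.35, abs=0.05)
        assert res.beta("lav_percent") == pytest.approx(-0.50, abs=0.05)
        assert res.r_squared == pytest.approx(0.3725, abs=0.05)

    def test_standardized_beta_consistent_with_raw_fit(self):
        rng = np.random.default_rng(11)
        x1 = rng.normal(10.0, 3.0, size=300)
        x2 = rng.normal(-5.0, 7.0, size=300)
        y = 2.0 * x1 - 0.4 * x2 + rng.normal(size=300)
        table = pd.DataFrame({"x1": x1, "x2": x2, "y": y})
        res = fit_standardized_ols(table, "y", ["x1", "x2"])
        raw = sm.OLS(y, sm.add_constant(np.column_stack([x1, x2]))).fit()
        sy = y.std(ddof=1)
        assert res.beta("x1") * sy / x1.std(ddof=1) == pytest.approx(raw.params[1], rel=1e-9)
        assert res.beta("x2") * sy / x2.std(ddof=1) == pytest.approx(raw.params[2], rel=1e-9)

    def test_duplicated_predictor_is_singular(self):
        rng = np.random.default_rng(2)
        x = rng.normal(size=100)
        table = pd.DataFrame({"x1": x, "x2": x.copy(), "y": x + rng.normal(size=100)})
        with pytest.raises(SingularDesignError):
            fit_standardized_ols(table, "y", ["x1", "x2"])

    def test_too_few_cases_rejected(self):
        table = pd.DataFrame({"x": [1.0, 2.0, 3.0], "y": [1.0, 2.0, 3.0]})
        with pytest.raises(InsufficientDataError):
            fit_standardized_ols(table, "y", ["x"], covariates=["x"])


class TestGroupCompare:
    def test_identical_groups_p_near_one(self):
        vals = np.tile(np.arange(10.0), 2)
        table = pd.DataFrame({"flag": [True] * 10 + [False] * 10, "v": vals})
        res = group_compare(table, "flag", "v")
        assert res.means[0] == pytest.approx(res.means[1])
        assert res.p_value == pytest.approx(1.0, abs=1e-9)

    def test_tiny_group_rejected(self):
        table = pd.DataFrame({"flag": [True] + [False] * 10, "v": np.arange(11.0)})
        with pytest.raises(InsufficientDataError):
            group_compare(table, "flag", "v")

    def test_welch_and_pooled_differ_under_unequal_variance(self):
        rng = np.random.default_rng(9)
        a = rng.normal(0.0, 5.0, size=20)
        b = rng.normal(0.0, 0.5, size=60)
        table = pd.DataFrame({"flag": [True] * 20 + [False] * 60, "v": np.concatenate([a, b])})
        welch = group_compare(table, "flag", "v", welch=True)
        pooled = group_compare(table, "flag", "v", welch=False)
        assert welch.p_value != pytest.approx(pooled.p_value, rel=1e-3)

    def test_cohort_symptom_contrast_runs(self):
        df = simulate_cohort(CohortSimSpec(n=147, seed=1))
        df["symptomatic"] = df["cat_score"] >= 10
        res = group_compare(df, "symptomatic", "awv_percent")
        assert res.ns[0] + res.ns[1] == 147
        assert 0.0 <= res.p_value <= 1.0


class TestAnova:
    def test_two_groups_f_is_t_squared(self):
        rng = np.random.default_rng(21)
        table = pd.DataFrame(
            {
                "gold_grade": [1] * 30 + [2] * 40,
                "v": np.concatenate([rng.normal(0, 1, 30), rng.normal(0.5, 1, 40)]),
            }
        )
        res = anova_across_gold(table, "v")
        g1 = table.loc[table.gold_grade == 1, "v"]
        g2 = table.loc[table.gold_grade == 2, "v"]
        t = sps.ttest_ind(g1, g2, equal_var=True)
        assert res.f_statistic == pytest.approx(t.statistic**2, rel=1e-9)

    def test_strong_separation_tiny_p(self):
        rng = np.random.default_rng(8)
        rows = []
        for grade, mu in ((1, 10.0), (2, 5.0), (3, 0.0), (4, -5.0)):
            rows += [(grade, v) for v in rng.normal(mu, 1.0, size=30)]
        table = pd.DataFrame(rows, columns=["gold_grade", "v"])
        assert anova_across_gold(table, "v").p_value < 1e-6

    def test_null_p_values_uniform(self):
        """ANOVA calibration: under the null, p is Uniform(0,1)."""
        rng = np.random.default_rng(123)
        pvals = []
        for _ in range(500):
            table = pd.DataFrame(
                {"gold_grade": np.repeat([1, 2, 3], 30), "v": rng.normal(size=90)}
            )
            pvals.append(anova_across_gold(table, "v").p_value)
        ks = sps.kstest(pvals, "uniform")
        assert ks.pvalue > 0.01

    def test_single_grade_rejected(self):
        table = pd.DataFrame({"gold_grade": [2] * 20, "v": np.arange(20.0)})
        with pytest.raises(InsufficientDataError):
            anova_across_gold(table, "v")
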