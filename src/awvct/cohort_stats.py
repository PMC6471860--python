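"""Cohort statistics: Pearson correlations, standardized-beta OLS with VIF,
group comparisons and one-way ANOVA across GOLD grades.

Conventions: pairwise deletion for correlations, complete cases per
regression model; standardization uses the sample SD (n-1); the two-sample
test defaults to Welch (unequal variances) with a pooled-variance option;
p-values are two-sided and reported raw (no multiple-testing correction).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .errors import InsufficientDataError, SingularDesignError

#: default adjustment covariates for the regression models
DEFAULT_COVARIATES = ("age_yr", "bmi", "pack_years", "ct_tlv_ml")


@dataclass
class CorrelationResult:
    var_a: str
    var_b: str
    r: float
    p_value: float
    n: int
    defined: bool = True


@dataclass
class PredictorStats:
    name: str
    beta_std: float
    p_value: float
    vif: float


@dataclass
class RegressionResult:
    outcome: str
    predictors: list[PredictorStats]
    r_squared: float
    n: int
    covariates: tuple[str, ...] = ()

    def beta(self, name: str) -> float:
        return next(p.beta_std for p in self.predictors if p.name == name)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "outcome": self.outcome,
                    "predictor": p.name,
                    "beta_std": p.beta_std,
                    "p_value": p.p_value,
                    "vif": p.vif,
                    "r_squared": self.r_squared,
                    "n": self.n,
                }
                for p in self.predictors
            ]
        )


# ---------------------------------------------------------------------------
# Pearson correlations
# ---------------------------------------------------------------------------

def pearson_correlation(x: np.ndarray, y: np.ndarray) -> tuple[float, float, int]:
    """Product-moment r with a two-sided p from the t transform (n-2 df)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    n = len(x)
    if n < 3:
        raise InsufficientDataError(f"need >= 3 complete pairs, have {n}")
    xc = x - x.mean()
    yc = y - y.mean()
    sxx = float(np.dot(xc, xc))
    syy = float(np.dot(yc, yc))
    if sxx == 0 or syy == 0:
        return float("nan"), float("nan"), n
    r = float(np.dot(xc, yc) / np.sqrt(sxx * syy))
    r = max(-1.0, min(1.0, r))
    if abs(r) == 1.0:
        return r, 0.0, n
    t = r * np.sqrt((n - 2) / (1.0 - r * r))
    p = 2.0 * stats.t.sf(abs(t), df=n - 2)
    return r, float(p), n


def pearson_matrix(table: pd.DataFrame, variables: list[str]) -> list[CorrelationResult]:
    """All unordered variable pairs with pairwise-complete observations.

    Zero-variance variables yield an undefined-correlation flag rather
    than an exception, so one degenerate column cannot sink the report.
    """
    out = []
    for i, a in enumerate(variables):
        for b in variables[i + 1:]:
            r, p, n = pearson_correlation(table[a].to_numpy(), table[b].to_numpy())
            out.append(CorrelationResult(a, b, r, p, n, defined=np.isfinite(r)))
    return out


# ---------------------------------------------------------------------------
# Standardized-beta regression with VIF
# ---------------------------------------------------------------------------

def _zscore(v: np.ndarray) -> np.ndarray:
    sd = v.std(ddof=1)
    if sd == 0:
        raise SingularDesignError("zero-variance variable cannot be standardized")
    return (v - v.mean()) / sd


def fit_standardized_ols(
    table: pd.DataFrame,
    outcome: str,
    predictors: list[str],
    covariates: tuple[str, ...] | list[str] = (),
) -> RegressionResult:
    """OLS on z-scored outcome and independent variables.

    Reports the standardized beta and two-sided p per independent variable
    and its variance inflation factor VIF_j = 1/(1 - R^2_j) from regressing
    variable j on the others.  Complete cases only.
    """
    cols = [outcome] + list(predictors) + list(covariates)
    data = table[cols].dropna()
    n = len(data)
    k = len(predictors) + len(covariates)
    if n <= k + 2:
        raise InsufficientDataError(f"{n} complete cases for {k} parameters")
    indep_names = list(predictors) + list(covariates)
    Z = np.column_stack([_zscore(data[c].to_numpy(dtype=float)) for c in indep_names])
    zy = _zscore(data[outcome].to_numpy(dtype=float))
    X = sm.add_constant(Z)
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        offenders = _collinear_sets(Z, indep_names)
        raise SingularDesignError(f"perfectly collinear predictors: {offenders}")
    fit = sm.OLS(zy, X).fit()
    preds = []
    for j, name in enumerate(indep_names):
        vif = _vif(Z, j)
        preds.append(PredictorStats(name=name, beta_std=float(fit.params[j + 1]), p_value=float(fit.pvalues[j + 1]), vif=vif))
    return RegressionResult(
        outcome=outcome,
        predictors=preds,
        r_squared=float(fit.rsquared),
        n=n,
        covariates=tuple(covariates),
    )


def _vif(Z: np.ndarray, j: int) -> float:
    if Z.shape[1] == 1:
        return 1.0
    others = np.delete(Z, j, axis=1)
    fit = sm.OLS(Z[:, j], sm.add_constant(others)).fit()
    r2 = min(float(fit.rsquared), 1.0 - 1e-12)
    return 1.0 / (1.0 - r2)


def _collinear_sets(Z: np.ndarray, names: list[str]) -> list[str]:
    out = []
    for j in range(Z.shape[1]):
        if Z.shape[1] > 1 and _vif(Z, j) > 1e6:
            out.append(names[j])
    return out or list(names)


# ---------------------------------------------------------------------------
# Group comparison and ANOVA
# ---------------------------------------------------------------------------

@dataclass
class GroupComparison:
    variable: str
    group_names: tuple[str, str]
    means: tuple[float, float]
    sds: tuple[float, float]
    ns: tuple[int, int]
    p_value: float
    welch: bool


def group_compare(
    table: pd.DataFrame,
    flag: str,
    variable: str,
    welch: bool = True,
) -> GroupComparison:
    """Two-group mean +- SD and a two-sided two-sample t-test.

    Welch's unequal-variance test by default; ``welch=False`` pools.
    """
    data = table[[flag, variable]].dropna()
    g1 = data.loc[data[flag].astype(bool), variable].to_numpy(dtype=float)
    g0 = data.loc[~data[flag].astype(bool), variable].to_numpy(dtype=float)
    if len(g1) < 2 or len(g0) < 2:
        raise InsufficientDataError(f"group sizes {len(g1)}/{len(g0)}; need >= 2 each")
    t = stats.ttest_ind(g1, g0, equal_var=not welch)
    return GroupComparison(
        variable=variable,
        group_names=(f"{flag}=True", f"{flag}=False"),
        means=(float(g1.mean()), float(g0.mean())),
        sds=(float(g1.std(ddof=1)), float(g0.std(ddof=1))),
        ns=(len(g1), len(g0)),
        p_value=float(t.pvalue),
        welch=welch,
    )


@dataclass
class AnovaResult:
    variable: str
    group_means: dict[int, float]
    group_ns: dict[int, int]
    f_statistic: float
    p_value: float


def anova_across_gold(table: pd.DataFrame, variable: str, grade_col: str = "gold_grade") -> AnovaResult:
    """One-way fixed-effects ANOVA of ``variable`` across GOLD grades."""
    data = table[[grade_col, variable]].dropna()
    groups = {int(g): sub[variable].to_numpy(dtype=float) for g, sub in data.groupby(grade_col)}
    groups = {g: v for g, v in groups.items() if len(v) >= 2}
    if len(groups) < 2:
        raise InsufficientDataError("ANOVA needs >= 2 grades with >= 2 subjects each")
    f, p = stats.f_oneway(*groups.values())
    return AnovaResult(
        variable=variable,
        group_means={g: float(v.mean()) for g, v in groups.items()},
        group_ns={g: len(v) for g, v in groups.items()},
        f_statistic=float(f),
        p_value=float(p),
    )
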