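"""Cohort-level statistics for the electrical activation parameters.

Implements the analysis layer applied to a cohort table:

* one-sample t-tests of the time-to-80% ratios against the constant-rate
  reference value 0.8 (linear activation over the QRS implies each 80%
  time equals 0.8 × QRS duration);
* per-group (LBBB vs RBBB) regression slopes of LV80/RV80/BIV80 on QRS
  duration, with the group difference tested via the group×QRS interaction
  in the pooled model;
* ratio models with moderator interactions (scar, ischemic etiology, Q-LV,
  QRS duration);
* robust (Huber M-estimator) regression of CRT response measures on the
  electrical predictors;
* Pearson correlation and nonparametric group comparisons
  (Kruskal–Wallis, Fisher exact, Shapiro–Wilk diagnostics).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from math import lgamma

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats as sps


class SampleSizeError(ValueError):
    """Too few observations for the requested test or model."""


class FitError(RuntimeError):
    """A regression fit failed (rank deficiency or non-convergence)."""


# ---------------------------------------------------------------------------
# simple tests
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TTestResult:
    t: float
    df: int
    p: float
    mean: float
    n: int
    mu0: float


def one_sample_t_vs(values, mu0: float = 0.8) -> TTestResult:
    """Two-sided one-sample t-test of ``values`` against ``mu0``.

    The default reference 0.8 is the value every time-to-80%/QRS ratio takes
    under a constant rate of chamber activation throughout the QRS.
    """
    x = np.asarray(values, dtype=float)
    if x.ndim != 1 or len(x) < 2:
        raise SampleSizeError("one-sample t-test needs at least 2 values")
    if not np.all(np.isfinite(x)):
        raise ValueError("values must be finite")
    if np.std(x, ddof=1) == 0.0:
        # degenerate sample: all values identical
        same = x[0] == mu0
        return TTestResult(
            t=0.0 if same else float(np.sign(x[0] - mu0)) * np.inf,
            df=len(x) - 1,
            p=1.0 if same else 0.0,
            mean=float(x[0]),
            n=len(x),
            mu0=mu0,
        )
    res = sps.ttest_1samp(x, popmean=mu0)
    return TTestResult(
        t=float(res.statistic),
        df=len(x) - 1,
        p=float(res.pvalue),
        mean=float(x.mean()),
        n=len(x),
        mu0=mu0,
    )


def pearson_corr(x, y) -> tuple[float, float]:
    """Pearson product-moment correlation with its t-based two-sided p."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 3:
        raise SampleSizeError("pearson_corr needs matched samples with n >= 3")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("correlation undefined for zero-variance input")
    r, p = sps.pearsonr(x, y)
    return float(r), float(p)


# ---------------------------------------------------------------------------
# regression results
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RegressionResult:
    """A fitted linear model summary.

    ``coefficients``, ``std_errors`` and ``p_values`` are pandas Series
    indexed by term name (including ``const``).  For robust fits,
    ``r_squared`` and ``model_p`` come from the weighted least-squares step
    at the final Huber weights.
    """

    method: str
    coefficients: pd.Series
    std_errors: pd.Series
    p_values: pd.Series
    r_squared: float
    model_p: float
    n_used: int

    def __post_init__(self) -> None:
        pv = self.p_values.to_numpy(float)
        if np.any((pv < 0) | (pv > 1)):
            raise ValueError("p-values must lie in [0, 1]")


def _design(df: pd.DataFrame, predictors: list[str]) -> pd.DataFrame:
    X = df[list(predictors)].astype(float)
    return sm.add_constant(X, has_constant="add")


def _check_rank(X: pd.DataFrame) -> None:
    rank = np.linalg.matrix_rank(X.to_numpy())
    if rank < X.shape[1]:
        raise FitError(
            f"design matrix is rank deficient (rank {rank} < {X.shape[1]}); "
            f"collinear terms among {list(X.columns)}"
        )


def robust_regress(
    cohort: pd.DataFrame,
    outcome: str,
    predictors: list[str],
    method: str = "huber",
) -> RegressionResult:
    """Regress a response measure on electrical predictors.

    ``method="huber"`` (default) fits a Huber M-estimator by iteratively
    reweighted least squares: tuning constant 1.345, scale re-estimated each
    iteration from the median absolute deviation, convergence when the
    maximum coefficient change falls below 1e-8 (at most 200 iterations).
    Standard errors and p-values come from the robust fit; R² and the model
    p-value from a weighted least-squares fit at the final Huber weights.
    ``method="ols"`` fits ordinary least squares.

    Rows with a missing outcome or predictor are dropped listwise; the
    remaining count is reported as ``n_used``.
    """
    cols = [outcome] + list(predictors)
    missing = [c for c in cols if c not in cohort.columns]
    if missing:
        raise KeyError(f"columns not in cohort table: {missing}")
    data = cohort[cols].dropna()
    n_used = len(data)
    if n_used <= len(predictors) + 1:
        raise SampleSizeError(
            f"{n_used} complete rows for {len(predictors) + 1} coefficients"
        )
    y = data[outcome].astype(float)
    X = _design(data, predictors)
    _check_rank(X)
    if method == "ols":
        fit = sm.OLS(y, X).fit()
        return RegressionResult(
            method="ols",
            coefficients=fit.params,
            std_errors=fit.bse,
            p_values=fit.pvalues,
            r_squared=float(fit.rsquared),
            model_p=float(fit.f_pvalue),
            n_used=n_used,
        )
    if method != "huber":
        raise ValueError(f"method must be 'huber' or 'ols', got {method!r}")
    model = sm.RLM(y, X, M=sm.robust.norms.HuberT(t=1.345))
    fit = model.fit(maxiter=200, tol=1e-8, conv="coefs", scale_est="mad")
    if len(fit.fit_history.get("params", [])) >= 200:
        raise FitError(
            f"Huber IRLS did not converge in 200 iterations; "
            f"last coefficients {fit.params.to_dict()}"
        )
    wls = sm.WLS(y, X, weights=fit.weights).fit()
    return RegressionResult(
        method="huber",
        coefficients=fit.params,
        std_errors=fit.bse,
        p_values=fit.pvalues,
        r_squared=float(wls.rsquared),
        model_p=float(wls.f_pvalue),
        n_used=n_used,
    )


# ---------------------------------------------------------------------------
# group slopes and ratio models
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GroupSlopes:
    """Per-group OLS slopes of a chamber metric on QRS duration.

    ``slopes[group]`` is the within-group slope; the LBBB-vs-RBBB slope
    difference is tested by the ``group × QRS`` interaction term of the
    pooled model (its coefficient equals the difference of the two
    within-group slopes).
    """

    metric: str
    setting: str
    slopes: dict
    intercepts: dict
    interaction_coef: float
    interaction_p: float
    n_by_group: dict


def _metric_column(metric: str, setting: str) -> str:
    return f"{metric.lower()}_{setting.lower()}"


def slope_by_group(
    cohort: pd.DataFrame,
    metric: str = "LV80",
    setting: str = "INTRINSIC",
    group_col: str = "bbb",
    qrs_col: str = "qrs_ms",
) -> GroupSlopes:
    """Within-group slopes of LV80/RV80/BIV80 versus QRS, plus interaction test.

    The slope of a chamber metric on QRS duration approximates the group's
    average metric/QRS ratio; under constant-rate activation it would be 0.8.
    """
    ycol = _metric_column(metric, setting)
    if ycol not in cohort.columns:
        raise KeyError(f"metric column {ycol!r} not in cohort table")
    data = cohort[[ycol, qrs_col, group_col]].dropna()
    groups = sorted(data[group_col].unique())
    if len(groups) != 2:
        raise SampleSizeError(f"need exactly 2 groups, found {groups}")
    slopes, intercepts, n_by_group = {}, {}, {}
    for g in groups:
        sub = data[data[group_col] == g]
        if len(sub) < 3:
            raise SampleSizeError(f"group {g} has {len(sub)} < 3 patients")
        X = sm.add_constant(sub[[qrs_col]].astype(float))
        _check_rank(X)
        fit = sm.OLS(sub[ycol].astype(float), X).fit()
        slopes[g] = float(fit.params[qrs_col])
        intercepts[g] = float(fit.params["const"])
        n_by_group[g] = len(sub)
    pooled = data.copy()
    pooled["group_ind"] = (pooled[group_col] == groups[1]).astype(float)
    pooled["interaction"] = pooled["group_ind"] * pooled[qrs_col].astype(float)
    X = sm.add_constant(pooled[[qrs_col, "group_ind", "interaction"]].astype(float))
    _check_rank(X)
    fit = sm.OLS(pooled[ycol].astype(float), X).fit()
    return GroupSlopes(
        metric=metric,
        setting=setting,
        slopes=slopes,
        intercepts=intercepts,
        interaction_coef=float(fit.params["interaction"]),
        interaction_p=float(fit.pvalues["interaction"]),
        n_by_group=n_by_group,
    )


@dataclass(frozen=True)
class RatioModelResult:
    """BBB effect on a metric/QRS ratio, with per-moderator interaction p's."""

    ratio: str
    bbb_coef: float
    bbb_p: float
    interaction_p: dict
    base_fit: RegressionResult


def ratio_model(
    cohort: pd.DataFrame,
    metric: str = "LV80",
    setting: str = "INTRINSIC",
    moderators: tuple = (),
    group_col: str = "bbb",
    qrs_col: str = "qrs_ms",
) -> RatioModelResult:
    """Model a metric/QRS ratio on LBBB-vs-RBBB status, probing moderators.

    Fits ``ratio ~ LBBB`` (LBBB coded 1) and, for each moderator, adds the
    moderator and its LBBB interaction, reporting the interaction p-value —
    i.e. whether the LBBB/RBBB difference in the ratio depends on scar,
    ischemic etiology, Q-LV or QRS duration.
    """
    ycol = _metric_column(metric, setting)
    data = cohort.copy()
    data["_ratio"] = data[ycol].astype(float) / data[qrs_col].astype(float)
    data["_lbbb"] = (data[group_col] == "LBBB").astype(float)
    base = robust_regress(
        data.rename(columns={"_ratio": "ratio", "_lbbb": "lbbb"}),
        "ratio",
        ["lbbb"],
        method="ols",
    )
    inter_p = {}
    for mod in moderators:
        if mod not in data.columns:
            raise KeyError(f"moderator {mod!r} not in cohort table")
        sub = data[["_ratio", "_lbbb", mod]].dropna().astype(float)
        sub["_inter"] = sub["_lbbb"] * sub[mod]
        X = sm.add_constant(sub[["_lbbb", mod, "_inter"]])
        _check_rank(X)
        fit = sm.OLS(sub["_ratio"], X).fit()
        inter_p[mod] = float(fit.pvalues["_inter"])
    return RatioModelResult(
        ratio=f"{metric}/QRS ({setting})",
        bbb_coef=float(base.coefficients["lbbb"]),
        bbb_p=float(base.p_values["lbbb"]),
        interaction_p=inter_p,
        base_fit=base,
    )


# ---------------------------------------------------------------------------
# nonparametric group comparisons
# ---------------------------------------------------------------------------

def fisher_exact_2xk(table: np.ndarray) -> float:
    """Two-sided Fisher exact p for a 2×k contingency table.

    Exact conditional enumeration: with both margins fixed, the p-value is
    the total probability of all tables whose point probability (a product
    of hypergeometric terms) does not exceed the observed table's.
    Delegates to the standard 2×2 routine when k = 2.
    """
    table = np.asarray(table, dtype=np.int64)
    if table.ndim != 2 or table.shape[0] != 2:
        raise ValueError("table must be 2×k")
    if table.shape[1] == 2:
        return float(sps.fisher_exact(table)[1])
    col_sums = table.sum(axis=0)
    row0 = int(table.sum(axis=1)[0])
    n = int(table.sum())

    def log_prob(cells0) -> float:
        # P(table | margins) = Π C(colsum_j, x_j) / C(n, row0)
        lp = -(lgamma(n + 1) - lgamma(row0 + 1) - lgamma(n - row0 + 1))
        for x, cs in zip(cells0, col_sums):
            lp += lgamma(cs + 1) - lgamma(x + 1) - lgamma(cs - x + 1)
        return lp

    observed = log_prob(table[0])
    total = 0.0
    ranges = [range(int(c) + 1) for c in col_sums[:-1]]
    for cells in itertools.product(*ranges):
        last = row0 - sum(cells)
        if not 0 <= last <= col_sums[-1]:
            continue
        lp = log_prob((*cells, last))
        if lp <= observed + 1e-9:
            total += np.exp(lp)
    return float(min(total, 1.0))


def group_compare(
    cohort: pd.DataFrame,
    variable: str,
    kind: str = "continuous",
    group_col: str = "bbb",
):
    """Compare a variable between the two bundle-branch-block groups.

    ``kind="continuous"`` runs a Kruskal–Wallis test on the two group
    samples; ``kind="categorical"`` a Fisher exact test on the 2×k table of
    group × category counts.  Returns ``(statistic, p)`` for continuous and
    ``(table, p)`` for categorical comparisons.
    """
    data = cohort[[variable, group_col]].dropna()
    groups = sorted(data[group_col].unique())
    if len(groups) != 2 or any((data[group_col] == g).sum() == 0 for g in groups):
        raise SampleSizeError("need two non-empty groups")
    if kind == "continuous":
        samples = [data.loc[data[group_col] == g, variable].astype(float) for g in groups]
        stat, p = sps.kruskal(*samples)
        return float(stat), float(p)
    if kind == "categorical":
        table = pd.crosstab(data[group_col], data[variable]).to_numpy()
        return table, fisher_exact_2xk(table)
    raise ValueError(f"kind must be 'continuous' or 'categorical', got {kind!r}")


def shapiro_normality(values) -> tuple[float, float]:
    """Shapiro–Wilk normality diagnostic: (W, p)."""
    x = np.asarray(values, dtype=float)
    if len(x) < 3:
        raise SampleSizeError("Shapiro–Wilk needs n >= 3")
    res = sps.shapiro(x)
    return float(res.statistic), float(res.pvalue)


def benjamini_hochberg(p_values) -> np.ndarray:
    """Benjamini–Hochberg adjusted p-values (optional; raw p's are the default
    reporting convention throughout this package)."""
    from statsmodels.stats.multitest import multipletests

    return multipletests(np.asarray(p_values, float), method="fdr_bh")[1]
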