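"""Cohort-level group comparisons: normality-gated test selection, Cohen's d,
ordinary least-squares regression, and the packaged demographics worked
example.

Group comparisons follow the convention of mainstream biostatistics
software: a Kolmogorov-Smirnov (Lilliefors) normality check on each group
gates the choice between an equal-variance two-sided Student's t-test and a
two-sided Mann-Whitney U test; Cohen's d (pooled SD) is always reported.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.stats
from statsmodels.stats.diagnostic import lilliefors

from .io import ValidationError, load_table1

logger = logging.getLogger(__name__)


@dataclass
class ComparisonResult:
    test_used: str                  # "t_test" or "mann_whitney"
    statistic: float
    p: float
    cohen_d: float
    normality_p_x: float
    normality_p_y: float
    mean_x: float
    mean_y: float
    sd_x: float
    sd_y: float
    n_x: int
    n_y: int


@dataclass
class RegressionResult:
    slope: float
    intercept: float
    r_squared: float
    p: float
    n: int


def ks_normality(x) -> float:
    """Lilliefors-corrected Kolmogorov-Smirnov p-value against normality.

    The KS distance is taken against a normal with the sample's mean and SD;
    because those parameters are estimated, the p-value uses the
    Dallal-Wilkinson-Lilliefors approximation rather than the naive KS null
    (which would be anticonservative).
    """
    x = np.asarray(x, float)
    if x.size < 4:
        raise ValidationError("ks_normality needs n >= 4")
    if np.ptp(x) == 0:
        raise ValidationError("ks_normality: zero variance")
    _, p = lilliefors(x, dist="norm", pvalmethod="approx")
    return float(min(p, 1.0))


def cohen_d(x, y) -> float:
    """Standardized mean difference with the pooled standard deviation."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.size < 2 or y.size < 2:
        raise ValidationError("cohen_d needs n >= 2 per group")
    nx, ny = x.size, y.size
    pooled = np.sqrt(((nx - 1) * x.var(ddof=1) + (ny - 1) * y.var(ddof=1)) / (nx + ny - 2))
    if pooled == 0:
        raise ValidationError("cohen_d: zero pooled SD")
    return float((x.mean() - y.mean()) / pooled)


def _mann_whitney(x, y) -> tuple[float, float]:
    pooled = np.concatenate([x, y])
    if np.all(pooled == pooled[0]):
        return float(len(x) * len(y) / 2), 1.0
    no_ties = np.unique(pooled).size == pooled.size
    method = "exact" if (max(len(x), len(y)) <= 8 and no_ties) else "asymptotic"
    res = scipy.stats.mannwhitneyu(x, y, alternative="two-sided", method=method,
                                   use_continuity=True)
    return float(res.statistic), float(res.pvalue)


def compare_groups(x, y, alpha_normality: float = 0.05) -> ComparisonResult:
    """Two-group comparison with a normality gate.

    If both groups pass the Lilliefors normality check (p > alpha), an
    equal-variance two-sided Student's t-test is used; otherwise a two-sided
    Mann-Whitney U test.  Groups smaller than 4 cannot be gated and default
    to Mann-Whitney with a warning.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.size == 0 or y.size == 0:
        raise ValidationError("compare_groups: empty group")

    px = py = np.nan
    if x.size >= 4 and y.size >= 4 and np.ptp(x) > 0 and np.ptp(y) > 0:
        px, py = ks_normality(x), ks_normality(y)
        normal = px > alpha_normality and py > alpha_normality
    else:
        warnings.warn("group too small (or constant) for the normality gate; "
                      "falling back to Mann-Whitney U")
        normal = False

    if normal:
        stat, p = scipy.stats.ttest_ind(x, y, equal_var=True)
        test = "t_test"
        if np.isnan(p):   # identical constant groups
            p = 1.0
    else:
        stat, p = _mann_whitney(x, y)
        test = "mann_whitney"

    try:
        d = cohen_d(x, y)
    except ValidationError:
        d = 0.0 if x.mean() == y.mean() else np.nan
    return ComparisonResult(
        test_used=test, statistic=float(stat), p=float(min(p, 1.0)), cohen_d=d,
        normality_p_x=px, normality_p_y=py,
        mean_x=float(x.mean()), mean_y=float(y.mean()),
        sd_x=float(x.std(ddof=1)) if x.size > 1 else np.nan,
        sd_y=float(y.std(ddof=1)) if y.size > 1 else np.nan,
        n_x=int(x.size), n_y=int(y.size),
    )


def linear_regression(x, y) -> RegressionResult:
    """Ordinary least squares of y on x; slope p from the t-test with n-2 df."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.size != y.size or x.size < 3:
        raise ValidationError("linear_regression needs n >= 3 paired values")
    if np.ptp(x) == 0:
        raise ValidationError("linear_regression: constant covariate")
    res = scipy.stats.linregress(x, y)
    return RegressionResult(
        slope=float(res.slope),
        intercept=float(res.intercept),
        r_squared=float(res.rvalue ** 2),
        p=float(res.pvalue) if not np.isnan(res.pvalue) else 0.0,
        n=int(x.size),
    )


def demographics_report(table: pd.DataFrame | None = None) -> pd.DataFrame:
    """Per-group means and gated group comparisons for a demographics table.

    With no argument, runs on the packaged 20-patient table (age in years,
    BMI in kg/m^2, prostate volume in mL; groups "small" and "large").
    Returns one row per variable with group means (also rounded to one
    decimal as printed summaries usually are), the selected test, p and
    Cohen's d (large vs small).
    """
    if table is None:
        table = load_table1()
    required = {"sample_id", "group"}
    if not required <= set(table.columns):
        raise ValidationError(f"demographics table must contain {sorted(required)}")
    variables = [c for c in table.columns if c not in required]
    groups = sorted(table["group"].unique())
    if len(groups) != 2:
        raise ValidationError("demographics_report expects exactly two groups")
    lo, hi = ("small", "large") if set(groups) == {"small", "large"} else groups

    rows = []
    for var in variables:
        x = table.loc[table["group"] == hi, var].to_numpy(float)
        y = table.loc[table["group"] == lo, var].to_numpy(float)
        cmp = compare_groups(x, y)
        rows.append({
            "variable": var,
            f"mean_{lo}": round(float(y.mean()), 1),
            f"mean_{hi}": round(float(x.mean()), 1),
            f"n_{lo}": y.size,
            f"n_{hi}": x.size,
            "test_used": cmp.test_used,
            "p": cmp.p,
            "cohen_d": cmp.cohen_d,
        })
    return pd.DataFrame(rows)
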