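"""Group comparisons for examinee cohorts.

Thin, validated wrappers over scipy.stats covering the three tests used to
compare correct- vs incorrect-answer groups: Student's two-sample t-test on
total scores (pooled variance by default, Welch by flag), Pearson's
chi-squared test of independence on categorical covariates (continuity
correction off by default), and Pearson correlation for paired continuous
measurements.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import AnalysisError


@dataclass(frozen=True)
class TTestResult:
    mean_a: float
    sd_a: float
    mean_b: float
    sd_b: float
    t: float
    p: float


@dataclass(frozen=True)
class Chi2Result:
    statistic: float
    df: int
    p: float


@dataclass(frozen=True)
class CorrelationResult:
    r: float
    p: float


def compare_continuous(
    group_a: Sequence[float], group_b: Sequence[float], equal_var: bool = True
) -> TTestResult:
    """Two-sample t-test on continuous scores (Student form by default)."""
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise AnalysisError(
            f"each group needs >= 2 observations (got {a.size} and {b.size})"
        )
    t, p = stats.ttest_ind(a, b, equal_var=equal_var)
    return TTestResult(
        mean_a=float(a.mean()),
        sd_a=float(a.std(ddof=1)),
        mean_b=float(b.mean()),
        sd_b=float(b.std(ddof=1)),
        t=float(t),
        p=float(p),
    )


def compare_categorical(table, correction: bool = False) -> Chi2Result:
    """Pearson chi-squared test of independence on a contingency table.

    *table* is a 2-D array of non-negative counts (groups x levels).  Yates'
    continuity correction is off by default; enable with ``correction=True``.
    """
    arr = np.asarray(table, dtype=float)
    if arr.ndim != 2 or min(arr.shape) < 2:
        raise AnalysisError(f"contingency table must be at least 2x2, got shape {arr.shape}")
    if (arr < 0).any():
        raise AnalysisError("contingency counts must be non-negative")
    row_sums = arr.sum(axis=1)
    col_sums = arr.sum(axis=0)
    if (row_sums == 0).any():
        raise AnalysisError(f"zero row margin at row {int(np.argmin(row_sums > 0))}")
    if (col_sums == 0).any():
        raise AnalysisError(f"zero column margin at column {int(np.argmin(col_sums > 0))}")
    res = stats.chi2_contingency(arr, correction=correction)
    return Chi2Result(statistic=float(res[0]), df=int(res[2]), p=float(res[1]))


def correlate(x: Sequence[float], y: Sequence[float]) -> CorrelationResult:
    """Pearson correlation with a two-sided t-approximation p value."""
    xa = np.asarray(x, dtype=float)
    ya = np.asarray(y, dtype=float)
    if xa.size != ya.size:
        raise AnalysisError(f"vectors differ in length ({xa.size} vs {ya.size})")
    if xa.size < 3:
        raise AnalysisError("correlation needs at least 3 paired observations")
    if xa.std() == 0.0 or ya.std() == 0.0:
        raise AnalysisError("correlation undefined: a vector has zero variance")
    r, p = stats.pearsonr(xa, ya)
    return CorrelationResult(r=float(r), p=float(p))


def cohort_comparison_table(
    cohort: pd.DataFrame, covariates: Sequence[str], score_col: str = "total_score"
) -> pd.DataFrame:
    """Correct- vs incorrect-group comparison of a cohort table.

    One chi-squared row per categorical covariate (levels collapsed into a
    single 2 x K table) and a final t-test row for the score column.
    Covariate rows with an examinee missing a value drop that examinee for
    that row only.
    """
    if "group" not in cohort.columns:
        raise AnalysisError("cohort table needs a 'group' column")
    rows = []
    for cov in covariates:
        sub = cohort[[cov, "group"]].dropna()
        table = pd.crosstab(sub["group"], sub[cov])
        table = table.reindex(index=["correct", "incorrect"], fill_value=0)
        res = compare_categorical(table.to_numpy())
        rows.append(
            {
                "variable": cov,
                "test": "chi2",
                "statistic": res.statistic,
                "df": res.df,
                "p": res.p,
            }
        )
    a = cohort.loc[cohort["group"] == "correct", score_col]
    b = cohort.loc[cohort["group"] == "incorrect", score_col]
    t = compare_continuous(a, b)
    rows.append(
        {"variable": score_col, "test": "t", "statistic": t.t, "df": len(a) + len(b) - 2, "p": t.p}
    )
    return pd.DataFrame(rows)
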