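"""Two-group cohort comparison: chi-square, Welch t, and absolute
standardized differences with the >10% imbalance flag.

With very large cohorts nearly any difference is statistically significant,
so alongside p-values each covariate gets an absolute standardized
difference (ASD), a scale-free effect size:

* binary:      ASD = 100 * |p1 − p2| / sqrt[(p1(1−p1) + p2(1−p2)) / 2]
* continuous:  ASD = 100 * |m1 − m2| / sqrt[(s1² + s2²) / 2]

An ASD above 10 percentage points flags a meaningfully imbalanced
covariate. Categorical variables are reported per level, each level as a
binary indicator. Displayed ASDs are rounded half away from zero to the
nearest integer percent; the raw value is kept alongside.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats


@dataclass(frozen=True)
class BinaryVarSummary:
    p1: float
    p2: float
    n1: int
    n2: int

    def __post_init__(self) -> None:
        if not (0 <= self.p1 <= 1 and 0 <= self.p2 <= 1):
            raise ValueError("proportions must lie in [0, 1]")


@dataclass(frozen=True)
class ContinuousVarSummary:
    m1: float
    s1: float
    m2: float
    s2: float
    n1: int
    n2: int

    def __post_init__(self) -> None:
        if self.s1 < 0 or self.s2 < 0:
            raise ValueError("standard deviations must be non-negative")


@dataclass(frozen=True)
class ComparisonRow:
    variable: str
    level: str
    asd_percent: float  # raw, unrounded
    asd_rounded: Optional[int]
    p_value: Optional[float]
    imbalanced: bool

    def __post_init__(self) -> None:
        if not math.isnan(self.asd_percent) and (self.asd_percent > 10) != self.imbalanced:
            raise ValueError("imbalanced flag must equal (ASD > 10)")


def round_half_away(x: float) -> int:
    """Round to the nearest integer, halves away from zero (table display)."""
    return int(math.floor(x + 0.5)) if x >= 0 else -int(math.floor(-x + 0.5))


def asd_binary(p1: float, p2: float) -> float:
    """Absolute standardized difference (raw percent) of two proportions.

    Returns NaN when both proportions are degenerate (0/1) in a way that
    zeroes the denominator; symmetric in its arguments.
    """
    if not (0 <= p1 <= 1 and 0 <= p2 <= 1):
        raise ValueError("proportions must lie in [0, 1]")
    denom = math.sqrt((p1 * (1 - p1) + p2 * (1 - p2)) / 2.0)
    if denom == 0.0:
        return 0.0 if p1 == p2 else math.nan
    return 100.0 * abs(p1 - p2) / denom


def asd_continuous(m1: float, s1: float, m2: float, s2: float) -> float:
    """Absolute standardized difference (raw percent) of two mean/SD pairs."""
    if s1 < 0 or s2 < 0:
        raise ValueError("standard deviations must be non-negative")
    denom = math.sqrt((s1 * s1 + s2 * s2) / 2.0)
    if denom == 0.0:
        return 0.0 if m1 == m2 else math.nan
    return 100.0 * abs(m1 - m2) / denom


def chi_square_test(table) -> tuple[float, float]:
    """Pearson chi-square on a 2xk contingency table, no continuity
    correction, df = k−1. Zero marginals are an error."""
    arr = np.asarray(table, dtype=float)
    if arr.ndim != 2 or arr.shape[0] != 2 or arr.shape[1] < 2:
        raise ValueError("expected a 2 x k contingency table with k >= 2")
    if (arr < 0).any():
        raise ValueError("counts must be non-negative")
    if (arr.sum(axis=0) == 0).any() or (arr.sum(axis=1) == 0).any():
        raise ValueError("contingency table has a zero marginal")
    stat, p, _, _ = stats.chi2_contingency(arr, correction=False)
    return float(stat), float(p)


def two_sample_t_test(summary: ContinuousVarSummary) -> tuple[float, float]:
    """Two-sided Welch t-test from summary statistics."""
    if summary.n1 < 2 or summary.n2 < 2:
        raise ValueError("each group needs n >= 2")
    res = stats.ttest_ind_from_stats(
        summary.m1, summary.s1, summary.n1,
        summary.m2, summary.s2, summary.n2,
        equal_var=False,
    )
    return float(res.statistic), float(res.pvalue)


def _row(variable: str, level: str, asd: float, p: Optional[float]) -> ComparisonRow:
    rounded = None if math.isnan(asd) else round_half_away(asd)
    imb = False if math.isnan(asd) else asd > 10
    return ComparisonRow(variable, level, asd, rounded, p, imb)


def build_comparison_table(
    patients: pd.DataFrame,
    group_col: str,
    group_a: str,
    group_b: str,
    variables: Mapping[str, str],
) -> pd.DataFrame:
    """Compare two patient groups on the requested covariates.

    ``variables`` maps column name -> kind in {"binary", "continuous",
    "categorical"}. Binary columns get a 2x2 chi-square p-value and a
    proportion ASD; continuous columns a Welch-t p-value and a mean/SD ASD;
    categorical columns one 2xk chi-square p-value (repeated on each level
    row) and a per-level binary ASD. Output columns mirror a standard
    baseline-characteristics table.
    """
    for col in (group_col, *variables):
        if col not in patients.columns:
            raise ValueError(f"unknown variable/column {col!r}")
    bad = {k for k in variables.values()} - {"binary", "continuous", "categorical"}
    if bad:
        raise ValueError(f"unknown variable kinds: {sorted(bad)}")
    a = patients[patients[group_col] == group_a]
    b = patients[patients[group_col] == group_b]
    if a.empty or b.empty:
        raise ValueError(f"empty group selection ({group_a!r}: {len(a)}, {group_b!r}: {len(b)})")

    rows: list[ComparisonRow] = []
    stats_cols: list[dict] = []
    for var, kind in variables.items():
        if kind == "binary":
            x, y = a[var].astype(float), b[var].astype(float)
            p1, p2 = float(x.mean()), float(y.mean())
            table = [
                [float(x.sum()), float(len(x) - x.sum())],
                [float(y.sum()), float(len(y) - y.sum())],
            ]
            try:
                _, p = chi_square_test(table)
            except ValueError:
                p = None
            rows.append(_row(var, "", asd_binary(p1, p2), p))
            stats_cols.append({"stat_a": p1, "stat_b": p2})
        elif kind == "continuous":
            x, y = a[var].astype(float), b[var].astype(float)
            summ = ContinuousVarSummary(
                float(x.mean()), float(x.std(ddof=1)),
                float(y.mean()), float(y.std(ddof=1)),
                len(x), len(y),
            )
            _, p = two_sample_t_test(summ)
            rows.append(_row(var, "", asd_continuous(summ.m1, summ.s1, summ.m2, summ.s2), p))
            stats_cols.append(
                {"stat_a": f"{summ.m1:.2f}/{summ.s1:.2f}", "stat_b": f"{summ.m2:.2f}/{summ.s2:.2f}"}
            )
        else:  # categorical
            levels = sorted(set(a[var].astype(str)) | set(b[var].astype(str)))
            counts_a = a[var].astype(str).value_counts()
            counts_b = b[var].astype(str).value_counts()
            table = [
                [float(counts_a.get(lv, 0)) for lv in levels],
                [float(counts_b.get(lv, 0)) for lv in levels],
            ]
            try:
                _, p = chi_square_test(table)
            except ValueError:
                p = None
            for lv in levels:
                p1 = float(counts_a.get(lv, 0)) / len(a)
                p2 = float(counts_b.get(lv, 0)) / len(b)
                rows.append(_row(var, lv, asd_binary(p1, p2), p))
                stats_cols.append({"stat_a": p1, "stat_b": p2})
    out = pd.DataFrame(
        {
            "variable": [r.variable for r in rows],
            "level": [r.level for r in rows],
            "stat_a": [c["stat_a"] for c in stats_cols],
            "stat_b": [c["stat_b"] for c in stats_cols],
            "p_value": [r.p_value for r in rows],
            "asd_percent": [r.asd_percent for r in rows],
            "asd_rounded": [r.asd_rounded for r in rows],
            "imbalanced": [r.imbalanced for r in rows],
        }
    )
    return out


#: variable kinds matching the synthetic patient table columns
DEFAULT_VARIABLES: dict[str, str] = {
    "gender": "categorical",
    "age": "continuous",
    "marital_status": "categorical",
    "race": "categorical",
    "ethnicity": "categorical",
    "hypertension": "binary",
    "diabetes": "binary",
    "depression": "binary",
    "ptsd": "binary",
    "cancer": "binary",
    "tobacco": "binary",
    "alcohol": "binary",
    "other_drug_addictions": "binary",
    "tbi": "binary",
    "anxiety": "binary",
    "neck_pain": "binary",
    "back_pain": "binary",
    "prior_opioid_rx": "binary",
    "concurrent_benzodiazepine_rx": "binary",
    "outpatient_encounters": "continuous",
}
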