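"""Group-comparison descriptives: median (IQR), Mann-Whitney U, chi-square.

Builds the baseline-characteristics table comparing metabolically healthy
and unhealthy nonobese groups: skewed continuous variables summarised as
median (Q1, Q3) and compared with the Mann-Whitney U test; categorical
variables as counts/proportions compared with Pearson chi-square.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .phenotype import MHNO, MUNO

#: Quantile estimator used everywhere (descriptives and quartile cutpoints):
#: linear interpolation between order statistics.
QUANTILE_METHOD = "linear"

#: Per-group size below which the exact Mann-Whitney null distribution is
#: enumerated instead of the normal approximation.
EXACT_MAX_N = 8


@dataclass
class GroupComparison:
    variable: str
    summary_a: tuple  # (q1, median, q3) or (count, pct)
    summary_b: tuple
    test: str  # "mann_whitney" | "chi_square"
    statistic: float
    p_value: float


def median_iqr(values) -> tuple[float, float, float]:
    """Return (q1, median, q3) by linear interpolation between order
    statistics."""
    arr = np.asarray(values, dtype=float)
    arr = arr[~np.isnan(arr)]
    if arr.size == 0:
        raise ValueError("median_iqr: empty input")
    q1, med, q3 = np.quantile(arr, [0.25, 0.5, 0.75], method=QUANTILE_METHOD)
    return float(q1), float(med), float(q3)


def mann_whitney(group_a, group_b) -> tuple[float, float]:
    """Two-sided Mann-Whitney U test with midranks and tie correction.

    Returns ``(U, p)`` with U reported under the min convention
    (``min(U_A, U_B)``).  The exact null distribution is enumerated when
    both groups have fewer than :data:`EXACT_MAX_N` observations and there
    are no ties; otherwise the normal approximation with continuity
    correction is used.  Fully tied data (every value identical) returns
    p = 1 by contract.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("mann_whitney: both groups must be nonempty")
    n_ab = a.size * b.size
    combined = np.concatenate([a, b])
    if np.all(combined == combined[0]):
        return n_ab / 2.0, 1.0
    if a.size < EXACT_MAX_N and b.size < EXACT_MAX_N:
        u1, p = _exact_mann_whitney(a, b)
    else:
        res = stats.mannwhitneyu(a, b, alternative="two-sided",
                                 method="asymptotic", use_continuity=True)
        u1, p = float(res.statistic), float(res.pvalue)
    return min(u1, n_ab - u1), float(min(p, 1.0))


def _exact_mann_whitney(a: np.ndarray, b: np.ndarray) -> tuple[float, float]:
    """Tie-aware exact test: enumerate every assignment of the pooled
    values to the two groups and count |U - mean| at least as extreme as
    observed (the permutation null of midrank U is symmetric)."""
    from itertools import combinations

    pooled = np.concatenate([a, b])
    ranks = stats.rankdata(pooled)
    na = a.size
    offset = na * (na + 1) / 2
    mean_u = na * b.size / 2.0
    u_obs = ranks[:na].sum() - offset
    d_obs = abs(u_obs - mean_u)
    n_extreme = 0
    n_total = 0
    for ia in combinations(range(pooled.size), na):
        u = ranks[list(ia)].sum() - offset
        n_extreme += abs(u - mean_u) >= d_obs - 1e-12
        n_total += 1
    return float(u_obs), n_extreme / n_total


def chi_square(table) -> tuple[float, float]:
    """Pearson chi-square test of independence (no Yates correction) on a
    2×k contingency table of nonnegative integer counts."""
    tab = np.asarray(table, dtype=float)
    if tab.ndim != 2 or np.any(tab < 0):
        raise ValueError("chi_square: need a 2-D table of nonnegative counts")
    if np.any(tab.sum(axis=0) == 0) or np.any(tab.sum(axis=1) == 0):
        raise ValueError("chi_square: zero marginal total")
    x2, p, _, _ = stats.chi2_contingency(tab, correction=False)
    return float(x2), float(p)


#: Default table rows: continuous variables summarised as median (IQR).
CONTINUOUS_VARS = ["age", "sbp", "dbp", "wc", "bmi", "whtr", "cvai", "vai",
                   "lap", "absi", "fpg", "tg", "hdl", "ldl", "tc"]
#: Categorical (binary) variables summarised as n (%).
CATEGORICAL_VARS = ["sex_male", "on_antihypertensive", "on_antidiabetic",
                    "smoker_history", "education_ge_junior_high"]


def build_table1(classified: pd.DataFrame,
                 continuous: list[str] | None = None,
                 categorical: list[str] | None = None) -> pd.DataFrame:
    """Baseline-characteristics table: one row per variable with MHNO and
    MUNO group summaries and a two-sided p-value.

    Continuous rows report ``median (q1, q3)`` per group and a Mann-Whitney
    p; categorical rows report ``n (pct%)`` and a chi-square p.
    """
    df = classified.copy()
    if "sex_male" not in df.columns:
        df["sex_male"] = (df["sex"] == "male").astype(int)
    continuous = CONTINUOUS_VARS if continuous is None else continuous
    categorical = CATEGORICAL_VARS if categorical is None else categorical

    g_mhno = df[df["phenotype"] == MHNO]
    g_muno = df[df["phenotype"] == MUNO]
    if len(g_mhno) == 0 or len(g_muno) == 0:
        raise ValueError("build_table1: both phenotype groups must be nonempty")

    rows = []
    for var in continuous:
        if var not in df.columns:
            continue
        a = g_mhno[var].dropna().to_numpy()
        b = g_muno[var].dropna().to_numpy()
        if a.size == 0 or b.size == 0:
            continue
        qa, qb = median_iqr(a), median_iqr(b)
        u, p = mann_whitney(a, b)
        rows.append({
            "variable": var, "test": "mann_whitney",
            "mhno_summary": f"{qa[1]:.2f} ({qa[0]:.2f}, {qa[2]:.2f})",
            "muno_summary": f"{qb[1]:.2f} ({qb[0]:.2f}, {qb[2]:.2f})",
            "statistic": u, "p_value": p,
        })
    for var in categorical:
        if var not in df.columns:
            continue
        ca1 = int(g_mhno[var].astype(bool).sum())
        cb1 = int(g_muno[var].astype(bool).sum())
        table = [[ca1, len(g_mhno) - ca1], [cb1, len(g_muno) - cb1]]
        if min(ca1 + cb1, len(g_mhno) + len(g_muno) - ca1 - cb1) == 0:
            continue  # variable constant in-sample; no test possible
        x2, p = chi_square(table)
        rows.append({
            "variable": var, "test": "chi_square",
            "mhno_summary": f"{ca1} ({100 * ca1 / len(g_mhno):.1f}%)",
            "muno_summary": f"{cb1} ({100 * cb1 / len(g_muno):.1f}%)",
            "statistic": x2, "p_value": p,
        })
    return pd.DataFrame(rows, columns=["variable", "mhno_summary",
                                       "muno_summary", "test", "statistic",
                                       "p_value"])
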