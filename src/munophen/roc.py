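"""Empirical ROC analysis, Youden-optimal cutoffs and the DeLong test.

The ROC curve is the empirical (FPR, TPR) staircase over all distinct score
thresholds with ties grouped; its trapezoidal area equals the Mann-Whitney
pair statistic (#concordant + half #tied) / (n1·n0) exactly, which is used
as an internal consistency check.  The convention throughout is that a
higher score predicts the positive (metabolically unhealthy) class.

AUC uncertainty and paired AUC comparisons use DeLong's nonparametric
placement-value covariance: for index k, each positive subject contributes
its placement V10 (fraction of negatives it outscores, ties half) and each
negative its V01; the covariance of the AUC vector across indices is
S10/m + S01/n with empirical covariance matrices of the placements.  The
paired test statistic is Z = (AUC_A − AUC_B) / sqrt(varA + varB − 2 cov).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

Z975 = 1.959963984540054


class RocError(ValueError):
    pass


def _check_binary(labels) -> np.ndarray:
    y = np.asarray(labels, dtype=int)
    classes = np.unique(y)
    if not np.array_equal(classes, [0, 1]):
        raise RocError(f"labels must contain both classes 0 and 1, got {classes}")
    return y


def roc_points(scores, labels) -> np.ndarray:
    """Empirical ROC curve as an (k+2, 2) array of (fpr, tpr) vertices.

    One vertex per distinct score value (ties grouped), from (0, 0) to
    (1, 1), monotone nondecreasing in both coordinates.
    """
    y = _check_binary(labels)
    s = np.asarray(scores, dtype=float)
    order = np.argsort(-s, kind="mergesort")
    s_sorted, y_sorted = s[order], y[order]
    # group ties: take cumulative counts at the last element of each tie block
    distinct = np.r_[np.nonzero(np.diff(s_sorted))[0], s_sorted.size - 1]
    tp = np.cumsum(y_sorted)[distinct]
    fp = np.cumsum(1 - y_sorted)[distinct]
    n1, n0 = tp[-1], fp[-1]
    fpr = np.r_[0.0, fp / n0]
    tpr = np.r_[0.0, tp / n1]
    return np.column_stack([fpr, tpr])


def auc_trapezoid(points: np.ndarray) -> float:
    """Trapezoidal area under an ROC vertex array from :func:`roc_points`."""
    pts = np.asarray(points, dtype=float)
    return float(np.trapezoid(pts[:, 1], pts[:, 0]))


def auc_mann_whitney(scores, labels) -> float:
    """AUC as the Mann-Whitney pair probability via midranks:
    P(score_pos > score_neg) + ½ P(tie)."""
    y = _check_binary(labels)
    s = np.asarray(scores, dtype=float)
    ranks = stats.rankdata(s)
    n1 = int(y.sum())
    n0 = y.size - n1
    return float((ranks[y == 1].sum() - n1 * (n1 + 1) / 2) / (n1 * n0))


def youden_cutoff(scores, labels) -> tuple[float, float, float, float]:
    """Youden-optimal cutoff over observed distinct score values.

    The classification rule is "positive if score >= cutoff"; the cutoff
    maximising J = sensitivity + specificity − 1 is returned as
    ``(cutoff, sensitivity, specificity, youden)``.  Ties in J — including
    floating-point near-ties within 1e-12 — are broken by the smallest
    cutoff.
    """
    y = _check_binary(labels)
    s = np.asarray(scores, dtype=float)
    n1 = int(y.sum())
    n0 = y.size - n1
    candidates = np.unique(s)  # ascending
    sens = np.array([(y[s >= c].sum()) / n1 for c in candidates])
    spec = np.array([((1 - y)[s < c].sum()) / n0 for c in candidates])
    j = sens + spec - 1.0
    best = int(np.argmax(j >= j.max() - 1e-12))  # first == smallest cutoff
    return float(candidates[best]), float(sens[best]), float(spec[best]), float(j[best])


def _placements(scores: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray, float]:
    """DeLong structural components (V10 for positives, V01 for negatives)
    and the AUC, via midranks."""
    pos = scores[y == 1]
    neg = scores[y == 0]
    m, n = pos.size, neg.size
    all_ranks = stats.rankdata(np.r_[pos, neg])
    pos_ranks = stats.rankdata(pos)
    neg_ranks = stats.rankdata(neg)
    v10 = (all_ranks[:m] - pos_ranks) / n
    v01 = 1.0 - (all_ranks[m:] - neg_ranks) / m
    auc = float(v10.mean())
    return v10, v01, auc


@dataclass
class DeLongComparison:
    """Paired comparison of two AUCs on the same subjects.

    ``z`` is signed as AUC_first − AUC_second; ``p`` is two-sided normal.
    """

    index_a: str
    index_b: str
    auc_a: float
    auc_b: float
    z: float
    p_value: float
    degenerate_variance: bool = False


def delong_auc_variance(scores, labels) -> tuple[float, float]:
    """AUC and its DeLong variance for a single score vector."""
    y = _check_binary(labels)
    s = np.asarray(scores, dtype=float)
    v10, v01, auc = _placements(s, y)
    var = v10.var(ddof=1) / v10.size + v01.var(ddof=1) / v01.size
    return auc, float(var)


def delong_test(scores_a, scores_b, labels,
                index_a: str = "A", index_b: str = "B") -> DeLongComparison:
    """DeLong paired test for the difference of two correlated AUCs
    measured on the same subjects."""
    y = _check_binary(labels)
    sa = np.asarray(scores_a, dtype=float)
    sb = np.asarray(scores_b, dtype=float)
    if sa.shape != sb.shape or sa.shape[0] != y.shape[0]:
        raise RocError("paired score vectors must match the label vector")
    v10a, v01a, auc_a = _placements(sa, y)
    v10b, v01b, auc_b = _placements(sb, y)
    m, n = v10a.size, v01a.size
    s10 = np.cov(np.vstack([v10a, v10b]), ddof=1)
    s01 = np.cov(np.vstack([v01a, v01b]), ddof=1)
    cov = s10 / m + s01 / n
    var_diff = cov[0, 0] + cov[1, 1] - 2 * cov[0, 1]
    if var_diff <= 1e-300:
        # degenerate variance: identical placements (p = 1) or perfect
        # separation with a real AUC gap (p -> 0); flagged either way
        diff = auc_a - auc_b
        if abs(diff) < 1e-12:
            return DeLongComparison(index_a, index_b, auc_a, auc_b, z=0.0,
                                    p_value=1.0, degenerate_variance=True)
        return DeLongComparison(index_a, index_b, auc_a, auc_b,
                                z=float(np.sign(diff) * np.inf), p_value=0.0,
                                degenerate_variance=True)
    z = (auc_a - auc_b) / np.sqrt(var_diff)
    p = 2 * stats.norm.sf(abs(z))
    return DeLongComparison(index_a, index_b, auc_a, auc_b,
                            z=float(z), p_value=float(p))


@dataclass
class RocResult:
    """Per-index, per-stratum ROC summary."""

    index_name: str
    stratum: str
    auc: float
    ci_low: float
    ci_high: float
    auc_p_vs_chance: float
    cutoff: float
    sensitivity: float
    specificity: float
    youden: float


def roc_summary(scores, labels, index_name: str = "",
                stratum: str = "all") -> RocResult:
    """Full ROC summary for one index: AUC with 95% DeLong normal-theory
    CI (clipped to [0, 1]), p-value against AUC = 0.5, and the
    Youden-optimal operating point."""
    auc, var = delong_auc_variance(scores, labels)
    se = float(np.sqrt(var))
    if se > 0:
        p_chance = 2 * stats.norm.sf(abs(auc - 0.5) / se)
    else:
        p_chance = 1.0 if auc == 0.5 else 0.0
    cutoff, sens, spec, j = youden_cutoff(scores, labels)
    return RocResult(
        index_name=index_name, stratum=stratum, auc=auc,
        ci_low=max(0.0, auc - Z975 * se), ci_high=min(1.0, auc + Z975 * se),
        auc_p_vs_chance=float(p_chance), cutoff=cutoff,
        sensitivity=sens, specificity=spec, youden=j)


#: Index pairs compared by default (overlapping-CI pairs in the source
#: analysis design).
DEFAULT_DELONG_PAIRS = [
    ("bmi", "wc"), ("bmi", "whtr"), ("bmi", "absi"),
    ("wc", "whtr"), ("wc", "absi"), ("wc", "cvai"),
    ("whtr", "cvai"), ("whtr", "absi"), ("lap", "vai"),
]


def run_roc_table(df: pd.DataFrame, index_names: list[str],
                  outcome_col: str = "muno", sex_col: str = "sex",
                  pairs: list[tuple[str, str]] | None = None,
                  ) -> tuple[pd.DataFrame, pd.DataFrame, dict]:
    """Sex-stratified ROC summary and paired DeLong comparison tables.

    Returns ``(roc_table, delong_table, curves)`` where ``curves`` maps
    ``(stratum, index)`` to the ROC vertex array.  A stratum in which the
    outcome has a single class is skipped with a log entry.
    """
    import logging
    logger = logging.getLogger("munophen")
    pairs = DEFAULT_DELONG_PAIRS if pairs is None else pairs
    roc_rows, delong_rows, curves = [], [], {}
    for stratum, sub in df.groupby(sex_col, sort=True):
        y = sub[outcome_col].to_numpy(dtype=int)
        if np.unique(y).size < 2:
            logger.warning("run_roc_table: stratum %r has a single outcome "
                           "class; skipped", stratum)
            continue
        for name in index_names:
            s = sub[name].to_numpy(dtype=float)
            res = roc_summary(s, y, index_name=name, stratum=str(stratum))
            roc_rows.append(res.__dict__)
            curves[(str(stratum), name)] = roc_points(s, y)
        for a, b in pairs:
            cmp_ = delong_test(sub[a].to_numpy(dtype=float),
                               sub[b].to_numpy(dtype=float), y,
                               index_a=a, index_b=b)
            delong_rows.append({"stratum": str(stratum), **cmp_.__dict__})
    return pd.DataFrame(roc_rows), pd.DataFrame(delong_rows), curves


def plot_roc_curves(curves: dict, ax=None, stratum: str | None = None):
    """Plot stored ROC curves (one line per index) on a matplotlib axes."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(5, 5))
    for (strat, name), pts in curves.items():
        if stratum is not None and strat != stratum:
            continue
        label = name if stratum is not None else f"{name} ({strat})"
        ax.plot(pts[:, 0], pts[:, 1], label=label, lw=1.2)
    ax.plot([0, 1], [0, 1], "k--", lw=0.8)
    ax.set_xlabel("1 - specificity")
    ax.set_ylabel("sensitivity")
    ax.legend(fontsize=8)
    return ax
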