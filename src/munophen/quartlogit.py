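"""Quartile-based logistic regression of the MUNO phenotype on adiposity
indices.

Each index is cut at its cohort quartiles (Q1 = lowest, the reference
category) and the binary phenotype is regressed on the three upper-quartile
indicators with covariate adjustment (age, sex, education, smoking history
by default).  Odds ratios per quartile are exponentiated coefficients with
95% Wald confidence intervals.

The fitter is plain maximum likelihood via iteratively reweighted least
squares (IRLS): convergence when the largest absolute coefficient change
drops below 1e-8, at most 100 iterations.  The per-iteration log-likelihood
history is retained so monotone ascent can be verified.  Quasi-separation
is flagged (huge standard errors / non-convergence), never reported as a
silent number.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import expit

from .descriptives import QUANTILE_METHOD

Z975 = 1.959963984540054  # standard normal 97.5th percentile

DEFAULT_COVARIATES = ["age", "sex_male", "education_ge_junior_high",
                      "smoker_history"]


class FitError(ValueError):
    """Design-matrix or convergence failure."""


@dataclass
class QuartileBinning:
    """Quartile cutpoints and per-subject labels for one index."""

    index_name: str
    cutpoints: tuple[float, float, float]  # (q25, q50, q75)
    labels: np.ndarray  # int 1..4, 1 = lowest quartile

    def __post_init__(self) -> None:
        q25, q50, q75 = self.cutpoints
        if not (q25 <= q50 <= q75):
            raise FitError(f"{self.index_name}: cutpoints must be nondecreasing")


def quartile_bin(values, cutpoints=None, index_name: str = "") -> QuartileBinning:
    """Assign quartile labels 1-4 with intervals
    ``(-inf, q25], (q25, q50], (q50, q75], (q75, inf)``.

    Cutpoints default to the sample quartiles (same linear-interpolation
    estimator as the descriptives); a value exactly at a cutpoint falls in
    the lower bin.  Supplying ``cutpoints`` overrides, e.g. to reuse
    published cuts.
    """
    arr = np.asarray(values, dtype=float)
    if np.any(np.isnan(arr)):
        raise FitError(f"{index_name}: NaN values cannot be binned")
    if cutpoints is None:
        if np.unique(arr).size < 4:
            raise FitError(
                f"{index_name}: fewer than 4 distinct values; supply manual cutpoints")
        cutpoints = tuple(np.quantile(arr, [0.25, 0.5, 0.75], method=QUANTILE_METHOD))
    cutpoints = tuple(float(c) for c in cutpoints)
    labels = np.searchsorted(np.asarray(cutpoints), arr, side="left") + 1
    return QuartileBinning(index_name=index_name, cutpoints=cutpoints,
                           labels=labels.astype(int))


@dataclass
class LogisticFit:
    """Maximum-likelihood logistic regression result."""

    params: np.ndarray
    bse: np.ndarray
    cov: np.ndarray
    loglike_history: list[float]
    converged: bool
    n_iter: int
    separation_flag: bool
    exog_names: list[str] = field(default_factory=list)

    @property
    def loglike(self) -> float:
        return self.loglike_history[-1]

    def conf_int(self, alpha: float = 0.05) -> np.ndarray:
        z = stats.norm.ppf(1 - alpha / 2)
        return np.column_stack([self.params - z * self.bse,
                                self.params + z * self.bse])

    def pvalues(self) -> np.ndarray:
        z = self.params / self.bse
        return 2 * stats.norm.sf(np.abs(z))


def fit_logistic_irls(X: np.ndarray, y: np.ndarray,
                      tol: float = 1e-8, max_iter: int = 100,
                      exog_names: list[str] | None = None) -> LogisticFit:
    """Fit logit(P(y=1)) = X beta by IRLS.

    ``X`` must already contain the intercept column.  Raises
    :class:`FitError` when the outcome is one-class or the design matrix is
    rank deficient; quasi-separation is reported through
    ``separation_flag`` (SE > 100 on the log-odds scale, or
    non-convergence).
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n, p = X.shape
    if y.min() == y.max():
        raise FitError("outcome has a single class")
    if np.linalg.matrix_rank(X) < p:
        raise FitError("design matrix is rank deficient "
                       "(collinear or constant predictor)")

    beta = np.zeros(p)
    history: list[float] = []
    converged = False
    n_iter = 0
    for n_iter in range(1, max_iter + 1):
        eta = X @ beta
        mu = expit(eta)
        history.append(float(np.sum(y * eta - np.logaddexp(0.0, eta))))
        w = np.clip(mu * (1.0 - mu), 1e-10, None)
        xtwx = X.T @ (X * w[:, None])
        try:
            delta = np.linalg.solve(xtwx, X.T @ (y - mu))
        except np.linalg.LinAlgError as exc:
            raise FitError(f"IRLS normal equations singular: {exc}") from exc
        beta = beta + delta
        if np.max(np.abs(delta)) < tol:
            converged = True
            break
    eta = X @ beta
    history.append(float(np.sum(y * eta - np.logaddexp(0.0, eta))))
    mu = expit(eta)
    w = np.clip(mu * (1.0 - mu), 1e-10, None)
    cov = np.linalg.inv(X.T @ (X * w[:, None]))
    bse = np.sqrt(np.diag(cov))
    separation = (not converged) or bool(np.any(bse > 100.0))
    return LogisticFit(params=beta, bse=bse, cov=cov, loglike_history=history,
                       converged=converged, n_iter=n_iter,
                       separation_flag=separation,
                       exog_names=exog_names or [f"x{i}" for i in range(p)])


def fit_adjusted_logistic(df: pd.DataFrame, index_name: str,
                          outcome_col: str = "muno",
                          covariates: list[str] | None = None,
                          cutpoints=None) -> pd.DataFrame:
    """Odds ratios (95% CI) of the outcome for quartiles 2-4 of one index
    versus its lowest quartile, adjusted for covariates.

    Returns one tidy row per upper quartile with columns
    ``index, quartile, or_, ci_low, ci_high, p_value, separation_flag``
    plus the cutpoints.  Covariates default to age, sex (male=1),
    education and smoking history.
    """
    covariates = DEFAULT_COVARIATES if covariates is None else covariates
    work = df.copy()
    if "sex_male" in covariates and "sex_male" not in work.columns:
        work["sex_male"] = (work["sex"] == "male").astype(int)
    binning = quartile_bin(work[index_name].to_numpy(), cutpoints=cutpoints,
                           index_name=index_name)
    dummies = np.column_stack([(binning.labels == q).astype(float)
                               for q in (2, 3, 4)])
    covs = work[covariates].to_numpy(dtype=float) if covariates else \
        np.empty((len(work), 0))
    X = np.column_stack([np.ones(len(work)), dummies, covs])
    names = ["const", "Q2", "Q3", "Q4"] + list(covariates)
    fit = fit_logistic_irls(X, work[outcome_col].to_numpy(dtype=float),
                            exog_names=names)
    ci = fit.conf_int()
    pvals = fit.pvalues()
    rows = []
    for i, q in enumerate((2, 3, 4), start=1):
        rows.append({
            "index": index_name, "quartile": q,
            "or_": float(np.exp(fit.params[i])),
            "ci_low": float(np.exp(ci[i, 0])),
            "ci_high": float(np.exp(ci[i, 1])),
            "p_value": float(pvals[i]),
            "separation_flag": fit.separation_flag,
            "cut_q25": binning.cutpoints[0],
            "cut_q50": binning.cutpoints[1],
            "cut_q75": binning.cutpoints[2],
        })
    return pd.DataFrame(rows)


def run_quartile_table(df: pd.DataFrame, index_names: list[str],
                       outcome_col: str = "muno",
                       covariates: list[str] | None = None) -> pd.DataFrame:
    """Quartile odds-ratio table across indices (one block of three rows
    per index; the lowest quartile is the implicit reference OR = 1)."""
    blocks = [fit_adjusted_logistic(df, name, outcome_col=outcome_col,
                                    covariates=covariates)
              for name in index_names]
    return pd.concat(blocks, ignore_index=True)
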