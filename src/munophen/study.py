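"""Top-level modelling surface: ``MunoStudy`` / ``MunoStudyResults``.

``MunoStudy`` wraps a patient cohort and, on ``fit()``, runs the full
analysis: eligibility screening, the seven adiposity indices, rule-based
phenotype classification, group descriptives, covariate-adjusted quartile
logistic regression, and sex-stratified ROC / Youden / DeLong comparison.
The returned ``MunoStudyResults`` carries the four analysis tables, the
ROC coordinates and a text ``summary()``.

Example
-------
>>> from munophen import GeneratorConfig, generate_cohort, MunoStudy
>>> cohort = generate_cohort(GeneratorConfig(n=2000, seed=1))
>>> res = MunoStudy(cohort).fit()
>>> print(res.summary())          # doctest: +SKIP
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import descriptives, quartlogit, roc
from .datamodel import CohortTable, ExclusionReport, apply_eligibility, read_cohort
from .indices import INDEX_NAMES, add_index_columns
from .phenotype import MUNO, add_phenotype_columns, phenotype_prevalence


class MunoStudy:
    """Discrimination study of adiposity indices for the MUNO phenotype.

    Parameters
    ----------
    cohort : CohortTable
        Raw patient cohort (eligibility is applied during ``fit``).
    indices : list of str, optional
        Index columns to analyse; defaults to all seven.
    delong_pairs : list of (str, str), optional
        Index pairs for the paired AUC comparisons; defaults to the nine
        overlapping-CI pairs of the study design.
    covariates : list of str, optional
        Adjustment covariates of the quartile logistic model (default:
        age, sex, education, smoking history).
    """

    def __init__(self, cohort: CohortTable,
                 indices: list[str] | None = None,
                 delong_pairs: list[tuple[str, str]] | None = None,
                 covariates: list[str] | None = None) -> None:
        self.cohort = cohort
        self.indices = list(indices) if indices is not None else list(INDEX_NAMES)
        self.delong_pairs = delong_pairs
        self.covariates = covariates

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, provenance: str = "dataframe",
                       **kwargs) -> "MunoStudy":
        return cls(CohortTable(df.copy(), provenance=provenance), **kwargs)

    @classmethod
    def from_csv(cls, path: str | Path, strict: bool = True, **kwargs) -> "MunoStudy":
        return cls(read_cohort(path, strict=strict), **kwargs)

    def fit(self) -> "MunoStudyResults":
        eligible, report = apply_eligibility(self.cohort)
        if len(eligible) == 0:
            raise ValueError("no eligible records to analyse")
        df = add_phenotype_columns(add_index_columns(eligible))
        df["muno"] = (df["phenotype"] == MUNO).astype(int)
        prevalence = phenotype_prevalence(df)

        table1 = descriptives.build_table1(df)
        table2 = quartlogit.run_quartile_table(
            df, self.indices, outcome_col="muno", covariates=self.covariates)
        table3, table4, curves = roc.run_roc_table(
            df, self.indices, outcome_col="muno", pairs=self.delong_pairs)
        return MunoStudyResults(
            model=self, data=df, exclusions=report, prevalence=prevalence,
            table1=table1, table2=table2, table3=table3, table4=table4,
            roc_curves=curves)


@dataclass
class MunoStudyResults:
    """Fitted study: analysis tables, prevalence and diagnostics."""

    model: MunoStudy
    data: pd.DataFrame
    exclusions: ExclusionReport
    prevalence: dict
    table1: pd.DataFrame
    table2: pd.DataFrame
    table3: pd.DataFrame
    table4: pd.DataFrame
    roc_curves: dict = field(default_factory=dict)

    def auc(self, index_name: str, stratum: str) -> float:
        t = self.table3
        row = t[(t["index_name"] == index_name) & (t["stratum"] == stratum)]
        if row.empty:
            raise KeyError(f"no ROC row for ({index_name}, {stratum})")
        return float(row["auc"].iloc[0])

    def summary(self) -> str:
        p = self.prevalence
        lines = [
            "MUNO discrimination study",
            "=" * 60,
            f"Cohort: {self.model.cohort.provenance}",
            f"Input records: {self.exclusions.n_input}   "
            f"analysed: {self.exclusions.n_retained}   "
            f"excluded: {self.exclusions.n_excluded} {self.exclusions.counts}",
            f"Phenotype: {p['n_muno']} MUNO / {p['n_total']} eligible "
            f"({p['pct_muno']}%)  [complete-case analysis]",
            "",
            "AUC by sex stratum (Youden-optimal cutoff):",
        ]
        for _, r in self.table3.iterrows():
            lines.append(
                f"  {r['stratum']:<7} {r['index_name']:<5} "
                f"AUC {r['auc']:.2f} ({r['ci_low']:.2f}-{r['ci_high']:.2f})  "
                f"cutoff {r['cutoff']:.2f}  sens {r['sensitivity']:.2f}  "
                f"spec {r['specificity']:.2f}  J {r['youden']:.2f}")
        lines.append("")
        lines.append("Adjusted OR (95% CI) per quartile vs Q1:")
        for name, block in self.table2.groupby("index", sort=False):
            cells = "  ".join(
                f"Q{int(r.quartile)} {r.or_:.2f} ({r.ci_low:.2f}-{r.ci_high:.2f})"
                for r in block.itertuples())
            flag = " [separation]" if bool(block["separation_flag"].any()) else ""
            lines.append(f"  {name:<5} {cells}{flag}")
        return "\n".join(lines)

    def plot_roc(self, stratum: str, ax=None):
        return roc.plot_roc_curves(self.roc_curves, ax=ax, stratum=stratum)
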