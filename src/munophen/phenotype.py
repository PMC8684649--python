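"""Rule-based metabolic-phenotype classification for nonobese subjects.

A nonobese subject (BMI < 25 kg/m²) is metabolically unhealthy (MUNO) when
at least two of four metabolic-syndrome components are present:

1. blood pressure: SBP ≥ 130 mmHg or DBP ≥ 85 mmHg, or antihypertensive use;
2. triglycerides: TG ≥ 1.7 mmol/L;
3. HDL-C: < 1.0 mmol/L in men, < 1.3 mmol/L in women, or lipid-lowering use;
4. fasting glucose: FPG ≥ 5.6 mmol/L, or antidiabetic treatment.

Medication use is sufficient for its component regardless of the measured
value.  Subjects with BMI ≥ 25 are outside the phenotype's domain
(``not_applicable``).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .datamodel import FEMALE, MALE, CohortTable, PatientRecord
from .indices import compute_bmi

MUNO = "MUNO"
MHNO = "MHNO"
NOT_APPLICABLE = "not_applicable"

SBP_CUT = 130.0
DBP_CUT = 85.0
TG_CUT = 1.7
HDL_CUT = {MALE: 1.0, FEMALE: 1.3}
FPG_CUT = 5.6
BMI_NONOBESE = 25.0


@dataclass
class PhenotypeResult:
    bp_component: bool
    tg_component: bool
    hdl_component: bool
    fpg_component: bool
    label: str | None = None

    @property
    def component_count(self) -> int:
        return int(self.bp_component) + int(self.tg_component) \
            + int(self.hdl_component) + int(self.fpg_component)


def mets_components(record: PatientRecord) -> PhenotypeResult:
    """Evaluate the four metabolic-syndrome component flags for one record.

    Thresholds are applied exactly as defined (≥ for SBP/DBP/TG/FPG,
    strict < for HDL).
    """
    for f in ("sbp", "dbp", "tg", "hdl", "fpg"):
        v = getattr(record, f)
        if v is None or np.isnan(v):
            raise ValueError(f"patient {record.id!r}: missing mandatory field {f}")
    if record.sex not in HDL_CUT:
        raise ValueError(f"patient {record.id!r}: unknown sex {record.sex!r}")
    return PhenotypeResult(
        bp_component=(record.sbp >= SBP_CUT) or (record.dbp >= DBP_CUT)
        or record.on_antihypertensive,
        tg_component=record.tg >= TG_CUT,
        hdl_component=(record.hdl < HDL_CUT[record.sex]) or record.on_lipid_lowering,
        fpg_component=(record.fpg >= FPG_CUT) or record.on_antidiabetic,
    )


def classify_phenotype(record: PatientRecord,
                       components: PhenotypeResult | None = None) -> str:
    """Label one record MUNO / MHNO / not_applicable.

    MUNO requires BMI < 25 and ≥ 2 components (the count-2 boundary is
    inclusive); MHNO is BMI < 25 with ≤ 1 component; BMI ≥ 25 is outside
    the nonobese domain.
    """
    if components is None:
        components = mets_components(record)
    bmi = compute_bmi(record.weight_kg, record.height_m)
    if bmi >= BMI_NONOBESE:
        return NOT_APPLICABLE
    return MUNO if components.component_count >= 2 else MHNO


def add_phenotype_columns(cohort: CohortTable | pd.DataFrame) -> pd.DataFrame:
    """Vectorised batch path: append component flags, count and label."""
    df = (cohort.data if isinstance(cohort, CohortTable) else cohort).copy()
    sex = df["sex"].to_numpy()
    sbp = df["sbp"].to_numpy(dtype=float)
    dbp = df["dbp"].to_numpy(dtype=float)
    tg = df["tg"].to_numpy(dtype=float)
    hdl = df["hdl"].to_numpy(dtype=float)
    fpg = df["fpg"].to_numpy(dtype=float)
    hdl_cut = np.where(sex == MALE, HDL_CUT[MALE], HDL_CUT[FEMALE])

    df["bp_component"] = (sbp >= SBP_CUT) | (dbp >= DBP_CUT) \
        | df["on_antihypertensive"].to_numpy(dtype=bool)
    df["tg_component"] = tg >= TG_CUT
    df["hdl_component"] = (hdl < hdl_cut) | df["on_lipid_lowering"].to_numpy(dtype=bool)
    df["fpg_component"] = (fpg >= FPG_CUT) | df["on_antidiabetic"].to_numpy(dtype=bool)
    df["component_count"] = (
        df[["bp_component", "tg_component", "hdl_component", "fpg_component"]]
        .to_numpy(dtype=int).sum(axis=1))

    if "bmi" in df.columns:
        bmi = df["bmi"].to_numpy(dtype=float)
    else:
        bmi = compute_bmi(df["weight_kg"].to_numpy(dtype=float),
                          df["height_m"].to_numpy(dtype=float))
    df["phenotype"] = np.where(
        bmi >= BMI_NONOBESE, NOT_APPLICABLE,
        np.where(df["component_count"].to_numpy() >= 2, MUNO, MHNO))
    return df


def phenotype_prevalence(classified: pd.DataFrame) -> dict:
    """Prevalence summary over an eligible (all BMI < 25) classified cohort.

    Returns ``{n_total, n_muno, n_mhno, pct_muno}`` with the percentage
    rounded to one decimal, as conventionally reported.
    """
    if len(classified) == 0:
        raise ValueError("phenotype_prevalence: empty cohort")
    labels = classified["phenotype"]
    if (labels == NOT_APPLICABLE).any():
        raise ValueError("phenotype_prevalence: cohort contains BMI >= 25 records; "
                         "apply eligibility screening first")
    n_muno = int((labels == MUNO).sum())
    n_mhno = int((labels == MHNO).sum())
    n_total = n_muno + n_mhno
    return {
        "n_total": n_total,
        "n_muno": n_muno,
        "n_mhno": n_mhno,
        "pct_muno": round(100.0 * n_muno / n_total, 1),
    }
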