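"""Patient data model, cohort CSV I/O, validation and eligibility screening.

A cohort is one row per hemodialysis patient with anthropometry (height,
weight, waist circumference), pre-dialysis blood pressure, fasting labs in
mmol/L, demographics, medication/lifestyle flags and dialysis vintage.
Canonical units are fixed once here: metres for height, centimetres for waist
circumference, mmol/L for every lab.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, fields as dc_fields
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

logger = logging.getLogger("munophen")

MALE = "male"
FEMALE = "female"

#: Mandatory numeric analysis fields: a record missing any of these cannot
#: enter the complete-case analysis.
MANDATORY_NUMERIC = [
    "age", "height_m", "weight_kg", "wc_cm", "sbp", "dbp",
    "fpg", "tg", "hdl", "vintage_months",
]
OPTIONAL_NUMERIC = ["ldl", "tc"]
FLAG_COLUMNS = [
    "on_antihypertensive", "on_antidiabetic", "on_lipid_lowering",
    "smoker_history", "education_ge_junior_high",
]
ALL_COLUMNS = ["id", "sex"] + MANDATORY_NUMERIC + OPTIONAL_NUMERIC + FLAG_COLUMNS

#: Case-insensitive header dictionary: accepted CSV header -> canonical column.
HEADER_ALIASES = {
    "id": "id", "patient_id": "id", "subject_id": "id",
    "sex": "sex", "gender": "sex",
    "age": "age", "age_years": "age",
    "height": "height_m", "height_m": "height_m",
    "weight": "weight_kg", "weight_kg": "weight_kg",
    "wc": "wc_cm", "wc_cm": "wc_cm", "waist": "wc_cm",
    "waist_circumference": "wc_cm",
    "sbp": "sbp", "systolic_bp": "sbp",
    "dbp": "dbp", "diastolic_bp": "dbp",
    "fpg": "fpg", "glucose": "fpg", "fasting_glucose": "fpg",
    "tg": "tg", "triglycerides": "tg",
    "hdl": "hdl", "hdl_c": "hdl",
    "ldl": "ldl", "ldl_c": "ldl",
    "tc": "tc", "total_cholesterol": "tc",
    "on_antihypertensive": "on_antihypertensive",
    "antihypertensive": "on_antihypertensive",
    "on_antidiabetic": "on_antidiabetic", "antidiabetic": "on_antidiabetic",
    "on_lipid_lowering": "on_lipid_lowering",
    "lipid_lowering": "on_lipid_lowering",
    "smoker_history": "smoker_history", "smoking": "smoker_history",
    "education_ge_junior_high": "education_ge_junior_high",
    "education": "education_ge_junior_high",
    "vintage_months": "vintage_months", "vintage": "vintage_months",
}

_TRUE = {"1", "1.0", "true", "yes", "y", "t"}
_FALSE = {"0", "0.0", "false", "no", "n", "f"}

#: Plausibility bounds for measured values; values outside violate record
#: invariants.  Labs must be strictly positive.
BOUNDS = {
    "age": (18.0, 120.0),
    "height_m": (0.5, 2.5),
    "wc_cm": (30.0, 200.0),
    "weight_kg": (20.0, 300.0),
    "sbp": (50.0, 300.0),
    "dbp": (20.0, 200.0),
    "vintage_months": (0.0, 600.0),
}
_POSITIVE = ["fpg", "tg", "hdl", "ldl", "tc"]


class CohortError(ValueError):
    """Malformed cohort file or record."""


@dataclass
class PatientRecord:
    """One subject's raw measurements in canonical units."""

    id: str
    sex: str
    age: float
    height_m: float
    weight_kg: float
    wc_cm: float
    sbp: float
    dbp: float
    fpg: float
    tg: float
    hdl: float
    vintage_months: float
    on_antihypertensive: bool
    on_antidiabetic: bool
    on_lipid_lowering: bool
    smoker_history: bool
    education_ge_junior_high: bool
    ldl: float | None = None
    tc: float | None = None

    def violations(self) -> list[str]:
        """Return invariant violations (empty list when the record is valid).

        Missing mandatory numerics are not violations here -- they make the
        record ineligible at the eligibility stage (complete-case analysis).
        """
        problems = []
        if self.sex not in (MALE, FEMALE):
            problems.append(f"sex must be '{MALE}' or '{FEMALE}', got {self.sex!r}")
        for name, (lo, hi) in BOUNDS.items():
            v = getattr(self, name)
            if v is not None and not np.isnan(v) and not (lo <= v <= hi):
                problems.append(f"{name}={v} outside [{lo}, {hi}]")
        for name in _POSITIVE:
            v = getattr(self, name)
            if v is not None and not np.isnan(v) and v <= 0:
                problems.append(f"{name}={v} must be > 0")
        return problems


@dataclass
class CohortTable:
    """Ordered cohort of patient records backed by a DataFrame.

    ``data`` always carries the canonical columns of :data:`ALL_COLUMNS`;
    ``provenance`` records where the rows came from (file path or generator
    seed string).
    """

    data: pd.DataFrame
    provenance: str = "unspecified"

    def __post_init__(self) -> None:
        if self.data["id"].duplicated().any():
            dups = self.data.loc[self.data["id"].duplicated(), "id"].tolist()
            raise CohortError(f"duplicate patient ids: {dups[:5]}")

    def __len__(self) -> int:
        return len(self.data)

    def records(self) -> Iterable[PatientRecord]:
        for row in self.data.itertuples(index=False):
            yield PatientRecord(**{f.name: getattr(row, f.name)
                                   for f in dc_fields(PatientRecord)})


@dataclass
class ExclusionReport:
    """Telescoping account of eligibility screening.

    Each excluded record is counted once, under the first matching rule in
    the fixed priority order ``vintage_le_3 -> bmi_ge_25 -> missing_mandatory``.
    """

    n_input: int
    n_retained: int
    counts: dict[str, int] = field(default_factory=dict)

    @property
    def n_excluded(self) -> int:
        return sum(self.counts.values())


def _parse_flag(value, column: str, row_id: str):
    if isinstance(value, (bool, np.bool_)):
        return bool(value)
    s = str(value).strip().lower()
    if s in _TRUE:
        return True
    if s in _FALSE:
        return False
    raise CohortError(f"row {row_id!r}: cannot parse {column}={value!r} as boolean")


def _normalise_headers(df: pd.DataFrame) -> pd.DataFrame:
    mapping = {}
    for col in df.columns:
        key = col.strip().lower()
        if key in HEADER_ALIASES:
            mapping[col] = HEADER_ALIASES[key]
    return df.rename(columns=mapping)


def read_cohort(path: str | Path, strict: bool = True) -> CohortTable:
    """Read a cohort CSV into a validated :class:`CohortTable`.

    Parameters
    ----------
    path : str or Path
        CSV file with headers from the documented dictionary
        (:data:`HEADER_ALIASES`, case-insensitive).
    strict : bool
        If True, any row with an unparseable value or an invariant violation
        raises :class:`CohortError` naming the row id; if False, such rows
        are dropped and the exclusion count is logged.
    """
    path = Path(path)
    if not path.exists():
        raise CohortError(f"cohort file not found: {path}")
    raw = pd.read_csv(path, dtype=str).pipe(_normalise_headers)

    mandatory_cols = ["id", "sex"] + MANDATORY_NUMERIC + FLAG_COLUMNS
    missing = [c for c in mandatory_cols if c not in raw.columns]
    if missing:
        raise CohortError(f"missing mandatory column(s): {', '.join(missing)}")
    for col in OPTIONAL_NUMERIC:
        if col not in raw.columns:
            raw[col] = np.nan

    rows, dropped = [], 0
    for _, r in raw.iterrows():
        rid = str(r["id"])
        try:
            rec: dict = {"id": rid, "sex": str(r["sex"]).strip().lower()}
            for col in MANDATORY_NUMERIC + OPTIONAL_NUMERIC:
                v = r[col]
                if v is None or (isinstance(v, float) and np.isnan(v)) or str(v).strip() == "":
                    rec[col] = np.nan
                    continue
                try:
                    rec[col] = float(v)
                except ValueError:
                    raise CohortError(
                        f"row {rid!r}: cannot parse {col}={v!r} as a number"
                    ) from None
            for col in FLAG_COLUMNS:
                v = r[col]
                if v is None or (isinstance(v, float) and np.isnan(v)) or str(v).strip() == "":
                    raise CohortError(f"row {rid!r}: flag {col} is missing")
                rec[col] = _parse_flag(v, col, rid)
            problems = PatientRecord(**rec).violations()
            if problems:
                raise CohortError(f"row {rid!r}: " + "; ".join(problems))
            rows.append(rec)
        except CohortError:
            if strict:
                raise
            dropped += 1
    if dropped:
        logger.info("read_cohort: dropped %d invalid row(s) from %s", dropped, path)
    df = pd.DataFrame(rows, columns=ALL_COLUMNS)
    return CohortTable(df, provenance=str(path))


def write_cohort(cohort: CohortTable, path: str | Path) -> Path:
    """Write a cohort to CSV with canonical headers (round-trips with
    :func:`read_cohort`)."""
    path = Path(path)
    out = cohort.data.copy()
    for col in FLAG_COLUMNS:
        out[col] = out[col].astype(int)
    out.to_csv(path, index=False)
    return path


def apply_eligibility(cohort: CohortTable) -> tuple[CohortTable, ExclusionReport]:
    """Screen a cohort for the analysis population.

    Retains subjects on dialysis for more than 3 months with BMI < 25 kg/m²
    and complete mandatory analysis fields.  A record failing several rules
    is counted once, under the first matching rule in the order
    ``vintage_le_3``, ``bmi_ge_25``, ``missing_mandatory``.  Idempotent.
    """
    if len(cohort) == 0:
        raise CohortError("apply_eligibility: empty cohort")
    df = cohort.data
    counts = {"vintage_le_3": 0, "bmi_ge_25": 0, "missing_mandatory": 0}
    keep = np.ones(len(df), dtype=bool)

    missing_any = df[MANDATORY_NUMERIC].isna().any(axis=1).to_numpy()
    vintage = df["vintage_months"].to_numpy(dtype=float)
    with np.errstate(invalid="ignore", divide="ignore"):
        bmi = df["weight_kg"].to_numpy(dtype=float) / df["height_m"].to_numpy(dtype=float) ** 2

    for i in range(len(df)):
        if not np.isnan(vintage[i]) and vintage[i] <= 3:
            counts["vintage_le_3"] += 1
            keep[i] = False
        elif not np.isnan(bmi[i]) and bmi[i] >= 25:
            counts["bmi_ge_25"] += 1
            keep[i] = False
        elif missing_any[i]:
            counts["missing_mandatory"] += 1
            keep[i] = False

    retained = df.loc[keep].reset_index(drop=True)
    report = ExclusionReport(n_input=len(df), n_retained=len(retained), counts=counts)
    if len(retained) == 0:
        logger.warning("apply_eligibility: no records remain after screening")
    for reason, n in counts.items():
        if n:
            logger.info("apply_eligibility: excluded %d record(s): %s", n, reason)
    return CohortTable(retained, provenance=cohort.provenance), report
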