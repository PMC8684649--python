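"""Seven adiposity indices: BMI, WC, WHtR, VAI, LAP, CVAI, ABSI.

All functions accept scalars or numpy arrays and use the sex-specific
formulas as published:

* LAP (lipid accumulation product): ``(WC − anchor) × TG`` with anchor
  65 cm for men and 58 cm for women.  Values at or below the anchor are
  retained as ≤ 0 (rank-based downstream analyses are unaffected).
* VAI (visceral adiposity index): sex-specific product of a WC/BMI ratio,
  a TG ratio and an HDL ratio.
* CVAI (Chinese visceral adiposity index): sex-specific linear score in
  age, BMI, WC, log10(TG) and HDL-C.  The male BMI coefficient (0.03) is
  transcribed literally from the source formula; see the methods note.
* ABSI (a body shape index): ``WC(m) / (BMI^(2/3) · height^(1/2))``; WC is
  stored in centimetres everywhere and converted to metres only here.

Inputs: WC in cm, height in m, weight in kg, TG/HDL in mmol/L, age in years.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .datamodel import FEMALE, MALE, CohortTable, PatientRecord

INDEX_NAMES = ["bmi", "wc", "whtr", "vai", "lap", "cvai", "absi"]

_LAP_ANCHOR = {MALE: 65.0, FEMALE: 58.0}
_VAI = {MALE: (39.68, 1.88, 1.03, 1.31), FEMALE: (36.58, 1.89, 0.81, 1.52)}
_CVAI = {
    # intercept, age, bmi, wc, log10(tg), hdl
    MALE: (-267.93, 0.68, 0.03, 4.00, 22.00, -16.32),
    FEMALE: (-187.32, 1.71, 4.23, 1.12, 39.76, -11.66),
}


class IndexDomainError(ValueError):
    """Input outside the index formula's domain."""


def _require_positive(**values) -> None:
    for name, v in values.items():
        if np.any(np.asarray(v) <= 0) or np.any(np.isnan(np.asarray(v, dtype=float))):
            raise IndexDomainError(f"{name} must be > 0, got {v!r}")


def _sex_constants(sex, table):
    sex_arr = np.asarray(sex)
    known = np.isin(sex_arr, [MALE, FEMALE])
    if not np.all(known):
        bad = np.unique(sex_arr[~known]) if sex_arr.ndim else sex_arr
        raise IndexDomainError(f"unknown sex level(s): {bad!r}")
    male = np.asarray(table[MALE], dtype=float)
    female = np.asarray(table[FEMALE], dtype=float)
    if sex_arr.ndim == 0:
        return table[str(sex_arr)]
    return tuple(np.where(sex_arr == MALE, m, f) for m, f in zip(male, female)) \
        if male.ndim else np.where(sex_arr == MALE, male, female)


def compute_bmi(weight_kg, height_m):
    """Body mass index, weight (kg) divided by squared height (m)."""
    _require_positive(weight_kg=weight_kg, height_m=height_m)
    return weight_kg / np.asarray(height_m) ** 2 if np.ndim(weight_kg) else weight_kg / height_m**2


def compute_whtr(wc_cm, height_m):
    """Waist-to-height ratio with both lengths in the same unit."""
    _require_positive(wc_cm=wc_cm, height_m=height_m)
    return wc_cm / (np.asarray(height_m) * 100.0) if np.ndim(wc_cm) else wc_cm / (height_m * 100.0)


def compute_lap(sex, wc_cm, tg):
    """Lipid accumulation product, (WC − sex anchor) × TG."""
    _require_positive(wc_cm=wc_cm, tg=tg)
    anchor = _sex_constants(sex, _LAP_ANCHOR)
    return (wc_cm - anchor) * tg


def compute_vai(sex, wc_cm, bmi, tg, hdl):
    """Visceral adiposity index (sex-specific product of three ratios)."""
    _require_positive(wc_cm=wc_cm, bmi=bmi, tg=tg, hdl=hdl)
    a, b, tg0, hdl0 = _sex_constants(sex, _VAI)
    return wc_cm / (a + b * bmi) * (tg / tg0) * (hdl0 / hdl)


def compute_cvai(sex, age, bmi, wc_cm, tg, hdl):
    """Chinese visceral adiposity index (sex-specific linear score)."""
    _require_positive(age=age, bmi=bmi, wc_cm=wc_cm, tg=tg, hdl=hdl)
    c0, c_age, c_bmi, c_wc, c_logtg, c_hdl = _sex_constants(sex, _CVAI)
    return c0 + c_age * age + c_bmi * bmi + c_wc * wc_cm \
        + c_logtg * np.log10(tg) + c_hdl * hdl


def compute_absi(wc_cm, bmi, height_m):
    """A body shape index, WC(m) / (BMI^(2/3) · height^(1/2))."""
    _require_positive(wc_cm=wc_cm, bmi=bmi, height_m=height_m)
    return (wc_cm / 100.0) / (bmi ** (2.0 / 3.0) * height_m**0.5)


@dataclass
class IndexPanel:
    """The seven computed adiposity indices for one subject."""

    bmi: float
    wc: float
    whtr: float
    vai: float
    lap: float
    cvai: float
    absi: float


def compute_panel(record: PatientRecord) -> IndexPanel:
    """Compute all seven indices for one record (BMI computed once and
    reused by VAI/CVAI/ABSI).  Domain errors are re-raised with the
    patient id attached."""
    try:
        bmi = compute_bmi(record.weight_kg, record.height_m)
        return IndexPanel(
            bmi=bmi,
            wc=record.wc_cm,
            whtr=compute_whtr(record.wc_cm, record.height_m),
            vai=compute_vai(record.sex, record.wc_cm, bmi, record.tg, record.hdl),
            lap=compute_lap(record.sex, record.wc_cm, record.tg),
            cvai=compute_cvai(record.sex, record.age, bmi, record.wc_cm,
                              record.tg, record.hdl),
            absi=compute_absi(record.wc_cm, bmi, record.height_m),
        )
    except IndexDomainError as exc:
        raise IndexDomainError(f"patient {record.id!r}: {exc}") from exc


def add_index_columns(cohort: CohortTable | pd.DataFrame) -> pd.DataFrame:
    """Vectorised batch path: return a copy of the cohort frame with the
    seven index columns appended (names fixed as :data:`INDEX_NAMES`)."""
    df = (cohort.data if isinstance(cohort, CohortTable) else cohort).copy()
    sex = df["sex"].to_numpy()
    h = df["height_m"].to_numpy(dtype=float)
    wc = df["wc_cm"].to_numpy(dtype=float)
    tg = df["tg"].to_numpy(dtype=float)
    hdl = df["hdl"].to_numpy(dtype=float)
    bmi = compute_bmi(df["weight_kg"].to_numpy(dtype=float), h)
    df["bmi"] = bmi
    df["wc"] = wc
    df["whtr"] = compute_whtr(wc, h)
    df["vai"] = compute_vai(sex, wc, bmi, tg, hdl)
    df["lap"] = compute_lap(sex, wc, tg)
    df["cvai"] = compute_cvai(sex, df["age"].to_numpy(dtype=float), bmi, wc, tg, hdl)
    df["absi"] = compute_absi(wc, bmi, h)
    n_nonpos_lap = int((df["lap"] <= 0).sum())
    if n_nonpos_lap:
        import logging
        logging.getLogger("munophen").info(
            "add_index_columns: %d record(s) with LAP <= 0 (WC at/below sex anchor)",
            n_nonpos_lap)
    return df
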