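"""Adiposity index formulas: frozen hand-substituted values, unit cases,
monotonicity and batch/scalar agreement."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from munophen.datamodel import PatientRecord
from munophen.indices import (IndexDomainError, add_index_columns, compute_absi,
                              compute_bmi, compute_cvai, compute_lap,
                              compute_panel, compute_vai, compute_whtr)

from conftest import RECORD_DEFAULTS, make_cohort_df


# -- scalar formula cases (expected values by independent hand substitution)

@pytest.mark.parametrize("weight, height, expected", [
    (1.0, 1.0, 1.0),
    (70.0, 1.75, 70.0 / 1.75**2),
    (80.0, 2.0, 20.0),
])
def test_bmi(weight, height, expected):
    assert compute_bmi(weight, height) == pytest.approx(expected, rel=1e-12)


@pytest.mark.parametrize("wc, height, expected", [
    (100.0, 2.0, 0.5),
    (81.5, 1.70, 81.5 / 170.0),
    (48.0, 1.0, 0.48),
])
def test_whtr(wc, height, expected):
    assert compute_whtr(wc, height) == pytest.approx(expected, rel=1e-12)


@pytest.mark.parametrize("sex, wc, tg, expected", [
    ("male", 65.0, 1.9, 0.0),      # male anchor
    ("female", 58.0, 0.7, 0.0),    # female anchor
    ("male", 90.0, 2.0, 50.0),     # (90-65)*2
    ("female", 50.0, 2.0, -16.0),  # below anchor retained, not truncated
])
def test_lap(sex, wc, tg, expected):
    assert compute_lap(sex, wc, tg) == pytest.approx(expected, abs=1e-12)


def test_vai_unity_configurations():
    bmi = 22.0
    assert compute_vai("male", 39.68 + 1.88 * bmi, bmi, 1.03, 1.31) == \
        pytest.approx(1.0, rel=1e-12)
    assert compute_vai("female", 36.58 + 1.89 * bmi, bmi, 0.81, 1.52) == \
        pytest.approx(1.0, rel=1e-12)


def test_vai_male_hand_value():
    # 85/(39.68+1.88*22) * 2.0/1.03 * 1.31/1.0 computed independently
    assert compute_vai("male", 85.0, 22.0, 2.0, 1.0) == \
        pytest.approx(2.6679860838229, rel=1e-10)


def test_cvai_log_term_vanishes_at_tg_one():
    got = compute_cvai("male", 50.0, 21.0, 80.0, 1.0, 1.2)
    expected = -267.93 + 0.68 * 50 + 0.03 * 21 + 4.00 * 80 - 16.32 * 1.2
    assert got == pytest.approx(expected, rel=1e-12)


@pytest.mark.parametrize("sex, expected", [
    ("male", 73.7100076992250),     # hand substitution, male coefficients
    ("female", 76.4593884600539),   # female coefficients differ
])
def test_cvai_hand_values(sex, expected):
    assert compute_cvai(sex, 54.0, 21.0, 80.0, 1.5, 1.2) == \
        pytest.approx(expected, rel=1e-10)


@pytest.mark.parametrize("wc, bmi, height, expected", [
    (100.0, 1.0, 1.0, 1.0),
    (80.0, 8.0, 1.0, 0.8 / 4.0),                # 8^(2/3) = 4 exactly
    (81.5, 22.0, 1.70, 0.0796131291885724),     # hand substitution
])
def test_absi(wc, bmi, height, expected):
    assert compute_absi(wc, bmi, height) == pytest.approx(expected, rel=1e-10)


@pytest.mark.parametrize("fn, args", [
    (compute_bmi, (0.0, 1.7)),
    (compute_whtr, (-1.0, 1.7)),
    (compute_vai, ("male", 80.0, 22.0, 1.2, 0.0)),
    (compute_cvai, ("female", 50.0, 21.0, 80.0, 0.0, 1.2)),
    (compute_absi, (80.0, -3.0, 1.7)),
])
def test_domain_errors(fn, args):
    with pytest.raises(IndexDomainError):
        fn(*args)


def test_unknown_sex_rejected():
    with pytest.raises(IndexDomainError, match="sex"):
        compute_lap("other", 80.0, 1.2)


def test_lap_below_anchor_decreases_in_tg():
    # below the sex anchor LAP is negative and TG scales it downward
    assert compute_lap("male", 60.0, 2.0) < compute_lap("male", 60.0, 1.0) < 0


# -- properties

@settings(max_examples=60, derandomize=True)
@given(wc=st.floats(66, 120), bmi=st.floats(16, 30), tg=st.floats(0.3, 5),
       hdl=st.floats(0.5, 3), age=st.floats(18, 90),
       dtg=st.floats(0.01, 2), dhdl=st.floats(0.01, 1), dwc=st.floats(0.1, 20))
def test_monotonicity(wc, bmi, tg, hdl, age, dtg, dhdl, dwc):
    """VAI/LAP/CVAI increase in TG; VAI/CVAI decrease in HDL; LAP/CVAI/ABSI/
    WHtR increase in WC (WC above the sex anchors, where LAP is positive)."""
    for sex in ("male", "female"):
        assert compute_vai(sex, wc, bmi, tg + dtg, hdl) > compute_vai(sex, wc, bmi, tg, hdl)
        assert compute_lap(sex, wc, tg + dtg) > compute_lap(sex, wc, tg)
        assert compute_cvai(sex, age, bmi, wc, tg + dtg, hdl) > \
            compute_cvai(sex, age, bmi, wc, tg, hdl)
        assert compute_vai(sex, wc, bmi, tg, hdl + dhdl) < compute_vai(sex, wc, bmi, tg, hdl)
        assert compute_cvai(sex, age, bmi, wc, tg, hdl + dhdl) < \
            compute_cvai(sex, age, bmi, wc, tg, hdl)
        assert compute_lap(sex, wc + dwc, tg) > compute_lap(sex, wc, tg)
        assert compute_cvai(sex, age, bmi, wc + dwc, tg, hdl) > \
            compute_cvai(sex, age, bmi, wc, tg, hdl)
    assert compute_absi(wc + dwc, bmi, 1.7) > compute_absi(wc, bmi, 1.7)
    assert compute_whtr(wc + dwc, 1.7) > compute_whtr(wc, 1.7)


@settings(max_examples=40, derandomize=True)
@given(wc=st.floats(60, 120), bmi=st.floats(16, 30), tg=st.floats(0.3, 5),
       hdl=st.floats(0.5, 3), age=st.floats(18, 90))
def test_sex_specific_formulas_differ(wc, bmi, tg, hdl, age):
    assert compute_vai("male", wc, bmi, tg, hdl) != \
        compute_vai("female", wc, bmi, tg, hdl)
    assert compute_cvai("male", age, bmi, wc, tg, hdl) != \
        compute_cvai("female", age, bmi, wc, tg, hdl)
    assert compute_lap("male", wc, tg) != compute_lap("female", wc, tg)


def test_panel_matches_scalar_composition():
    record = PatientRecord(id="X", **RECORD_DEFAULTS)
    panel = compute_panel(record)
    bmi = compute_bmi(record.weight_kg, record.height_m)
    assert panel.bmi == bmi
    assert panel.wc == record.wc_cm
    assert panel.whtr == compute_whtr(record.wc_cm, record.height_m)
    assert panel.vai == compute_vai(record.sex, record.wc_cm, bmi, record.tg, record.hdl)
    assert panel.lap == compute_lap(record.sex, record.wc_cm, record.tg)
    assert panel.cvai == compute_cvai(record.sex, record.age, bmi, record.wc_cm,
                                      record.tg, record.hdl)
    assert panel.absi == compute_absi(record.wc_cm, bmi, record.height_m)


def test_panel_error_carries_patient_id():
    record = PatientRecord(id="BADTG", **{**RECORD_DEFAULTS, "tg": -1.0})
    with pytest.raises(IndexDomainError, match="BADTG"):
        compute_panel(record)


def test_batch_equals_scalar_path():
    df = make_cohort_df([{}, {"sex": "female", "wc_cm": 95.0, "tg": 2.2},
                         {"hdl": 0.8, "weight_kg": 70.0}])
    out = add_index_columns(df)
    for i, rec_row in df.iterrows():
        record = PatientRecord(**rec_row.to_dict())
        panel = compute_panel(record)
        for name in ("bmi", "whtr", "vai", "lap", "cvai", "absi"):
            assert out.loc[i, name] == pytest.approx(getattr(panel, name), rel=1e-14)
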