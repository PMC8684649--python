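import numpy as np
import pandas as pd
import pytest

from munophen.datamodel import ALL_COLUMNS

#: Defaults for a valid male record; tests override individual fields.
RECORD_DEFAULTS = dict(
    sex="male", age=54.0, height_m=1.66, weight_kg=60.0, wc_cm=80.0,
    sbp=140.0, dbp=78.0, fpg=5.0, tg=1.2, hdl=1.2, ldl=2.2, tc=3.9,
    vintage_months=48.0, on_antihypertensive=False, on_antidiabetic=False,
    on_lipid_lowering=False, smoker_history=False,
    education_ge_junior_high=True,
)


def make_cohort_df(overrides: list[dict]) -> pd.DataFrame:
    """Build a cohort frame from per-row override dicts."""
    rows = []
    for i, ov in enumerate(overrides):
        row = {"id": f"P{i + 1:03d}", **RECORD_DEFAULTS, **ov}
        rows.append(row)
    return pd.DataFrame(rows, columns=ALL_COLUMNS)


@pytest.fixture
def cohort_df_factory():
    return make_cohort_df


@pytest.fixture
def rng():
    return np.random.default_rng(20210907)
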