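"""Seeded synthetic hemodialysis cohorts with realistic metabolic structure.

The generator emulates a nonobese maintenance-hemodialysis population as a
two-component mixture: each subject is first destined to the metabolically
healthy (MHNO) or unhealthy (MUNO) stratum, then laboratory, blood-pressure
and anthropometric values are drawn from group-specific skewed marginals
(lognormal, shifted lognormal for blood pressure) coupled through a
Gaussian copula so that ranks correlate plausibly (WC with BMI, TG against
HDL, ...).  Medication flags follow logistic links to the latent values so
that, e.g., high-glucose subjects are likelier to be on antidiabetic
treatment.

The realized phenotype of a subject is whatever the classification rule
says about its drawn values, so destined and realized labels disagree for
borderline subjects.  The prevalence knob is honoured by an internal pilot
calibration: the generator estimates the realization rates of both destined
groups on a seeded pilot draw and solves the destined-group mixing fraction
so the realized MUNO prevalence matches the target in expectation.

Default marginal targets (median, Q1, Q3) are per-group values of the kind
observed in nonobese dialysis cohorts; the latent correlations and
medication-flag links are stated modelling assumptions, not estimates.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .datamodel import FEMALE, MALE, ALL_COLUMNS, CohortTable

_Z75 = 0.6744897501960817  # standard normal 75th percentile


@dataclass(frozen=True)
class MarginalSpec:
    """(Shifted) lognormal marginal parameterised by target quantiles.

    ``median``, ``q1``, ``q3`` are on the data scale; ``shift`` is the
    lower bound of the support (0 for labs, >0 for blood pressure so the
    skew stays mild).  The log-scale sigma is the average implied by the
    two quartiles.
    """

    median: float
    q1: float
    q3: float
    shift: float = 0.0

    def __post_init__(self):
        if not (self.shift < self.q1 < self.median < self.q3):
            raise ValueError(f"need shift < q1 < median < q3, got {self}")

    def from_z(self, z: np.ndarray) -> np.ndarray:
        mu = np.log(self.median - self.shift)
        sigma = (np.log(self.q3 - self.shift) - np.log(self.q1 - self.shift)) / (2 * _Z75)
        return self.shift + np.exp(mu + sigma * np.asarray(z, dtype=float))


#: Copula variable order (height is drawn separately, conditional on sex).
COPULA_VARS = ["age", "sbp", "dbp", "wc", "bmi", "fpg", "tg", "hdl",
               "ldl", "tc", "vintage"]

_MHNO_MARGINALS = {
    "age": MarginalSpec(59, 47, 70),
    "sbp": MarginalSpec(140, 125, 154, shift=60),
    "dbp": MarginalSpec(80, 70, 89.5, shift=30),
    "wc": MarginalSpec(77.5, 72, 84.2),
    "bmi": MarginalSpec(20.35, 18.91, 22.20),
    "fpg": MarginalSpec(4.73, 4.35, 5.17),
    "tg": MarginalSpec(1.05, 0.81, 1.33),
    "hdl": MarginalSpec(1.31, 1.12, 1.55),
    "ldl": MarginalSpec(2.10, 1.64, 2.75),
    "tc": MarginalSpec(3.87, 3.24, 4.42),
    "vintage": MarginalSpec(48, 24, 84),
}
_MUNO_MARGINALS = {
    "age": MarginalSpec(52, 39, 65),
    "sbp": MarginalSpec(140, 127, 154, shift=60),
    "dbp": MarginalSpec(77, 68, 88, shift=30),
    "wc": MarginalSpec(82, 75.5, 87),
    "bmi": MarginalSpec(21.46, 19.63, 23.06),
    "fpg": MarginalSpec(6.22, 4.99, 8.10),
    "tg": MarginalSpec(1.62, 1.10, 2.31),
    "hdl": MarginalSpec(1.02, 0.84, 1.26),
    "ldl": MarginalSpec(2.20, 1.70, 2.78),
    "tc": MarginalSpec(3.89, 3.31, 4.60),
    "vintage": MarginalSpec(48, 24, 84),
}

#: Latent-scale correlations (pairs not listed are 0).
DEFAULT_CORRELATIONS = {
    ("wc", "bmi"): 0.80,
    ("sbp", "dbp"): 0.60,
    ("tg", "hdl"): -0.40,
    ("wc", "tg"): 0.30,
    ("bmi", "tg"): 0.25,
    ("fpg", "tg"): 0.20,
    ("wc", "fpg"): 0.20,
    ("bmi", "fpg"): 0.15,
    ("ldl", "tc"): 0.70,
    ("tc", "tg"): 0.25,
    ("tc", "hdl"): 0.15,
    ("fpg", "hdl"): -0.20,
    ("wc", "hdl"): -0.20,
}

#: Medication / lifestyle flag model: (MHNO base rate, MUNO base rate,
#: linked copula variable or None, logistic slope on the latent z).
DEFAULT_FLAGS = {
    "on_antihypertensive": (0.45, 0.80, "sbp", 1.0),
    "on_antidiabetic": (0.10, 0.33, "fpg", 1.5),
    "on_lipid_lowering": (0.05, 0.12, "tg", 0.5),
    "smoker_history": (0.415, 0.356, None, 0.0),
    "education_ge_junior_high": (0.348, 0.363, None, 0.0),
}

#: Multiplicative sex adjustment of the HDL marginal (women run higher);
#: chosen to preserve the pooled median at the default sex mix.
HDL_SEX_FACTOR = {MALE: 0.94, FEMALE: 1.10}

#: Height (m): mean and SD by sex, truncated to plausible adult range.
HEIGHT_BY_SEX = {MALE: (1.66, 0.06), FEMALE: (1.55, 0.06)}


@dataclass
class GeneratorConfig:
    """Configuration of the synthetic-cohort generator."""

    n: int = 1302
    seed: int = 0
    male_fraction: float = 0.603
    muno_target: float = 0.656
    marginals_mhno: dict = field(default_factory=lambda: dict(_MHNO_MARGINALS))
    marginals_muno: dict = field(default_factory=lambda: dict(_MUNO_MARGINALS))
    correlations: dict = field(default_factory=lambda: dict(DEFAULT_CORRELATIONS))
    flags: dict = field(default_factory=lambda: dict(DEFAULT_FLAGS))
    pilot_n: int = 4000

    def correlation_matrix(self) -> np.ndarray:
        k = len(COPULA_VARS)
        idx = {v: i for i, v in enumerate(COPULA_VARS)}
        r = np.eye(k)
        for (a, b), rho in self.correlations.items():
            r[idx[a], idx[b]] = r[idx[b], idx[a]] = rho
        eigmin = float(np.linalg.eigvalsh(r).min())
        if eigmin <= 1e-10:
            raise ValueError(
                f"latent correlation matrix is not positive definite "
                f"(min eigenvalue {eigmin:.3g}); shrink the off-diagonals "
                f"toward zero or project to the nearest PD matrix")
        return r


def _logit(p: float) -> float:
    return float(np.log(p / (1.0 - p)))


def _expit(x):
    return 1.0 / (1.0 + np.exp(-np.asarray(x, dtype=float)))


def _draw_block(rng: np.random.Generator, config: GeneratorConfig,
                destined_muno: np.ndarray, sex: np.ndarray,
                latent_shift: dict | None = None,
                pooled_marginals: dict | None = None,
                pooled_flags: bool = False,
                start_id: int = 1) -> pd.DataFrame:
    """Draw one block of subjects given destined labels and sexes."""
    n = destined_muno.size
    chol = np.linalg.cholesky(config.correlation_matrix())
    z = rng.standard_normal((n, len(COPULA_VARS))) @ chol.T

    if latent_shift:
        sign = np.where(destined_muno, 0.5, -0.5)
        for var, delta in latent_shift.items():
            if var == "height":
                continue
            z[:, COPULA_VARS.index(var)] += sign * delta

    values = {}
    for j, var in enumerate(COPULA_VARS):
        if pooled_marginals is not None:
            values[var] = pooled_marginals[var].from_z(z[:, j])
        else:
            v = np.empty(n)
            muno_mask = destined_muno
            v[muno_mask] = config.marginals_muno[var].from_z(z[muno_mask, j])
            v[~muno_mask] = config.marginals_mhno[var].from_z(z[~muno_mask, j])
            values[var] = v
    hdl_factor = np.where(sex == MALE, HDL_SEX_FACTOR[MALE], HDL_SEX_FACTOR[FEMALE])
    values["hdl"] = values["hdl"] * hdl_factor

    age = np.clip(np.rint(values["age"]), 18, 90).astype(float)
    h_mu = np.where(sex == MALE, HEIGHT_BY_SEX[MALE][0], HEIGHT_BY_SEX[FEMALE][0])
    h_sd = np.where(sex == MALE, HEIGHT_BY_SEX[MALE][1], HEIGHT_BY_SEX[FEMALE][1])
    z_height = rng.standard_normal(n)
    if latent_shift and "height" in latent_shift:
        z_height = z_height + np.where(destined_muno, 0.5, -0.5) * latent_shift["height"]
    height = np.clip(h_mu + h_sd * z_height, 1.40, 1.95)
    weight = values["bmi"] * height**2

    flags = {}
    for name, (base_mhno, base_muno, link_var, slope) in config.flags.items():
        if pooled_flags:
            base = np.full(n, 0.5 * (base_mhno + base_muno))
        else:
            base = np.where(destined_muno, base_muno, base_mhno)
        logits = np.log(base / (1.0 - base))
        if link_var is not None:
            logits = logits + slope * z[:, COPULA_VARS.index(link_var)]
        flags[name] = rng.random(n) < _expit(logits)

    df = pd.DataFrame({
        "id": [f"S{start_id + i:05d}" for i in range(n)],
        "sex": sex,
        "age": age,
        "height_m": np.round(height, 3),
        "weight_kg": np.round(weight, 2),
        "wc_cm": np.round(values["wc"], 1),
        "sbp": np.round(values["sbp"], 1),
        "dbp": np.round(values["dbp"], 1),
        "fpg": np.round(values["fpg"], 2),
        "tg": np.round(values["tg"], 2),
        "hdl": np.round(values["hdl"], 2),
        "ldl": np.round(values["ldl"], 2),
        "tc": np.round(values["tc"], 2),
        "vintage_months": np.round(np.clip(values["vintage"], 0.1, 600.0), 1),
        "on_antihypertensive": flags["on_antihypertensive"],
        "on_antidiabetic": flags["on_antidiabetic"],
        "on_lipid_lowering": flags["on_lipid_lowering"],
        "smoker_history": flags["smoker_history"],
        "education_ge_junior_high": flags["education_ge_junior_high"],
    })
    df["destined_muno"] = destined_muno.astype(int)
    return df[ALL_COLUMNS + ["destined_muno"]]


def _realized_muno_rate(block: pd.DataFrame) -> tuple[float, float]:
    """(eligible fraction, MUNO rate among eligible) of a block, where
    eligible means BMI < 25."""
    from .indices import add_index_columns
    from .phenotype import MUNO, add_phenotype_columns

    classified = add_phenotype_columns(add_index_columns(block))
    eligible = classified[classified["bmi"] < 25.0]
    if len(eligible) == 0:
        return 0.0, 0.0
    return len(eligible) / len(block), float((eligible["phenotype"] == MUNO).mean())


def generate_cohort(config: GeneratorConfig) -> CohortTable:
    """Generate a seeded synthetic cohort honouring the prevalence knob.

    Deterministic given ``(config, seed)``.  The returned table carries the
    extra column ``destined_muno`` recording the latent group assignment
    (the realized phenotype is left to the classification rule).
    """
    ss = np.random.SeedSequence(config.seed)
    pilot_seed, main_seed = ss.spawn(2)

    # pilot: realization rates of each destined group
    rng_p = np.random.default_rng(pilot_seed)
    half = max(200, config.pilot_n // 2)
    sex_p = np.where(rng_p.random(2 * half) < config.male_fraction, MALE, FEMALE)
    destined_p = np.r_[np.ones(half, bool), np.zeros(half, bool)]
    pilot = _draw_block(rng_p, config, destined_p, sex_p)
    elig_m, rate_m = _realized_muno_rate(pilot[pilot["destined_muno"] == 1])
    elig_h, rate_h = _realized_muno_rate(pilot[pilot["destined_muno"] == 0])
    t = config.muno_target
    # solve the destined mixing fraction on the eligible subpopulation:
    # destined-MUNO subjects are likelier to exceed the BMI eligibility
    # bound, so eligibility weights enter the mixture equation
    if rate_m - rate_h > 0.05 and rate_h < t < rate_m and min(elig_m, elig_h) > 0:
        odds = (elig_h * (t - rate_h)) / (elig_m * (rate_m - t))
        p_destined = odds / (1.0 + odds)
    else:  # groups barely separated; fall back to the raw target
        p_destined = t
    p_destined = float(np.clip(p_destined, 0.02, 0.98))

    rng = np.random.default_rng(main_seed)
    destined = rng.random(config.n) < p_destined
    sex = np.where(rng.random(config.n) < config.male_fraction, MALE, FEMALE)
    df = _draw_block(rng, config, destined, sex)
    return CohortTable(df, provenance=f"synthetic seed={config.seed} n={config.n}")


#: Latent shift profiles (in latent SD units) used by the separability
#: scenarios; the dominant index's distinctive inputs receive the largest
#: shifts so that it attains the highest AUC by construction.
SEPARABILITY_PROFILES = {
    "vai": {"tg": 0.9, "hdl": -0.7, "wc": 0.35, "bmi": 0.15, "fpg": 0.25,
            "sbp": 0.15, "dbp": 0.10, "height": -0.15},
    "lap": {"wc": 0.7, "tg": 0.8, "hdl": -0.2, "bmi": 0.2, "fpg": 0.2},
    "cvai": {"wc": 0.8, "tg": 0.5, "hdl": -0.4, "bmi": 0.3, "age": 0.3},
    "bmi": {"bmi": 0.8, "wc": 0.5},
    "wc": {"wc": 0.8, "bmi": 0.4},
    "whtr": {"wc": 0.8, "bmi": 0.3, "height": -0.3},
    "absi": {"wc": 0.6, "bmi": -0.4},
}


def _pooled_marginals(config: GeneratorConfig) -> dict:
    pooled = {}
    for var in COPULA_VARS:
        a = config.marginals_mhno[var]
        b = config.marginals_muno[var]
        pooled[var] = MarginalSpec(
            median=0.5 * (a.median + b.median),
            q1=0.5 * (a.q1 + b.q1),
            q3=0.5 * (a.q3 + b.q3),
            shift=0.5 * (a.shift + b.shift))
    return pooled


def make_separability_scenario(config: GeneratorConfig, dominant_index: str,
                               strength: float = 1.0) -> CohortTable:
    """Generate a scenario cohort in which ``dominant_index`` is the
    strongest discriminator of the scenario outcome by construction.

    All subjects share pooled marginals and pooled flag rates; the latent
    components feeding the dominant index are shifted by ±strength·δ/2
    between outcome-positive and outcome-negative subjects.  The scenario
    outcome is the assigned label itself (column ``scenario_label``), so a
    zero-strength scenario is an exact null (all AUCs ≈ 0.5).
    """
    if dominant_index not in SEPARABILITY_PROFILES:
        raise ValueError(
            f"unknown dominant index {dominant_index!r}; "
            f"choose from {sorted(SEPARABILITY_PROFILES)}")
    profile = {v: d * strength for v, d in SEPARABILITY_PROFILES[dominant_index].items()}
    rng = np.random.default_rng(np.random.SeedSequence(config.seed).spawn(3)[2])
    destined = rng.random(config.n) < config.muno_target
    sex = np.where(rng.random(config.n) < config.male_fraction, MALE, FEMALE)
    df = _draw_block(rng, config, destined, sex, latent_shift=profile,
                     pooled_marginals=_pooled_marginals(config),
                     pooled_flags=True)
    df = df.rename(columns={"destined_muno": "scenario_label"})
    return CohortTable(df, provenance=(f"scenario dominant={dominant_index} "
                                       f"strength={strength} seed={config.seed}"))
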