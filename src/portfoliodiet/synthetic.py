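"""Synthetic cohort generator.

Emulates the data structure of a young-adult nutrition cohort: per-participant
intakes of the six Portfolio Diet components, gram/day intakes per Portfolio
pillar, a fasting biomarker panel, anthropometrics and lifestyle covariates.
The marginal structure defaults to the study population it models
(n=1,507, age 23 +/- 3 years, 68% female, ethnicity ~48/34/11/7%,
LDL-C 2.3 +/- 0.7 mmol/L) with a configurable true inverse score -> LDL-C
effect so that downstream estimators can be validated by parameter recovery.

Generation is two-pass: component intakes are drawn first (right-skewed
log-normal with optional zero inflation, producing the heavy ties at zero
that quintile scoring must tolerate), the Portfolio Diet Score is computed
from them, and outcomes are then drawn as linear functions of the realised
score plus covariate effects and Gaussian noise on each outcome's analysis
scale (log scale for outcomes analysed log-transformed). The true
score-outcome slope is therefore exactly the configured value.

LDL-C is special: the cohort table stores the measured panel (TC, HDL, TG),
not LDL, so the generator draws the target LDL-C level and inverts the
Sampson-NIH equation (linear in TC given HDL and TG) for total cholesterol.
The planted LDL slope is then recovered exactly when LDL is re-derived by
the same equation. TC and non-HDL slopes are induced by this construction
rather than independently configurable.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .scoring import COMPONENTS, score_cohort


class ConfigError(ValueError):
    """Invalid generator configuration; message names the offending field."""


ETHNICITIES = ("Caucasian", "East Asian", "South Asian", "other")
EDUCATION_LEVELS = ("high_school", "some_college", "college_degree", "graduate")

#: Analysis scale per outcome: slopes/residual SDs for "log" outcomes act on
#: log(outcome); natural-scale outcomes are additive.
OUTCOME_SCALE = {
    "ldl": "none", "hdl": "none", "glucose": "none", "sbp": "none",
    "dbp": "none", "tg": "log", "crp": "log", "bmi": "log",
}


@dataclass(frozen=True)
class IntakeParams:
    """Right-skewed intake model: log-normal around ``median`` with log-scale
    ``sigma``, a point mass of true zero consumers with probability ``p_zero``,
    and a gram conversion for the pillar intake (g per serving; phytosterols
    use mg -> g)."""

    median: float
    sigma: float
    p_zero: float = 0.0
    grams_per_unit: float = 1.0


DEFAULT_INTAKE_PARAMS = {
    "plant_protein": IntakeParams(0.25, 1.0, 0.25, grams_per_unit=6.0),
    "viscous_fibre": IntakeParams(1.0, 0.7, 0.02, grams_per_unit=1.5),
    "nuts": IntakeParams(0.4, 1.0, 0.30, grams_per_unit=7.0),
    "phytosterols": IntakeParams(250.0, 0.5, 0.0, grams_per_unit=1e-3),  # mg/day
    "mufas": IntakeParams(0.25, 1.0, 0.30, grams_per_unit=10.0),
    "sat_fat_chol": IntakeParams(2.0, 0.6, 0.0),
}

#: Five Portfolio pillars with gram/day intakes (saturated fat is not a pillar).
PILLARS = ("plant_protein", "viscous_fibre", "nuts", "phytosterols", "mufas")

DEFAULT_TRUE_EFFECTS = {
    "ldl": -0.009,      # mmol/L per PDS point
    "hdl": 0.0005,
    "tg": -0.005,       # log scale
    "glucose": -0.001,
    "crp": -0.007,      # log scale
    "sbp": -0.150,      # mmHg per point
    "dbp": -0.133,
    "bmi": -0.0016,     # log scale
}

#: (natural-scale mean, analysis-scale residual SD)
DEFAULT_OUTCOME_BASELINES = {
    "ldl": (2.3, 0.7),
    "hdl": (1.54, 0.33),
    "tg": (0.97, 0.40),
    "glucose": (4.79, 0.40),
    "crp": (1.0, 0.9),
    "sbp": (114.0, 9.0),
    "dbp": (69.3, 7.5),
    "bmi": (23.0, 0.14),
}

#: Covariate slopes per outcome on the analysis scale. "female" is the
#: indicator centred at the configured female proportion and "age" is centred
#: at the configured mean age, so the configured baseline means stay the
#: marginal outcome means.
DEFAULT_COVARIATE_EFFECTS = {
    "ldl": {"female": -0.10, "age": 0.010},
    "hdl": {"female": 0.25},
    "tg": {"female": -0.10},
    "glucose": {"female": -0.15, "age": 0.010},
    "crp": {"female": 0.30},
    "sbp": {"female": -6.0, "age": 0.20},
    "dbp": {"female": -2.0, "age": 0.30},
    "bmi": {"female": -0.02, "age": 0.005},
}


@dataclass(frozen=True)
class CohortConfig:
    n_participants: int = 1507
    seed: int = 0
    age_mean: float = 23.0
    age_sd: float = 3.0
    prop_female: float = 0.68
    ethnicity_probs: tuple[float, float, float, float] = (0.48, 0.34, 0.11, 0.07)
    component_intake_params: dict = field(
        default_factory=lambda: dict(DEFAULT_INTAKE_PARAMS))
    true_effects: dict = field(default_factory=lambda: dict(DEFAULT_TRUE_EFFECTS))
    outcome_baselines: dict = field(
        default_factory=lambda: dict(DEFAULT_OUTCOME_BASELINES))
    covariate_effects: dict = field(
        default_factory=lambda: dict(DEFAULT_COVARIATE_EFFECTS))
    energy_link: float = 60.0       # kcal/day per PDS point
    energy_mean: float = 1985.0
    energy_sd: float = 550.0

    def validate(self) -> None:
        if self.n_participants < 30:
            raise ConfigError("n_participants must be >= 30")
        if not 0.0 <= self.prop_female <= 1.0:
            raise ConfigError("prop_female must lie in [0, 1]")
        probs = np.asarray(self.ethnicity_probs, dtype=float)
        if probs.shape != (4,):
            raise ConfigError("ethnicity_probs must have 4 entries")
        if np.any(probs < 0) or abs(probs.sum() - 1.0) > 1e-9:
            raise ConfigError("ethnicity_probs must be non-negative and sum to 1")
        if self.age_sd <= 0:
            raise ConfigError("age_sd must be > 0")
        if self.energy_sd <= 0:
            raise ConfigError("energy_sd must be > 0")
        for comp in COMPONENTS:
            if comp not in self.component_intake_params:
                raise ConfigError(f"component_intake_params missing {comp!r}")
            p = self.component_intake_params[comp]
            if p.median <= 0 or p.sigma <= 0:
                raise ConfigError(
                    f"component_intake_params[{comp!r}]: median and sigma must be > 0")
            if not 0.0 <= p.p_zero <= 1.0:
                raise ConfigError(
                    f"component_intake_params[{comp!r}].p_zero must lie in [0, 1]")
        for outcome, (mean, sd) in self.outcome_baselines.items():
            if sd <= 0:
                raise ConfigError(f"outcome_baselines[{outcome!r}]: residual SD must be > 0")
            if OUTCOME_SCALE.get(outcome) == "log" and mean <= 0:
                raise ConfigError(f"outcome_baselines[{outcome!r}]: log outcome needs mean > 0")
        for outcome in self.true_effects:
            if outcome not in self.outcome_baselines:
                raise ConfigError(f"true_effects names unknown outcome {outcome!r}")


# Sampson-NIH constants, mg/dL (see ingest.ldl_nih); inverted for TC below.
_MGDL_CHOL = 38.67
_MGDL_TG = 88.57


def _tc_from_target_ldl(ldl, hdl, tg):
    """Invert the Sampson-NIH equation for total cholesterol (all mmol/L).

    The equation is linear in TC given HDL and TG:
    LDL = TC/0.948 - HDL/0.971 - TG/8.56 - TG*(TC - HDL)/2140 + TG^2/16100 - 9.44.
    """
    ldl_m, hdl_m, tg_m = ldl * _MGDL_CHOL, hdl * _MGDL_CHOL, tg * _MGDL_TG
    rhs = (ldl_m + hdl_m / 0.971 + tg_m / 8.56 - tg_m * hdl_m / 2140.0
           - tg_m ** 2 / 16100.0 + 9.44)
    return rhs / (1.0 / 0.948 - tg_m / 2140.0) / _MGDL_CHOL


def generate_cohort(config: CohortConfig | None = None) -> pd.DataFrame:
    """Generate a participant table; reproducible given ``config.seed``.

    Returns one row per participant with raw component intakes (servings/day;
    phytosterols mg/day), pillar gram/day intakes (``grams_<pillar>``),
    covariates, and the measured biomarker panel. The realised score used to
    plant the outcome effects is included as ``pds_true`` for diagnostics;
    analyses should re-score from the intake columns.
    """
    config = config or CohortConfig()
    config.validate()
    rng = np.random.default_rng(config.seed)
    n = config.n_participants

    # demographics and lifestyle
    sex = np.where(rng.random(n) < config.prop_female, "female", "male")
    ethnicity = rng.choice(ETHNICITIES, size=n, p=np.asarray(config.ethnicity_probs))
    age = np.clip(rng.normal(config.age_mean, config.age_sd, n), 18.0, None)
    education = rng.choice(EDUCATION_LEVELS, size=n, p=[0.02, 0.58, 0.31, 0.09])
    smoking = np.where(rng.random(n) < 0.05, "current", "non")
    physical_activity = rng.uniform(1.2, 2.2, n)
    alcohol = np.where(rng.random(n) < 0.30, 0.0,
                       rng.lognormal(np.log(3.0), 1.0, n))
    family_cvd = rng.random(n) < 0.02
    family_diabetes = rng.random(n) < 0.13
    hypertension = rng.random(n) < 0.01
    hypercholesterolemia = rng.random(n) < 0.03

    # component intakes: zero-inflated log-normal (pass 1)
    intakes = {}
    for comp in COMPONENTS:
        p = config.component_intake_params[comp]
        x = rng.lognormal(np.log(p.median), p.sigma, n)
        if p.p_zero > 0:
            x = np.where(rng.random(n) < p.p_zero, 0.0, x)
        intakes[comp] = x
    df = pd.DataFrame(intakes)

    # pillar gram/day intakes (for absolute adherence)
    for pillar in PILLARS:
        p = config.component_intake_params[pillar]
        noise = np.exp(rng.normal(0.0, 0.3, n))
        df[f"grams_{pillar}"] = df[pillar] * p.grams_per_unit * noise

    # score the realised intakes (pass 2 uses the realised score)
    pds = score_cohort(df[list(COMPONENTS)])["pds"].to_numpy()
    pds_c = pds - pds.mean()

    energy = config.energy_mean + config.energy_link * pds_c \
        + rng.normal(0.0, config.energy_sd, n)
    energy = np.clip(energy, 100.0, None)

    female = (sex == "female").astype(float) - config.prop_female
    age_c = age - config.age_mean

    def linear_predictor(outcome):
        slope = config.true_effects.get(outcome, 0.0)
        lin = slope * pds_c
        for cov, beta in config.covariate_effects.get(outcome, {}).items():
            lin = lin + beta * {"female": female, "age": age_c}[cov]
        return lin

    def draw(outcome, clip_min=None):
        mean, sd = config.outcome_baselines[outcome]
        lin = linear_predictor(outcome) + rng.normal(0.0, sd, n)
        if OUTCOME_SCALE[outcome] == "log":
            y = np.exp(np.log(mean) + lin)
        else:
            y = mean + lin
        return np.clip(y, clip_min, None) if clip_min is not None else y

    hdl = draw("hdl", clip_min=0.4)
    tg = draw("tg")
    ldl = draw("ldl", clip_min=0.3)
    tc = np.maximum(_tc_from_target_ldl(ldl, hdl, tg), hdl + 0.05)
    glucose = draw("glucose", clip_min=2.0)
    crp = draw("crp")
    sbp = draw("sbp", clip_min=70.0)
    dbp = draw("dbp", clip_min=40.0)

    height = np.where(sex == "female",
                      rng.normal(1.63, 0.065, n), rng.normal(1.78, 0.07, n))
    bmi = draw("bmi")
    weight = bmi * height ** 2

    out = pd.DataFrame({
        "id": np.arange(1, n + 1),
        "age": age, "sex": sex, "ethnicity": ethnicity, "education": education,
        "smoking": smoking, "physical_activity": physical_activity,
        "energy_kcal": energy, "alcohol_g": alcohol,
        "family_cvd": family_cvd, "family_diabetes": family_diabetes,
        "hypertension": hypertension, "hypercholesterolemia": hypercholesterolemia,
    })
    for comp in COMPONENTS:
        out[comp] = df[comp]
    for pillar in PILLARS:
        out[f"grams_{pillar}"] = df[f"grams_{pillar}"]
    out["tc"] = tc
    out["hdl"] = hdl
    out["tg"] = tg
    out["glucose"] = glucose
    out["crp"] = crp
    out["sbp"] = sbp
    out["dbp"] = dbp
    out["height_m"] = height
    out["weight_kg"] = weight
    out["pds_true"] = pds
    return out


def inject_missingness(df: pd.DataFrame, rates: dict[str, float],
                       seed: int = 0) -> pd.DataFrame:
    """Set each named column to NaN independently with the given rate.

    Deterministic given ``seed``; rates must lie in [0, 1].
    """
    for col, rate in rates.items():
        if not 0.0 <= rate <= 1.0:
            raise ValueError(f"missingness rate for {col!r} must lie in [0, 1]")
        if col not in df.columns:
            raise KeyError(f"no column {col!r} in cohort table")
    rng = np.random.default_rng(seed)
    out = df.copy()
    for col, rate in rates.items():
        mask = rng.random(len(df)) < rate
        if mask.any():
            out[col] = out[col].astype(float) if out[col].dtype.kind in "biu" else out[col]
            out.loc[mask, col] = np.nan
    return out


def with_effects(config: CohortConfig, **slopes: float) -> CohortConfig:
    """Convenience: return a config with some true per-point slopes replaced."""
    effects = dict(config.true_effects)
    effects.update(slopes)
    return replace(config, true_effects=effects)
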