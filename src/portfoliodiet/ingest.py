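"""Cohort cleaning and derived biomarkers.

Implements the exclusion rules applied before analysis (implausible energy
intake, incomplete diet data, missing covariates, missing outcomes) and the
derived biomarkers: estimated LDL-C by three equations (Sampson-NIH as the
primary, Martin/Hopkins and Vujovic as sensitivity equations), non-HDL-C,
BMI, Deurenberg body-fat percentage and fat mass index (FMI).

All lipid equations are evaluated in mg/dL (their native scale) and reported
in mmol/L; conversions use the conventional factors 38.67 (cholesterol),
88.57 (triglycerides) and 18.018 (glucose).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import pandas as pd

# -- unit conversions ---------------------------------------------------------

MGDL_PER_MMOL_CHOL = 38.67
MGDL_PER_MMOL_TG = 88.57
MGDL_PER_MMOL_GLUCOSE = 18.018


def chol_mmol_to_mgdl(x):
    return np.asarray(x, dtype=float) * MGDL_PER_MMOL_CHOL


def chol_mgdl_to_mmol(x):
    return np.asarray(x, dtype=float) / MGDL_PER_MMOL_CHOL


def tg_mmol_to_mgdl(x):
    return np.asarray(x, dtype=float) * MGDL_PER_MMOL_TG


def tg_mgdl_to_mmol(x):
    return np.asarray(x, dtype=float) / MGDL_PER_MMOL_TG


def glucose_mmol_to_mgdl(x):
    return np.asarray(x, dtype=float) * MGDL_PER_MMOL_GLUCOSE


def glucose_mgdl_to_mmol(x):
    return np.asarray(x, dtype=float) / MGDL_PER_MMOL_GLUCOSE


# -- LDL-C estimating equations ----------------------------------------------

def _check_lipid_inputs(tc, hdl, tg):
    tc = np.asarray(tc, dtype=float)
    hdl = np.asarray(hdl, dtype=float)
    tg = np.asarray(tg, dtype=float)
    for name, v in (("tc", tc), ("hdl", hdl), ("tg", tg)):
        if np.any(v[~np.isnan(v)] < 0):
            raise ValueError(f"negative {name} value in lipid panel")
    return tc, hdl, tg


def ldl_nih(tc, hdl, tg):
    """Sampson-NIH estimated LDL-C (mmol/L in, mmol/L out).

    In mg/dL: LDL = TC/0.948 - HDL/0.971
                    - (TG/8.56 + TG*nonHDL/2140 - TG^2/16100) - 9.44.
    The result may be negative for extreme panels; cohort-level correction is
    handled by :func:`replace_negative_ldl`.
    """
    tc, hdl, tg = _check_lipid_inputs(tc, hdl, tg)
    tc_m, hdl_m, tg_m = chol_mmol_to_mgdl(tc), chol_mmol_to_mgdl(hdl), tg_mmol_to_mgdl(tg)
    nonhdl_m = tc_m - hdl_m
    ldl_m = (tc_m / 0.948 - hdl_m / 0.971
             - (tg_m / 8.56 + tg_m * nonhdl_m / 2140.0 - tg_m ** 2 / 16100.0)
             - 9.44)
    out = chol_mgdl_to_mmol(ldl_m)
    return out if out.ndim else float(out)


_MARTIN_TABLE: pd.DataFrame | None = None
_MARTIN_NONHDL_EDGES = (100.0, 130.0, 160.0, 190.0, 220.0)


def martin_factor_table() -> pd.DataFrame:
    """The packaged 30x6 Martin/Hopkins TG:VLDL-C factor table (mg/dL strata)."""
    global _MARTIN_TABLE
    if _MARTIN_TABLE is None:
        with resources.files("portfoliodiet.data").joinpath("martin_factors.csv").open() as fh:
            _MARTIN_TABLE = pd.read_csv(fh, comment="#")
    return _MARTIN_TABLE


def martin_factor(tg_mgdl, nonhdl_mgdl):
    """Adjustable TG:VLDL-C divisor looked up in the packaged table.

    TG outside the tabulated range is clamped to the boundary stratum with a
    warning.
    """
    table = martin_factor_table()
    tg = np.atleast_1d(np.asarray(tg_mgdl, dtype=float))
    nonhdl = np.atleast_1d(np.asarray(nonhdl_mgdl, dtype=float))
    tg, nonhdl = np.broadcast_arrays(tg, nonhdl)
    lo, hi = table["tg_min"].iloc[0], table["tg_max"].iloc[-1]
    if np.any(tg < lo) or np.any(tg > hi):
        warnings.warn(
            f"triglycerides outside the Martin table range [{lo}, {hi}] mg/dL; "
            "clamped to the boundary stratum", stacklevel=2)
    row = np.searchsorted(table["tg_max"].to_numpy(), tg, side="left")
    row = np.clip(row, 0, len(table) - 1)
    col = np.searchsorted(np.asarray(_MARTIN_NONHDL_EDGES), nonhdl, side="right")
    factors = table.iloc[:, 2:].to_numpy()
    out = factors[row, col]
    return out if np.ndim(tg_mgdl) else float(out[0])


def ldl_martin(tc, hdl, tg):
    """Martin/Hopkins estimated LDL-C: non-HDL - TG/factor (mmol/L in/out)."""
    tc, hdl, tg = _check_lipid_inputs(tc, hdl, tg)
    tg_m = tg_mmol_to_mgdl(tg)
    nonhdl_m = chol_mmol_to_mgdl(tc) - chol_mmol_to_mgdl(hdl)
    with np.errstate(invalid="ignore"):
        factor = martin_factor(tg_m, nonhdl_m)
    out = chol_mgdl_to_mmol(nonhdl_m - tg_m / factor)
    return out if np.ndim(tc) else float(out)


def ldl_vujovic(tc, hdl, tg):
    """Vujovic estimated LDL-C: TC - HDL - TG/6.85 in mg/dL (mmol/L in/out)."""
    tc, hdl, tg = _check_lipid_inputs(tc, hdl, tg)
    ldl_m = chol_mmol_to_mgdl(tc) - chol_mmol_to_mgdl(hdl) - tg_mmol_to_mgdl(tg) / 6.85
    out = chol_mgdl_to_mmol(ldl_m)
    return out if out.ndim else float(out)


def non_hdl(tc, hdl):
    """Non-HDL cholesterol = total cholesterol - HDL-C (mmol/L)."""
    out = np.asarray(tc, dtype=float) - np.asarray(hdl, dtype=float)
    return out if out.ndim else float(out)


def replace_negative_ldl(values):
    """Replace negative computed LDL-C with the minimum positive sample value.

    Non-negative inputs pass through unchanged; NaNs are preserved. Raises if
    no positive value exists (the replacement would be undefined).
    """
    x = np.asarray(values, dtype=float).copy()
    pos = x[np.isfinite(x) & (x > 0)]
    if pos.size == 0:
        raise ValueError("no positive LDL-C value in sample; replacement undefined")
    x[np.isfinite(x) & (x < 0)] = pos.min()
    return x


# -- anthropometry ------------------------------------------------------------

def bmi(weight_kg, height_m):
    """Body mass index, kg/m^2."""
    out = np.asarray(weight_kg, dtype=float) / np.asarray(height_m, dtype=float) ** 2
    return out if out.ndim else float(out)


def deurenberg_bf(bmi_val, age, sex):
    """Deurenberg adult body-fat percentage.

    BF% = 1.20*BMI + 0.23*age - 10.8*[male] - 5.4; clipped to [0, 100] with a
    warning if the formula leaves that range. ``sex`` is 'male'/'female' (or
    an array thereof). Requires adults (age >= 18) and positive BMI.
    """
    b = np.asarray(bmi_val, dtype=float)
    a = np.asarray(age, dtype=float)
    if np.any(b[~np.isnan(b)] <= 0):
        raise ValueError("bmi must be positive")
    if np.any(a[~np.isnan(a)] < 18):
        raise ValueError("Deurenberg adult formula requires age >= 18")
    male = np.char.lower(np.asarray(sex, dtype="U6")) == "male"
    bf = 1.20 * b + 0.23 * a - 10.8 * male - 5.4
    if np.any((bf < 0) | (bf > 100)):
        warnings.warn("Deurenberg BF% outside [0, 100]; clipped", stacklevel=2)
        bf = np.clip(bf, 0.0, 100.0)
    return bf if bf.ndim else float(bf)


def fmi(body_fat_pct, weight_kg, height_m):
    """Fat mass index = (BF% x weight) / height^2, kg/m^2. Always <= BMI."""
    fat_mass = np.asarray(body_fat_pct, dtype=float) / 100.0 * np.asarray(weight_kg, dtype=float)
    out = fat_mass / np.asarray(height_m, dtype=float) ** 2
    return out if out.ndim else float(out)


# -- exclusions ---------------------------------------------------------------

#: Diet components whose intake must be present for the score to exist.
DIET_FIELDS = ("plant_protein", "viscous_fibre", "nuts",
               "phytosterols", "mufas", "sat_fat_chol")

DEFAULT_COVARIATE_FIELDS = (
    "sex", "age", "education", "ethnicity", "family_cvd", "family_diabetes",
    "hypertension", "hypercholesterolemia", "energy_kcal", "smoking",
    "physical_activity", "alcohol_g",
)

#: Raw fields each outcome's derivation needs (complete-case per outcome).
DEFAULT_OUTCOME_FIELDS = {
    "ldl": ("tc", "hdl", "tg"),
    "non_hdl": ("tc", "hdl"),
    "tc": ("tc",),
    "hdl": ("hdl",),
    "tg": ("tg",),
    "crp": ("crp",),
    "glucose": ("glucose",),
    "sbp": ("sbp",),
    "dbp": ("dbp",),
    "bmi": ("weight_kg", "height_m"),
    "weight": ("weight_kg",),
    "fmi": ("weight_kg", "height_m", "age", "sex"),
}


@dataclass(frozen=True)
class ExclusionPolicy:
    """Energy-implausibility bounds and per-outcome required fields.

    Thresholds are strict inequalities: a female at exactly 3500 kcal/day is
    retained, one above it is excluded.
    """

    max_kcal_female: float = 3500.0
    max_kcal_male: float = 4500.0
    min_kcal: float = 800.0
    required_fields_per_outcome: dict = field(
        default_factory=lambda: dict(DEFAULT_OUTCOME_FIELDS))

    def __post_init__(self) -> None:
        if not (self.min_kcal < self.max_kcal_female < self.max_kcal_male):
            raise ValueError("require min_kcal < max_kcal_female < max_kcal_male")


def apply_exclusions(df: pd.DataFrame, policy: ExclusionPolicy | None = None
                     ) -> tuple[pd.DataFrame, dict]:
    """Apply the exclusion cascade and return (retained, ledger).

    Order: implausible energy -> incomplete diet data -> missing covariates ->
    missing outcome data (counted per outcome among the remaining records).
    A record excluded at an earlier step is never recounted later. Records
    missing only outcome fields stay in the retained table; the ledger
    records, per outcome, how many of the retained records lack that
    outcome's inputs (complete-case analysis drops them per model).
    """
    policy = policy or ExclusionPolicy()
    n_input = len(df)
    if n_input == 0:
        ledger = {"n_input": 0, "implausible_energy": 0, "incomplete_diet": 0,
                  "missing_covariates": 0, "missing_outcome": {}, "n_retained": 0}
        return df.copy(), ledger

    energy = df["energy_kcal"].to_numpy(dtype=float)
    is_female = df["sex"].astype(str).str.lower().eq("female").to_numpy()
    too_high = np.where(is_female, energy > policy.max_kcal_female,
                        energy > policy.max_kcal_male)
    too_low = energy < policy.min_kcal
    bad_energy = (too_high | too_low) & ~np.isnan(energy)

    keep = ~bad_energy
    diet_cols = [c for c in DIET_FIELDS if c in df.columns]
    incomplete_diet = df[diet_cols].isna().any(axis=1).to_numpy() & keep
    keep &= ~incomplete_diet

    cov_cols = [c for c in DEFAULT_COVARIATE_FIELDS if c in df.columns]
    missing_cov = df[cov_cols].isna().any(axis=1).to_numpy() & keep
    keep &= ~missing_cov

    retained = df.loc[keep].copy()
    missing_outcome = {}
    for outcome, fields in policy.required_fields_per_outcome.items():
        cols = [c for c in fields if c in retained.columns]
        if cols:
            missing_outcome[outcome] = int(retained[cols].isna().any(axis=1).sum())

    ledger = {
        "n_input": int(n_input),
        "implausible_energy": int(bad_energy.sum()),
        "incomplete_diet": int(incomplete_diet.sum()),
        "missing_covariates": int(missing_cov.sum()),
        "missing_outcome": missing_outcome,
        "n_retained": int(len(retained)),
    }
    return retained, ledger


# -- derived-biomarker convenience --------------------------------------------

def derive_biomarkers(df: pd.DataFrame, replace_negatives: bool = True) -> pd.DataFrame:
    """Append derived outcome columns to a cohort table.

    Adds ldl_nih/ldl_martin/ldl_vujovic (each with cohort-level negative-value
    replacement, applied per equation), non_hdl, bmi, body_fat_pct and fmi.
    Rows with missing inputs yield NaN in the derived column.
    """
    out = df.copy()
    tc, hdl, tg = out["tc"], out["hdl"], out["tg"]
    for name, fn in (("ldl_nih", ldl_nih), ("ldl_martin", ldl_martin),
                     ("ldl_vujovic", ldl_vujovic)):
        vals = fn(tc.to_numpy(dtype=float), hdl.to_numpy(dtype=float),
                  tg.to_numpy(dtype=float))
        if replace_negatives and np.any(np.isfinite(vals) & (vals < 0)):
            vals = replace_negative_ldl(vals)
        out[name] = vals
    out["non_hdl"] = non_hdl(tc.to_numpy(dtype=float), hdl.to_numpy(dtype=float))
    if {"weight_kg", "height_m"} <= set(out.columns):
        out["bmi"] = bmi(out["weight_kg"].to_numpy(dtype=float),
                         out["height_m"].to_numpy(dtype=float))
        if {"age", "sex"} <= set(out.columns):
            out["body_fat_pct"] = deurenberg_bf(out["bmi"].to_numpy(dtype=float),
                                                out["age"].to_numpy(dtype=float),
                                                out["sex"].to_numpy())
            out["fmi"] = fmi(out["body_fat_pct"].to_numpy(dtype=float),
                             out["weight_kg"].to_numpy(dtype=float),
                             out["height_m"].to_numpy(dtype=float))
    return out
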