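"""Absolute adherence and cumulative LDL-C exposure projection.

Converts gram/day pillar intakes into absolute adherence against the
Portfolio Diet recommendations (50 g/day plant protein, 20 g/day viscous
fibre, 45 g/day nuts, 2 g/day phytosterols, 45 g/day MUFAs), expresses
overall adherence as a percentage and as the food-based 0-25 point clinical
Portfolio Diet Score (c-PDS), and projects lifetime cardiovascular risk
onset from cumulative LDL-C exposure.

The exposure model holds LDL-C constant over life, so cumulative exposure is
``LDL-C x age`` (mmol/L-years, linear through the origin). Risk onset is the
age at which cumulative exposure crosses a plaque-burden threshold. The
default threshold is 5,000 mg/dL-years (= 5,000/38.67 = 129.30 mmol/L-years,
the Ference cumulative-exposure framework); onset ages are rounded to the
nearest whole year, half away from zero. The commonly quoted round figure of
125 mmol/L-years is available via the ``threshold`` argument but is not the
default because it is mutually inconsistent with nearest-year onset ages for
typical young-adult LDL-C levels under this model.

LDL-C at adherence levels between (or beyond) the observed tertiles is
interpolated linearly through two (adherence %, LDL-C) anchor points,
conventionally the lowest and highest tertiles of the scored cohort.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .ingest import MGDL_PER_MMOL_CHOL

#: Established daily-gram recommendations per Portfolio pillar.
DEFAULT_RECOMMENDATIONS_G = {
    "plant_protein": 50.0,
    "viscous_fibre": 20.0,
    "nuts": 45.0,
    "phytosterols": 2.0,
    "mufas": 45.0,
}

#: Plaque-burden threshold: 5,000 mg/dL-years on the cholesterol scale.
DEFAULT_THRESHOLD_MMOL_YEARS = 5000.0 / MGDL_PER_MMOL_CHOL

C_PDS_MAX = 25


def round_half_away(x: float) -> int:
    """Round to nearest integer, ties away from zero (not banker's rounding)."""
    return int(math.floor(abs(x) + 0.5) * (1 if x >= 0 else -1))


@dataclass(frozen=True)
class Recommendations:
    plant_protein: float = 50.0
    viscous_fibre: float = 20.0
    nuts: float = 45.0
    phytosterols: float = 2.0
    mufas: float = 45.0

    def __post_init__(self) -> None:
        if any(v <= 0 for v in self.as_dict().values()):
            raise ValueError("all recommendations must be positive g/day")

    def as_dict(self) -> dict[str, float]:
        return {"plant_protein": self.plant_protein,
                "viscous_fibre": self.viscous_fibre, "nuts": self.nuts,
                "phytosterols": self.phytosterols, "mufas": self.mufas}


@dataclass(frozen=True)
class AdherenceProfile:
    """Per-pillar and overall absolute adherence.

    ``component_pct`` holds unrounded fractions of the recommendation;
    ``overall_frac`` is their unrounded mean; ``overall_pct`` the whole-percent
    reporting value; ``cpds_points`` = round(overall_frac x 25), in [0, 25].
    """

    component_pct: dict[str, float]

    @property
    def overall_frac(self) -> float:
        return float(np.mean(list(self.component_pct.values())))

    @property
    def overall_pct(self) -> int:
        return round_half_away(100.0 * self.overall_frac)

    @property
    def cpds_points(self) -> int:
        return int(np.clip(round_half_away(C_PDS_MAX * self.overall_frac), 0, C_PDS_MAX))

    @classmethod
    def from_percentages(cls, pcts, components=tuple(DEFAULT_RECOMMENDATIONS_G)):
        """Build a profile directly from per-component adherence percentages."""
        return cls(component_pct={c: p / 100.0 for c, p in zip(components, pcts, strict=True)})


def absolute_adherence(pillar_grams: dict[str, float],
                       recommendations: Recommendations | None = None,
                       cap: bool = False) -> AdherenceProfile:
    """Adherence profile from gram/day pillar intakes.

    Per-pillar adherence is intake / recommendation; ``cap=True`` truncates
    each pillar at 100%. Negative intakes are a domain error.
    """
    rec = (recommendations or Recommendations()).as_dict()
    pct = {}
    for pillar, r in rec.items():
        g = float(pillar_grams[pillar])
        if g < 0:
            raise ValueError(f"negative intake for pillar {pillar!r}")
        frac = g / r
        pct[pillar] = min(frac, 1.0) if cap else frac
    return AdherenceProfile(component_pct=pct)


def cohort_adherence(df: pd.DataFrame, tertile_col: str = "tertile",
                     recommendations: Recommendations | None = None) -> pd.DataFrame:
    """Mean gram/day intake per tertile converted to an adherence profile.

    Expects ``grams_<pillar>`` columns and a tertile label column; returns one
    row per tertile with per-pillar %, overall % and c-PDS points.
    """
    rec = recommendations or Recommendations()
    rows = []
    for t, sub in df.groupby(tertile_col, sort=True):
        grams = {p: float(sub[f"grams_{p}"].mean()) for p in rec.as_dict()}
        prof = absolute_adherence(grams, rec)
        rows.append({tertile_col: t,
                     **{f"pct_{p}": 100.0 * v for p, v in prof.component_pct.items()},
                     "overall_pct": prof.overall_pct, "cpds": prof.cpds_points})
    return pd.DataFrame(rows)


def ldl_at_adherence(query_pct: float,
                     anchors: tuple[tuple[float, float], tuple[float, float]]
                     = ((6.0, 2.34), (27.0, 2.24))) -> float:
    """LDL-C (mmol/L) at an adherence percentage, linear through two anchors.

    Anchors are (adherence %, LDL-C mmol/L) points, conventionally the lowest
    and highest adherence tertiles; the line extrapolates beyond them.
    """
    (x1, y1), (x2, y2) = anchors
    if x1 == x2:
        raise ValueError("anchor adherence percentages must differ")
    return y1 + (y2 - y1) * (query_pct - x1) / (x2 - x1)


def cumulative_ldl(ldl_constant: float, age: float) -> float:
    """Cumulative LDL-C exposure, mmol/L-years, assuming a constant level."""
    return ldl_constant * age


def onset_age(ldl_constant: float,
              threshold: float = DEFAULT_THRESHOLD_MMOL_YEARS) -> int:
    """Age at which cumulative LDL-C crosses the threshold, to the nearest year."""
    if ldl_constant <= 0:
        raise ValueError("LDL-C level must be positive")
    return round_half_away(threshold / ldl_constant)


def onset_age_exact(ldl_constant: float,
                    threshold: float = DEFAULT_THRESHOLD_MMOL_YEARS) -> float:
    """Unrounded threshold-crossing age (threshold / LDL)."""
    if ldl_constant <= 0:
        raise ValueError("LDL-C level must be positive")
    return threshold / ldl_constant


def delay_vs_reference(onset_ages: dict[str, int], reference: str) -> dict[str, int]:
    """Years of risk-onset delay for each level relative to the reference level."""
    if reference not in onset_ages:
        raise KeyError(f"reference level {reference!r} not among onset ages")
    ref = onset_ages[reference]
    return {level: age - ref for level, age in onset_ages.items()}


def trajectory_table(levels: dict[str, float], ages,
                     threshold: float = DEFAULT_THRESHOLD_MMOL_YEARS,
                     cohort_age: float = 23.0) -> pd.DataFrame:
    """Tidy cumulative-exposure curves with cohort-age and onset markers.

    One row per (level, age) with the cumulative mmol/L-years, plus marker
    columns: ``at_cohort_age`` flags the grid age nearest the cohort mean age
    and ``onset`` flags the rounded threshold-crossing age for that level.
    """
    ages = np.asarray(ages, dtype=float)
    if ages.size and np.any(np.diff(ages) < 0):
        raise ValueError("ages grid must be ascending")
    rows = []
    for level, ldl in levels.items():
        onset = onset_age(ldl, threshold)
        nearest_cohort = ages[np.argmin(np.abs(ages - cohort_age))] if ages.size else None
        for a in ages:
            rows.append({
                "level": level, "ldl_mmol_l": ldl, "age": float(a),
                "cumulative_mmol_years": cumulative_ldl(ldl, float(a)),
                "at_cohort_age": bool(nearest_cohort is not None and a == nearest_cohort),
                "onset": bool(a == onset),
                "onset_age": onset,
            })
    return pd.DataFrame(rows)


def exposure_report(anchors=((6.0, 2.34), (27.0, 2.24)),
                    tertile_levels: dict[str, float] | None = None,
                    adherence_levels=(50.0, 100.0),
                    threshold: float = DEFAULT_THRESHOLD_MMOL_YEARS) -> pd.DataFrame:
    """Onset ages and delays for tertile LDL-C levels and target adherences.

    ``tertile_levels`` defaults to the anchor LDL values for T1/T3 plus their
    midpoint convention is NOT applied -- callers pass the observed tertile
    means. Adherence levels are evaluated on the two-anchor line, with LDL
    rounded to 2 decimals before the onset computation (reporting precision).
    """
    levels: dict[str, float] = dict(tertile_levels or
                                    {"T1": anchors[0][1], "T3": anchors[1][1]})
    for pct in adherence_levels:
        levels[f"{round_half_away(pct)}%"] = round(ldl_at_adherence(pct, anchors), 2)
    ages = {name: onset_age(ldl, threshold) for name, ldl in levels.items()}
    ref = "T1" if "T1" in ages else next(iter(ages))
    delays = delay_vs_reference(ages, ref)
    return pd.DataFrame(
        [{"level": name, "ldl_mmol_l": levels[name], "onset_age": ages[name],
          "delay_years_vs_" + ref: delays[name]} for name in levels])
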