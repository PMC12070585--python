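"""Population-based Portfolio Diet Score (PDS).

The PDS grades adherence to the Portfolio dietary pattern from the
within-sample distribution of six food components: five recommended
("favourable") components -- sources of plant protein, viscous fibre, nuts,
phytosterols and MUFAs -- and one discouraged component, sources of
saturated fat and cholesterol. Each participant receives 1-5 points per
component according to the population quintile of their intake; the
saturated-fat/cholesterol component is reverse-scored (highest quintile
earns one point). The six component points sum to a total between 6 and 30,
with higher totals indicating closer adherence.

Quintile cutpoints are the 20/40/60/80th sample percentiles computed with
linear-interpolation (type-7) quantiles. Intakes exactly equal to a
boundary fall in the lower quintile (half-open intervals ``(b_{k-1}, b_k]``);
with heavily tied intakes (e.g. many zero consumers of nuts) several
boundaries can coincide, in which case all tied values land in the lowest
quintile and upper quintiles may be empty. Both behaviours are deliberate
and documented because they change scores for non-consumers.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: Canonical component order. Intakes are servings/day except phytosterols
#: (mg/day). Only ``sat_fat_chol`` is reverse-scored.
COMPONENTS = (
    "plant_protein",
    "viscous_fibre",
    "nuts",
    "phytosterols",
    "mufas",
    "sat_fat_chol",
)

REVERSE_COMPONENTS = frozenset({"sat_fat_chol"})

PDS_MIN = 6
PDS_MAX = 30

TERTILE_LABELS = ("T1", "T2", "T3")


@dataclass(frozen=True)
class QuintileCutpoints:
    """Per-component quintile boundaries (4 ascending quantile values)."""

    component: str
    boundaries: tuple[float, float, float, float]

    def __post_init__(self) -> None:
        b = np.asarray(self.boundaries, dtype=float)
        if b.shape != (4,):
            raise ValueError(f"{self.component}: expected 4 boundaries, got {b.shape}")
        if np.any(np.diff(b) < 0):
            raise ValueError(f"{self.component}: boundaries must be non-decreasing")


@dataclass(frozen=True)
class PdsResult:
    """Component points (each 1-5), their 6-30 total and a tertile label."""

    component_points: dict[str, int]
    total: int
    tertile: str | None = None

    def __post_init__(self) -> None:
        if self.total != sum(self.component_points.values()):
            raise ValueError("total must equal the sum of component points")


def estimate_cutpoints(intakes, component: str = "") -> QuintileCutpoints:
    """20/40/60/80th percentiles of the non-missing intakes (type-7).

    Requires at least 5 non-missing values; the cutpoints are estimated from
    the analysis sample itself ("population mode").
    """
    x = np.asarray(pd.Series(intakes).dropna(), dtype=float)
    if x.size < 5:
        raise ValueError(
            f"need >= 5 non-missing intakes to estimate quintiles for "
            f"{component or 'component'}, got {x.size}"
        )
    q = np.quantile(x, [0.2, 0.4, 0.6, 0.8])  # linear interpolation (type 7)
    return QuintileCutpoints(component=component, boundaries=tuple(q))


def quintile_of(intake, cutpoints: QuintileCutpoints, ties: str = "lower"):
    """Quintile (1-5) of an intake given the cutpoints.

    ``ties='lower'`` (default) assigns boundary-equal values to the lower
    quintile; ``ties='upper'`` to the upper one. Vectorised; NaN maps to NaN.
    """
    if ties not in ("lower", "upper"):
        raise ValueError(f"ties must be 'lower' or 'upper', got {ties!r}")
    x = np.asarray(intake, dtype=float)
    b = np.asarray(cutpoints.boundaries, dtype=float)
    cmp = np.greater if ties == "lower" else np.greater_equal
    q = 1.0 + cmp(x[..., None], b).sum(axis=-1)
    q = np.where(np.isnan(x), np.nan, q)
    return q if q.ndim else float(q)


def score_component(intake, cutpoints: QuintileCutpoints, reverse: bool = False,
                    ties: str = "lower"):
    """Points (1-5) for one component: quintile q forward, 6-q reversed.

    Missing intake yields missing points (NaN); such a record is excluded
    from any analysis needing a total score.
    """
    q = quintile_of(intake, cutpoints, ties=ties)
    return 6.0 - q if reverse else q


def compute_pds(intakes: dict, cutpoints: dict[str, QuintileCutpoints],
                ties: str = "lower") -> PdsResult:
    """Total PDS for one participant from their six component intakes."""
    points: dict[str, int] = {}
    for comp in COMPONENTS:
        if comp not in intakes or pd.isna(intakes[comp]):
            raise ValueError(f"missing intake for component {comp!r}")
        if comp not in cutpoints:
            raise ValueError(f"missing cutpoints for component {comp!r}")
        p = score_component(intakes[comp], cutpoints[comp],
                            reverse=comp in REVERSE_COMPONENTS, ties=ties)
        points[comp] = int(p)
    return PdsResult(component_points=points, total=sum(points.values()))


def score_cohort(df: pd.DataFrame, cutpoints: dict[str, QuintileCutpoints] | None = None,
                 ties: str = "lower") -> pd.DataFrame:
    """Score every row of a cohort table.

    Expects one column per component name. With ``cutpoints=None`` the
    quintiles are estimated from this sample (population mode); passing a
    cutpoints dict reproduces scores on new data ("frozen cutpoints" mode).
    Returns a DataFrame with ``points_<component>`` columns and ``pds``
    (NaN where any component intake is missing), indexed like ``df``.
    """
    if cutpoints is None:
        cutpoints = {c: estimate_cutpoints(df[c], c) for c in COMPONENTS}
    out = pd.DataFrame(index=df.index)
    for comp in COMPONENTS:
        out[f"points_{comp}"] = score_component(
            df[comp].to_numpy(dtype=float), cutpoints[comp],
            reverse=comp in REVERSE_COMPONENTS, ties=ties)
    out["pds"] = out.sum(axis=1, skipna=False)
    return out


@dataclass(frozen=True)
class TertileAssignment:
    labels: pd.Series
    boundaries: tuple[float, float]
    medians: dict[str, float] = field(default_factory=dict)
    sizes: dict[str, int] = field(default_factory=dict)


def assign_tertiles(totals) -> TertileAssignment:
    """Split total scores into sample tertiles T1/T2/T3.

    Boundaries are the 33.3/66.7th percentiles of the integer score; values
    equal to a boundary go to the lower tertile, mirroring the half-open
    quintile convention. Per-tertile median scores are reported for use as
    the continuous trend regressor.
    """
    s = pd.Series(totals, dtype=float)
    valid = s.dropna()
    if valid.size < 3:
        raise ValueError(f"need >= 3 scores to form tertiles, got {valid.size}")
    b = np.quantile(valid.to_numpy(), [1 / 3, 2 / 3])
    idx = (s.to_numpy()[:, None] > b).sum(axis=1).astype(float)
    labels = pd.Series(
        [TERTILE_LABELS[int(i)] if not np.isnan(v) else None
         for i, v in zip(idx, s.to_numpy())],
        index=s.index, dtype="object")
    medians = {t: float(valid[labels.loc[valid.index] == t].median())
               for t in TERTILE_LABELS if (labels == t).any()}
    sizes = {t: int((labels == t).sum()) for t in TERTILE_LABELS}
    return TertileAssignment(labels=labels, boundaries=(float(b[0]), float(b[1])),
                             medians=medians, sizes=sizes)


# -- cutpoint serialization ("frozen cutpoints" sidecar) ---------------------

def cutpoints_to_json(cutpoints: dict[str, QuintileCutpoints]) -> str:
    payload = {
        "format": "portfoliodiet.cutpoints/1",
        "quantile_definition": "type-7 linear interpolation, 20/40/60/80th percentiles",
        "components": {c: list(cp.boundaries) for c, cp in cutpoints.items()},
    }
    return json.dumps(payload, indent=2, sort_keys=True)


def cutpoints_from_json(text: str) -> dict[str, QuintileCutpoints]:
    payload = json.loads(text)
    return {c: QuintileCutpoints(component=c, boundaries=tuple(b))
            for c, b in payload["components"].items()}
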