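"""Regression program for score-outcome associations.

Fits the multivariable linear models relating the Portfolio Diet Score to
cardiovascular risk factors: continuous effects per 1 and per 8 score points,
tertile marginal means with a median-assignment trend test, log/sqrt outcome
transforms with back-transformation to the reporting scale, a priori subgroup
interaction tests, and per-serving regressions for individual components.

Conventions
-----------
* Outcomes analysed on a log scale (triglycerides, CRP and the adiposity
  markers) are transformed before fitting; p-values come from the transformed
  fit while marginal means are reported on the untransformed scale and the
  continuous effect is back-transformed to an absolute difference anchored at
  the untransformed sample mean, ``(exp(beta) - 1) * mean``.
* Alcohol enters as a square-root-transformed covariate (zero-heavy, so log
  is undefined).
* Marginal means are population-averaged: predictions at each tertile are
  averaged over the observed covariate distribution of the analysis sample,
  with delta-method confidence intervals on the linear predictor.
* Missing data are handled by complete-case analysis per outcome.
* BMI is never a covariate when the outcome is itself an adiposity marker.
* No multiple-testing adjustment; two-sided t-based inference at alpha 0.05.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import patsy
import scipy.linalg
import statsmodels.formula.api as smf

from . import scoring

ADIPOSITY_OUTCOMES = frozenset({"bmi", "waist", "waist_cm", "weight", "weight_kg", "fmi"})

DEFAULT_TRANSFORMS = {
    "tg": "log", "crp": "log", "bmi": "log", "waist": "log", "waist_cm": "log",
    "weight": "log", "weight_kg": "log", "fmi": "log",
}

DEFAULT_COVARIATES = (
    "sex", "age", "education", "ethnicity", "bmi", "family_cvd",
    "family_diabetes", "hypertension", "hypercholesterolemia", "energy_kcal",
    "smoking", "physical_activity", "alcohol_sqrt",
)

_CATEGORICAL = frozenset({"sex", "education", "ethnicity", "smoking", "tertile"})
_BOOLEAN = frozenset({"family_cvd", "family_diabetes", "hypertension",
                      "hypercholesterolemia"})

#: Phytosterol intakes arrive in mg/day; one serving is 25 mg.
PHYTOSTEROL_MG_PER_SERVING = 25.0


class RankDeficiencyError(ValueError):
    """Design matrix is rank deficient; message names the aliased columns."""


def default_covariates(outcome: str) -> tuple[str, ...]:
    """The standard covariate set, without BMI for adiposity outcomes."""
    if outcome in ADIPOSITY_OUTCOMES:
        return tuple(c for c in DEFAULT_COVARIATES if c != "bmi")
    return DEFAULT_COVARIATES


@dataclass(frozen=True)
class ModelSpec:
    outcome: str
    transform: str = "none"            # none | log | sqrt
    exposure: str = "pds_points"       # pds_points | pds_tertiles | component_servings
    covariates: tuple[str, ...] = ()
    subgroup: str | None = None        # sex | ethnicity | bmi_class
    component: str | None = None       # required for component_servings

    def __post_init__(self) -> None:
        if self.transform not in ("none", "log", "sqrt"):
            raise ValueError(f"unknown transform {self.transform!r}")
        if self.exposure not in ("pds_points", "pds_tertiles", "component_servings"):
            raise ValueError(f"unknown exposure {self.exposure!r}")
        if self.outcome in ADIPOSITY_OUTCOMES and "bmi" in self.covariates:
            raise ValueError(
                f"BMI may not be a covariate for adiposity outcome {self.outcome!r}")
        if self.exposure == "component_servings" and not self.component:
            raise ValueError("component_servings exposure requires a component name")


@dataclass(frozen=True)
class ModelResult:
    outcome: str
    model: str                          # unadjusted | multivariable
    beta_per_point: float | None = None
    ci95: tuple[float, float] | None = None
    p_value: float | None = None
    marginal_means: dict | None = None  # tertile -> (mean, lo, hi)
    p_trend: float | None = None
    p_interaction: float | None = None
    stratum_betas: dict | None = None
    n_used: int = 0
    transform: str = "none"
    reported_beta: float | None = None  # back-transformed, reporting scale
    reported_ci95: tuple[float, float] | None = None

    @property
    def beta_per_8(self) -> float | None:
        return None if self.beta_per_point is None else 8.0 * self.beta_per_point

    @property
    def ci95_per_8(self) -> tuple[float, float] | None:
        if self.ci95 is None:
            return None
        return (8.0 * self.ci95[0], 8.0 * self.ci95[1])


# -- data preparation ---------------------------------------------------------

def attach_scores(df: pd.DataFrame, ties: str = "lower") -> pd.DataFrame:
    """Score a cohort table and append pds, tertile and tertile-median columns."""
    out = df.copy()
    scores = scoring.score_cohort(out, ties=ties)
    out["pds"] = scores["pds"]
    tert = scoring.assign_tertiles(out["pds"])
    out["tertile"] = tert.labels
    out["tertile_median_pds"] = out["tertile"].map(tert.medians)
    return out


def _transform_series(y: pd.Series, transform: str) -> pd.Series:
    if transform == "none":
        return y
    if transform == "log":
        if (y <= 0).any():
            raise ValueError("log transform requires strictly positive outcome values")
        return np.log(y)
    if transform == "sqrt":
        if (y < 0).any():
            raise ValueError("sqrt transform requires non-negative outcome values")
        return np.sqrt(y)
    raise ValueError(f"unknown transform {transform!r}")


def _prepare(df: pd.DataFrame, columns: list[str]) -> pd.DataFrame:
    """Complete-case subset with derived covariate columns materialised."""
    work = df.copy()
    if "alcohol_sqrt" in columns and "alcohol_sqrt" not in work.columns:
        work["alcohol_sqrt"] = np.sqrt(work["alcohol_g"].astype(float))
    if "bmi_class" in columns and "bmi_class" not in work.columns:
        work["bmi_class"] = np.where(work["bmi"].astype(float) >= 25.0, "ge25", "lt25")
    for col in columns:
        if col not in work.columns:
            raise KeyError(f"column {col!r} not in cohort table")
        if col in _BOOLEAN or work[col].dtype == bool:
            work[col] = work[col].astype(float)
    return work[columns].dropna()


def _term(name: str) -> str:
    return f"C({name})" if name in _CATEGORICAL else name


def _check_full_rank(X: np.ndarray, names: list[str]) -> None:
    n, p = X.shape
    _, r, piv = scipy.linalg.qr(X, mode="economic", pivoting=True)
    diag = np.abs(np.diag(r))
    tol = (diag.max() if diag.size else 0.0) * max(n, p) * np.finfo(float).eps
    bad = [names[j] for j, d in zip(piv, diag) if d <= tol]
    bad += [names[j] for j in piv[min(n, p):]]
    if bad:
        raise RankDeficiencyError(f"design matrix is rank deficient; aliased columns: {bad}")


def _ols(formula: str, data: pd.DataFrame):
    y, X = patsy.dmatrices(formula, data, return_type="dataframe")
    if len(data) <= X.shape[1] + 1:
        raise ValueError(
            f"too few observations (n={len(data)}) for {X.shape[1]} parameters")
    _check_full_rank(X.to_numpy(), list(X.columns))
    return smf.ols(formula, data=data).fit()


# -- core operations ----------------------------------------------------------

def fit_linear(spec: ModelSpec, df: pd.DataFrame) -> ModelResult:
    """OLS fit of a (possibly transformed) outcome on the chosen exposure.

    For continuous exposures the result carries the per-point slope, its 95%
    CI and two-sided t-based p-value, plus the per-8-point rescaling and, for
    log/sqrt outcomes, the back-transformed effect anchored at the
    untransformed sample mean.
    """
    if spec.exposure == "pds_points":
        exposure_col = "pds"
    elif spec.exposure == "component_servings":
        exposure_col = "_servings"
    else:
        exposure_col = "tertile"
    needed = [spec.outcome, exposure_col if exposure_col != "_servings" else spec.component]
    needed += [c for c in spec.covariates]
    work = _prepare(df, list(dict.fromkeys(needed)))
    if spec.exposure == "component_servings":
        x = work[spec.component].astype(float)
        if spec.component == "phytosterols":
            x = x / PHYTOSTEROL_MG_PER_SERVING
        work["_servings"] = x
    work["_y"] = _transform_series(work[spec.outcome].astype(float), spec.transform)

    rhs = " + ".join([_term(exposure_col)] + [_term(c) for c in spec.covariates]) or "1"
    res = _ols(f"_y ~ {rhs}", work)

    result = ModelResult(
        outcome=spec.outcome,
        model="multivariable" if spec.covariates else "unadjusted",
        n_used=int(res.nobs), transform=spec.transform)
    if exposure_col != "tertile":
        beta = float(res.params[exposure_col])
        lo, hi = (float(v) for v in res.conf_int().loc[exposure_col])
        p = float(res.pvalues[exposure_col])
        raw_mean = float(work[spec.outcome].mean())
        rep, rep_ci = back_transform(beta, spec.transform, raw_mean, ci=(lo, hi))
        result = ModelResult(
            outcome=spec.outcome, model=result.model, beta_per_point=beta,
            ci95=(lo, hi), p_value=p, n_used=int(res.nobs),
            transform=spec.transform, reported_beta=rep, reported_ci95=rep_ci)
    result.__dict__["_fit"] = res  # fitted statsmodels results, for diagnostics
    return result


def back_transform(beta: float, transform: str, raw_mean: float,
                   ci: tuple[float, float] | None = None):
    """Convert a transformed-scale slope to the reporting scale.

    log:  absolute difference per point = (exp(beta) - 1) * untransformed mean
    sqrt: delta-method difference = 2 * sqrt(untransformed mean) * beta
    none: identity.
    P-values always remain those of the transformed fit.
    """
    if transform == "none":
        f = lambda b: b
    elif transform == "log":
        f = lambda b: float(np.expm1(b) * raw_mean)
    elif transform == "sqrt":
        f = lambda b: float(2.0 * np.sqrt(raw_mean) * b)
    else:
        raise ValueError(f"unknown transform {transform!r}")
    out = f(beta)
    if ci is None:
        return out, None
    return out, (f(ci[0]), f(ci[1]))


def marginal_means(df: pd.DataFrame, outcome: str,
                   covariates: tuple[str, ...] = (),
                   tertile_col: str = "tertile") -> tuple[dict, int]:
    """Population-averaged tertile means of the untransformed outcome.

    Fits ``outcome ~ C(tertile) + covariates`` on the raw scale, predicts for
    every analysis-sample row with the tertile forced to each level, averages,
    and attaches delta-method 95% CIs. Returns ({tertile: (mean, lo, hi)}, n).
    """
    cols = list(dict.fromkeys([outcome, tertile_col, *covariates]))
    work = _prepare(df, cols)
    work["_y"] = work[outcome].astype(float)
    rhs = " + ".join([_term(tertile_col)] + [_term(c) for c in covariates])
    res = _ols(f"_y ~ {rhs}", work)
    design_info = res.model.data.design_info
    means = {}
    for t in scoring.TERTILE_LABELS:
        cf = work.copy()
        cf[tertile_col] = t
        (X,) = patsy.build_design_matrices([design_info], cf)
        gbar = np.asarray(X).mean(axis=0)
        tt = res.t_test(gbar)
        lo, hi = (float(v) for v in np.ravel(tt.conf_int()))
        means[t] = (float(np.ravel(tt.effect)[0]), lo, hi)
    return means, int(res.nobs)


def trend_test(df: pd.DataFrame, outcome: str, transform: str = "none",
               covariates: tuple[str, ...] = (), tertile_col: str = "tertile",
               tertile_medians: dict[str, float] | None = None) -> float:
    """Median-assignment test for linear trend across tertiles.

    Each participant's tertile is replaced by the tertile's median score,
    entered as a continuous regressor; the returned p-value is that
    coefficient's two-sided t-test from the transformed-outcome fit.
    """
    cols = list(dict.fromkeys([outcome, tertile_col, *covariates]))
    if tertile_medians is None and "tertile_median_pds" in df.columns:
        cols.append("tertile_median_pds")
    work = _prepare(df, cols)
    if tertile_medians is not None:
        unknown = set(work[tertile_col].unique()) - set(tertile_medians)
        if unknown:
            raise ValueError(f"no median supplied for tertiles {sorted(unknown)}")
        work["_trend"] = work[tertile_col].map(tertile_medians).astype(float)
    else:
        work["_trend"] = work["tertile_median_pds"].astype(float)
    if work["_trend"].nunique() < 2:
        raise ValueError("degenerate tertile structure: all records in one tertile")
    work["_y"] = _transform_series(work[outcome].astype(float), transform)
    rhs = " + ".join(["_trend"] + [_term(c) for c in covariates])
    res = _ols(f"_y ~ {rhs}", work)
    return float(res.pvalues["_trend"])


def interaction_test(df: pd.DataFrame, outcome: str, subgroup: str,
                     transform: str = "none",
                     covariates: tuple[str, ...] = ()) -> tuple[float, dict]:
    """Joint F-test of PDS x subgroup product terms plus per-stratum slopes.

    The covariate set should not repeat the subgroup variable. Returns
    (p_interaction, {stratum: (beta, lo, hi, n)}).
    """
    covs = tuple(c for c in covariates if c != subgroup)
    cols = list(dict.fromkeys([outcome, "pds", subgroup, *covs]))
    work = _prepare(df, cols)
    strata = sorted(work[subgroup].astype(str).unique())
    if len(strata) < 2:
        raise ValueError(f"subgroup {subgroup!r} has a single stratum: {strata}")
    work["_y"] = _transform_series(work[outcome].astype(float), transform)

    base_rhs = " + ".join(["pds", _term(subgroup)] + [_term(c) for c in covs])
    full_rhs = base_rhs + f" + pds:{_term(subgroup)}"
    res_base = _ols(f"_y ~ {base_rhs}", work)
    res_full = _ols(f"_y ~ {full_rhs}", work)
    f_stat, p_inter, _ = res_full.compare_f_test(res_base)

    stratum_betas = {}
    for s in strata:
        sub = work[work[subgroup].astype(str) == s]
        n_params = 2 + len(covs)  # rough floor before categorical expansion
        if len(sub) <= n_params:
            raise ValueError(f"stratum {s!r} of {subgroup!r} too small (n={len(sub)})")
        rhs = " + ".join(["pds"] + [_term(c) for c in covs]) or "pds"
        res_s = _ols(f"_y ~ {rhs}", sub)
        lo, hi = (float(v) for v in res_s.conf_int().loc["pds"])
        stratum_betas[s] = (float(res_s.params["pds"]), lo, hi, int(res_s.nobs))
    return float(p_inter), stratum_betas


def component_regression(df: pd.DataFrame, component: str, outcome: str,
                         transform: str = "none",
                         covariates: tuple[str, ...] = ()) -> ModelResult:
    """Per-serving effect of one diet component (phytosterols: mg/day / 25)."""
    spec = ModelSpec(outcome=outcome, transform=transform,
                     exposure="component_servings", covariates=covariates,
                     component=component)
    return fit_linear(spec, df)


# -- Table-2-style consolidated results ---------------------------------------

def results_table(df: pd.DataFrame, outcomes: dict[str, str] | None = None,
                  covariates: tuple[str, ...] | None = None) -> pd.DataFrame:
    """Unadjusted and multivariable rows per outcome in a tidy CSV-able layout.

    ``outcomes`` maps outcome column -> transform; defaults to the standard
    panel with the standard transforms. The cohort table must already carry
    ``pds``/``tertile``/``tertile_median_pds`` columns (see
    :func:`attach_scores`).
    """
    if outcomes is None:
        candidates = ("ldl_nih", "non_hdl", "tc", "hdl", "tg", "crp", "glucose",
                      "sbp", "dbp", "bmi", "weight_kg", "fmi")
        outcomes = {c: DEFAULT_TRANSFORMS.get(c, "none")
                    for c in candidates if c in df.columns}
    rows = []
    for outcome, transform in outcomes.items():
        covs = covariates if covariates is not None else default_covariates(outcome)
        covs = tuple(c for c in covs if c != outcome)
        for label, use_covs in (("unadjusted", ()), ("multivariable", covs)):
            cont = fit_linear(ModelSpec(outcome=outcome, transform=transform,
                                        covariates=use_covs), df)
            means, _ = marginal_means(df, outcome, use_covs)
            p_tr = trend_test(df, outcome, transform, use_covs)
            rows.append({
                "outcome": outcome, "model": label, "n": cont.n_used,
                **{f"{t}_{k}": v for t in scoring.TERTILE_LABELS
                   for k, v in zip(("mean", "lo", "hi"), means[t])},
                "p_trend": p_tr,
                "beta_per_point": cont.beta_per_point,
                "beta_lo": cont.ci95[0], "beta_hi": cont.ci95[1],
                "beta_per_8": cont.beta_per_8,
                "beta8_lo": cont.ci95_per_8[0], "beta8_hi": cont.ci95_per_8[1],
                "p_value": cont.p_value,
                "reported_beta": cont.reported_beta,
                "transform": transform,
            })
    return pd.DataFrame(rows)
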