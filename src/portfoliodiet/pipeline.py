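"""End-to-end orchestration: generate -> ingest -> score -> model -> exposure.

A run is fully determined by a :class:`RunConfig`; all randomness flows from
its root seed through named substreams, one per stage, so any stage can be
re-run from its serialized inputs and reproduce its outputs bit-identically.
Artifacts are plain text (CSV/JSON/YAML) plus a manifest recording the seed,
a hash of the resolved configuration, and library versions.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .exposure import (DEFAULT_THRESHOLD_MMOL_YEARS, cohort_adherence,
                       exposure_report, trajectory_table)
from .ingest import ExclusionPolicy, apply_exclusions, derive_biomarkers
from .models import attach_scores, results_table
from .scoring import COMPONENTS, cutpoints_to_json, estimate_cutpoints
from .synthetic import CohortConfig, ConfigError, generate_cohort

logger = logging.getLogger("portfoliodiet")


class PipelineError(RuntimeError):
    """A stage failed; message names the stage and the cause."""


@dataclass(frozen=True)
class ExposureSettings:
    """Anchors default to None: derived from the scored cohort (overall
    adherence % and unadjusted marginal mean LDL-C in T1/T3)."""

    anchors: tuple[tuple[float, float], tuple[float, float]] | None = None
    threshold_mmol_years: float = DEFAULT_THRESHOLD_MMOL_YEARS
    adherence_levels: tuple[float, ...] = (50.0, 100.0)
    ages: tuple[float, ...] = tuple(float(a) for a in range(0, 91, 1))


@dataclass(frozen=True)
class RunConfig:
    cohort: CohortConfig = field(default_factory=CohortConfig)
    exclusions: ExclusionPolicy = field(default_factory=ExclusionPolicy)
    outcomes: dict | None = None    # outcome column -> transform; None = default panel
    exposure: ExposureSettings = field(default_factory=ExposureSettings)
    output_dir: str = "portfoliodiet_run"
    seed: int = 0


def stage_seed(root_seed: int, stage: str) -> int:
    """Deterministic per-stage substream seed (< 2**31) from the root seed."""
    entropy = int.from_bytes(hashlib.sha256(stage.encode()).digest()[:4], "big")
    return int(np.random.SeedSequence([root_seed, entropy]).generate_state(1)[0] % 2**31)


def config_hash(config: RunConfig) -> str:
    """Hash of the scientific configuration (the output location is excluded)."""
    payload = dataclasses.asdict(config)
    payload.pop("output_dir", None)
    return hashlib.sha256(
        yaml.safe_dump(payload, sort_keys=True).encode()).hexdigest()[:16]


def config_to_yaml(config: RunConfig) -> str:
    return yaml.safe_dump(dataclasses.asdict(config), sort_keys=True)


def validate_config(config: RunConfig) -> list[str]:
    """Every violated invariant, with its field path; empty list means valid."""
    errors: list[str] = []
    try:
        config.cohort.validate()
    except ConfigError as exc:
        errors.append(f"cohort: {exc}")
    try:
        ExclusionPolicy(max_kcal_female=config.exclusions.max_kcal_female,
                        max_kcal_male=config.exclusions.max_kcal_male,
                        min_kcal=config.exclusions.min_kcal)
    except ValueError as exc:
        errors.append(f"exclusions: {exc}")
    exp = config.exposure
    if exp.anchors is not None and exp.anchors[0][0] == exp.anchors[1][0]:
        errors.append("exposure.anchors: anchor adherence percentages must differ")
    if exp.threshold_mmol_years <= 0:
        errors.append("exposure.threshold_mmol_years: must be > 0")
    if not isinstance(config.seed, (int, np.integer)):
        errors.append("seed: must be an integer")
    return errors


def run_pipeline(config: RunConfig | None = None) -> dict:
    """Execute all stages; returns artifact paths and key in-memory tables."""
    config = config or RunConfig()
    errs = validate_config(config)
    if errs:
        raise PipelineError("stage validate_config: " + "; ".join(errs))

    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    artifacts: dict = {"output_dir": str(out)}

    def stage(name, fn):
        logger.info("stage %s", name)
        try:
            return fn()
        except Exception as exc:
            raise PipelineError(f"stage {name}: {exc}") from exc

    # generate
    cohort_cfg = dataclasses.replace(config.cohort,
                                     seed=stage_seed(config.seed, "generate"))
    cohort = stage("generate", lambda: generate_cohort(cohort_cfg))
    cohort.to_csv(out / "cohort.csv", index=False)
    (out / "config.yaml").write_text(config_to_yaml(config))

    # ingest
    def _ingest():
        retained, ledger = apply_exclusions(cohort, config.exclusions)
        return derive_biomarkers(retained), ledger
    analysed, ledger = stage("ingest", _ingest)
    (out / "exclusions.json").write_text(json.dumps(ledger, indent=2))

    # score
    def _score():
        scored = attach_scores(analysed)
        cutpoints = {c: estimate_cutpoints(analysed[c], c) for c in COMPONENTS}
        return scored, cutpoints
    scored, cutpoints = stage("score", _score)
    (out / "cutpoints.json").write_text(cutpoints_to_json(cutpoints))
    score_cols = ["id", "pds", "tertile", "tertile_median_pds"]
    scored[score_cols].to_csv(out / "scores.csv", index=False)

    # model
    results = stage("analyze", lambda: results_table(scored, config.outcomes))
    results.to_csv(out / "results.csv", index=False)

    # exposure
    def _exposure():
        adher = cohort_adherence(scored)
        if config.exposure.anchors is not None:
            # explicit anchors define the tertile LDL-C levels too
            anchors = config.exposure.anchors
            tertile_ldl = {"T1": anchors[0][1], "T3": anchors[1][1]}
        else:
            mm = {t: float(results.loc[(results["outcome"] == "ldl_nih")
                                       & (results["model"] == "unadjusted"),
                                       f"{t}_mean"].iloc[0])
                  for t in ("T1", "T2", "T3")}
            pct = adher.set_index("tertile")["overall_pct"]
            anchors = ((float(pct["T1"]), mm["T1"]), (float(pct["T3"]), mm["T3"]))
            tertile_ldl = mm
        report = exposure_report(anchors=anchors, tertile_levels=tertile_ldl,
                                 adherence_levels=config.exposure.adherence_levels,
                                 threshold=config.exposure.threshold_mmol_years)
        levels = dict(zip(report["level"], report["ldl_mmol_l"]))
        traj = trajectory_table(levels, config.exposure.ages,
                                threshold=config.exposure.threshold_mmol_years)
        return adher, anchors, report, traj
    adher, anchors, report, traj = stage("exposure", _exposure)
    adher.to_csv(out / "adherence.csv", index=False)
    report.to_csv(out / "exposure.csv", index=False)
    traj.to_csv(out / "trajectory.csv", index=False)

    manifest = {
        "package": "portfoliodiet",
        "version": __version__,
        "seed": int(config.seed),
        "stage_seeds": {"generate": stage_seed(config.seed, "generate")},
        "config_hash": config_hash(config),
        "anchors": [list(a) for a in anchors],
        "threshold_mmol_years": config.exposure.threshold_mmol_years,
        "n_input": ledger["n_input"],
        "n_retained": ledger["n_retained"],
        "lib_versions": {"numpy": np.__version__, "pandas": pd.__version__},
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))

    artifacts.update({
        "cohort": cohort, "ledger": ledger, "scored": scored, "results": results,
        "adherence": adher, "exposure": report, "trajectory": traj,
        "manifest": manifest,
        "paths": {name: str(out / f"{name}.csv") for name in
                  ("cohort", "scores", "results", "adherence", "exposure", "trajectory")},
    })
    return artifacts
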