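"""Config-driven orchestration of the full bidirectional analysis grid.

One run covers sexes x exposure contrasts x both causal directions
(substance use as mediator of depression, and depression as mediator of
substance use), applies the respondent exclusion flow, per-cell listwise
deletion, point estimation and the percentile bootstrap, and writes
results tables, a descriptives table and a JSON run manifest.

Exposure contrasts follow the study conventions:

* ``lifetime`` — any lifetime sexual-assault experience vs none;
* ``childhood`` — childhood event vs no lifetime event (respondents with a
  non-childhood lifetime event are dropped from the contrast);
* ``repeated`` — more than one event vs no lifetime event (single-event
  respondents are dropped; repeated-vs-single is deliberately not offered).
"""

from __future__ import annotations

import json
import logging
import sys
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .bootstrap import BootstrapConfig, bootstrap_mediation
from .cohort import (AGE_LEVELS, CHILDHOOD, DEPRESSION, EDU_LEVELS, EXPOSURE,
                     REPEATED, SUBSTANCES, VARIABLES, default_params,
                     generate_cohort, inject_missingness, read_cohort)
from .descriptives import apply_exclusion_flow, prevalence_table
from .design import SurveyDesign
from .errors import EstimationError, InputError
from .mediation import MediationSpec, proportion_mediated

logger = logging.getLogger(__name__)

CONTRASTS = ("lifetime", "childhood", "repeated")
DIRECTIONS = ("substance_mediator", "depression_mediator")


@dataclass
class AnalysisConfig:
    """Declarative description of a full analysis run."""

    input_csv: str | None = None
    simulate_n: int = 20000
    seed: int = 42
    sexes: tuple[str, ...] = ("female", "male")
    contrasts: tuple[str, ...] = ("lifetime", "childhood")
    substances: tuple[str, ...] = SUBSTANCES
    directions: tuple[str, ...] = DIRECTIONS
    include_interaction: bool = True
    covariate_evaluation: str = "weighted_mean"
    replicates: int = 1000
    resampling: str = "psu-within-stratum"
    min_success_fraction: float = 0.95
    out_dir: str = "survmediate_out"
    quiet: bool = False

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "AnalysisConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        raw.update(overrides)
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise InputError(f"unknown config keys: {sorted(unknown)}")
        for key in ("sexes", "contrasts", "substances", "directions"):
            if key in raw and isinstance(raw[key], list):
                raw[key] = tuple(raw[key])
        return cls(**raw)


@dataclass
class ValidationReport:
    """Findings from config validation; fatal findings block ``run_grid``."""

    findings: list[tuple[str, str]] = field(default_factory=list)

    def add(self, level: str, message: str) -> None:
        self.findings.append((level, message))

    @property
    def fatal(self) -> bool:
        return any(level == "fatal" for level, _ in self.findings)


def validate_config(config: AnalysisConfig,
                    cohort: pd.DataFrame | None = None) -> ValidationReport:
    """Check a config (and optionally the cohort it will run on)."""
    report = ValidationReport()
    if not config.substances:
        report.add("fatal", "substance (mediator) list is empty")
    for s in config.substances:
        if s not in SUBSTANCES:
            report.add("fatal", f"unknown substance column {s!r}")
    for sex in config.sexes:
        if sex not in ("female", "male"):
            report.add("fatal", f"unknown sex label {sex!r}")
    for contrast in config.contrasts:
        if contrast not in CONTRASTS:
            report.add("fatal", f"unknown exposure contrast {contrast!r}")
    for direction in config.directions:
        if direction not in DIRECTIONS:
            report.add("fatal", f"unknown direction {direction!r}")
    if DEPRESSION in config.substances:
        report.add("fatal", "depression cannot be both mediator and outcome")
    if config.replicates < 2:
        report.add("fatal", "bootstrap replicates must be >= 2")
    if config.input_csv is not None and cohort is not None:
        needed = ([EXPOSURE, "sae_recent", "sex", "age_group", "education",
                   "weight", "stratum", "psu", DEPRESSION]
                  + list(config.substances))
        if "childhood" in config.contrasts:
            needed.append(CHILDHOOD)
        if "repeated" in config.contrasts:
            needed.append(REPEATED)
        for col in needed:
            if col not in cohort.columns:
                report.add("fatal", f"column {col!r} missing from input")
    if not report.findings:
        logger.debug("config valid with defaults applied")
    return report


def select_contrast(cohort: pd.DataFrame, contrast: str
                    ) -> tuple[pd.DataFrame, str]:
    """Subset a cohort to one exposure contrast; returns (table, exposure
    column to model)."""
    if contrast == "lifetime":
        return cohort, EXPOSURE
    if contrast == "childhood":
        keep = ~((cohort[EXPOSURE] == 1) & (cohort[CHILDHOOD] != 1))
        return cohort[keep], CHILDHOOD
    if contrast == "repeated":
        keep = ~((cohort[EXPOSURE] == 1) & (cohort[REPEATED] != 1))
        return cohort[keep], REPEATED
    raise InputError(f"unknown exposure contrast {contrast!r}")


def _simulated_cohorts(config: AnalysisConfig
                       ) -> dict[tuple[str, str], pd.DataFrame]:
    """One cohort per (sex, substance), carrying that substance and
    depression alongside the exposure columns."""
    cohorts: dict[tuple[str, str], pd.DataFrame] = {}
    offset = 0
    for sex in config.sexes:
        for substance in config.substances:
            # stable per-cell seeds below 2**31, derived from the run seed
            cell_seed = int((config.seed * 1000003 + offset * 7919)
                            % (2 ** 31 - 1))
            offset += 1
            params = default_params(sex, mediator=substance,
                                    outcome=DEPRESSION)
            table, _ = generate_cohort(params, config.simulate_n, cell_seed)
            table = inject_missingness(table, params.missing_rates,
                                       seed=cell_seed + 1)
            cohorts[(sex, substance)] = table
    return cohorts


def run_grid(config: AnalysisConfig) -> list[dict]:
    """Execute the full analysis grid and write outputs to
    ``config.out_dir``.

    Returns the list of per-cell result records. Cells that fail hard are
    recorded in the manifest and do not stop the remaining cells.
    """
    report = validate_config(config)
    if report.fatal:
        raise InputError("config validation failed: "
                         + "; ".join(m for lv, m in report.findings
                                     if lv == "fatal"))
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    design = SurveyDesign()

    if config.input_csv is not None:
        raw = read_cohort(config.input_csv)
        check = validate_config(config, raw)
        if check.fatal:
            raise InputError("input validation failed: "
                             + "; ".join(m for lv, m in check.findings))
        cohorts = {(sex, substance): raw[raw["sex"] == sex]
                   for sex in config.sexes
                   for substance in config.substances}
    else:
        cohorts = _simulated_cohorts(config)

    results: list[dict] = []
    errors: list[dict] = []
    exclusions: dict[str, dict] = {}
    cell_index = 0
    for sex in config.sexes:
        for substance in config.substances:
            cohort = cohorts[(sex, substance)]
            cohort, excl = apply_exclusion_flow(cohort)
            exclusions[f"{sex}/{substance}"] = asdict(excl)
            for contrast in config.contrasts:
                subset, exposure_col = select_contrast(cohort, contrast)
                for direction in config.directions:
                    if direction == "substance_mediator":
                        mediator, outcome = substance, DEPRESSION
                    else:
                        mediator, outcome = DEPRESSION, substance
                    cell = dict(sex=sex, contrast=contrast,
                                direction=direction, mediator=mediator,
                                outcome=outcome)
                    if not config.quiet:
                        print(f"[survmediate] cell {cell_index}: {cell}",
                              file=sys.stderr)
                    spec = MediationSpec(
                        exposure=exposure_col, mediator=mediator,
                        outcome=outcome,
                        include_interaction=config.include_interaction,
                        covariate_evaluation=config.covariate_evaluation)
                    boot = BootstrapConfig(
                        n_replicates=config.replicates,
                        seed=int((config.seed * 99991 + cell_index * 104729)
                                 % (2 ** 31 - 1)),
                        resampling=config.resampling,
                        min_success_fraction=config.min_success_fraction)
                    try:
                        est = bootstrap_mediation(subset, spec, design, boot)
                    except (EstimationError, InputError) as exc:
                        errors.append({**cell, "error": str(exc)})
                        cell_index += 1
                        continue
                    results.append({
                        **cell,
                        "or_te": est.or_te, "ci_te_low": est.ci_te[0],
                        "ci_te_high": est.ci_te[1],
                        "or_nde": est.or_nde, "ci_nde_low": est.ci_nde[0],
                        "ci_nde_high": est.ci_nde[1],
                        "or_nie": est.or_nie, "ci_nie_low": est.ci_nie[0],
                        "ci_nie_high": est.ci_nie[1],
                        "pm_percent": (100.0 * est.pm if est.pm_defined
                                       else float("nan")),
                        "n_used": est.n_used,
                        "n_bootstrap_ok": est.n_bootstrap_ok,
                    })
                    cell_index += 1

    frame = pd.DataFrame(results)
    for direction in config.directions:
        sub = (frame[frame["direction"] == direction]
               if len(frame) else frame)
        sub.to_csv(out_dir / f"results_{direction}.csv", index=False)

    desc_rows = []
    for (sex, substance), cohort in cohorts.items():
        cohort, _ = apply_exclusion_flow(cohort)
        variables = {"age_group": list(AGE_LEVELS),
                     "education": list(EDU_LEVELS),
                     EXPOSURE: None, substance: None, DEPRESSION: None}
        table = prevalence_table(cohort, variables, design)
        table.insert(0, "sex", sex)
        table.insert(1, "cohort", substance)
        desc_rows.append(table)
    pd.concat(desc_rows, ignore_index=True).to_csv(
        out_dir / "descriptives.csv", index=False)

    manifest = {
        "package_version": __version__,
        "numpy_version": np.__version__,
        "pandas_version": pd.__version__,
        "config": {k: (list(v) if isinstance(v, tuple) else v)
                   for k, v in asdict(config).items()},
        "exclusions": exclusions,
        "cells_completed": len(results),
        "cell_errors": errors,
        "per_cell_n": {f"{r['sex']}/{r['contrast']}/{r['direction']}/"
                       f"{r['mediator']}->{r['outcome']}": r["n_used"]
                       for r in results},
    }
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return results


def render_pm_percent(or_nie: float, or_te: float) -> float:
    """Proportion mediated as the percentage the results tables print
    (one decimal)."""
    return round(100.0 * proportion_mediated(or_nie, or_te), 1)
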