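"""Percentile-bootstrap confidence intervals honouring the survey design.

The default resampling unit is the primary sampling unit: within each
stratum, PSUs are drawn with replacement up to the original PSU count and
carry all their member records and weights. An i.i.d. row bootstrap is
available as an alternative. Replicate random streams are derived from
``(seed, replicate_index)``, so a replicate's resample does not depend on
execution order.

Intervals are plain percentile intervals (empirical 2.5th/97.5th percentiles
at the 95% level) with linear interpolation between order statistics.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .design import SurveyDesign
from .errors import EstimationError, InputError
from .mediation import MediationEstimate, MediationProblem, MediationSpec

logger = logging.getLogger(__name__)

PSU_WITHIN_STRATUM = "psu-within-stratum"
IID_ROWS = "iid-rows"


@dataclass(frozen=True)
class BootstrapConfig:
    """Bootstrap settings.

    ``min_success_fraction`` is the smallest fraction of replicates that may
    survive (non-convergence, separation and empty-class replicates are
    dropped) before interval estimation refuses to proceed.
    """

    n_replicates: int = 1000
    seed: int = 0
    resampling: str = PSU_WITHIN_STRATUM
    min_success_fraction: float = 0.95
    level: float = 0.95

    def __post_init__(self) -> None:
        if self.n_replicates < 2:
            raise InputError("n_replicates must be >= 2")
        if not 0.0 < self.min_success_fraction <= 1.0:
            raise InputError("min_success_fraction must be in (0, 1]")
        if not 0.0 < self.level < 1.0:
            raise InputError("level must be in (0, 1)")
        if self.resampling not in (PSU_WITHIN_STRATUM, IID_ROWS):
            raise InputError(
                f"resampling must be {PSU_WITHIN_STRATUM!r} or {IID_ROWS!r}")


def replicate_rng(seed: int, replicate_index: int) -> np.random.Generator:
    """The random stream of one replicate; independent of execution order."""
    return np.random.default_rng(
        np.random.SeedSequence(entropy=seed, spawn_key=(replicate_index,)))


class _ClusterIndex:
    """Row indices grouped by (stratum, PSU), built once per dataset."""

    def __init__(self, strata: np.ndarray, psus: np.ndarray):
        frame = pd.DataFrame({"stratum": strata, "psu": psus})
        self.groups: list[tuple[object, list[np.ndarray]]] = []
        for stratum, sub in frame.groupby("stratum", sort=True,
                                          observed=True):
            arrays = [np.asarray(idx.to_numpy())
                      for _, idx in sub.groupby("psu", sort=True,
                                                observed=True).groups.items()]
            arrays = [np.sort(a) for a in arrays]
            self.groups.append((stratum, arrays))
        self.singletons = [s for s, arrs in self.groups if len(arrs) == 1]
        if self.singletons:
            logger.info(
                "strata with a single PSU fall back to iid resampling "
                "within stratum: %s", self.singletons)

    def resample(self, rng: np.random.Generator) -> np.ndarray:
        picked: list[np.ndarray] = []
        for _stratum, arrays in self.groups:
            k = len(arrays)
            if k == 1:
                rows = arrays[0]
                picked.append(rng.choice(rows, size=len(rows), replace=True))
                continue
            for j in rng.integers(0, k, size=k):
                picked.append(arrays[j])
        return np.concatenate(picked)


def resample(cohort: pd.DataFrame, design: SurveyDesign,
             config: BootstrapConfig, replicate_index: int) -> pd.DataFrame:
    """One bootstrap resample of ``cohort``; deterministic given
    ``(config.seed, replicate_index)``."""
    design.validate(cohort)
    rng = replicate_rng(config.seed, replicate_index)
    if config.resampling == IID_ROWS:
        idx = rng.integers(0, len(cohort), size=len(cohort))
    else:
        index = _ClusterIndex(cohort[design.stratum].to_numpy(),
                              cohort[design.psu].to_numpy())
        idx = index.resample(rng)
    return cohort.iloc[idx].reset_index(drop=True)


def percentile_ci(replicate_values, level: float = 0.95
                  ) -> tuple[float, float]:
    """Empirical percentile interval with linear interpolation.

    Raises :class:`EstimationError` with fewer than two finite values.
    """
    values = np.asarray(replicate_values, dtype=float)
    finite = values[np.isfinite(values)]
    if len(finite) < 2:
        raise EstimationError(
            f"too few finite replicate values ({len(finite)}) for a "
            "percentile interval")
    alpha = 100.0 * (1.0 - level) / 2.0
    lo, hi = np.percentile(finite, [alpha, 100.0 - alpha],
                           method="linear")
    return float(lo), float(hi)


def ci_excludes_one(ci: tuple[float, float]) -> bool:
    """Significance flag for an odds-ratio CI: True iff 1 lies outside."""
    lo, hi = ci
    return not (lo <= 1.0 <= hi)


def bootstrap_mediation(cohort: pd.DataFrame, spec: MediationSpec,
                        design: SurveyDesign,
                        config: BootstrapConfig) -> MediationEstimate:
    """Point estimate plus percentile CIs for one mediation cell.

    The point estimate is computed on the full data (and must succeed);
    each replicate re-runs the complete estimation — listwise-deleted rows
    resampled by cluster, both logistic fits (warm-started at the full-data
    coefficients), effect combination and proportion mediated. Replicates
    failing with separation, non-convergence or an empty class are dropped
    and tallied; if fewer than ``min_success_fraction`` survive an
    :class:`EstimationError` naming the tally is raised.
    """
    problem = MediationProblem(cohort, spec, design)
    point, beta_m, beta_o = problem.estimate(strict_separation=True)

    if config.resampling == IID_ROWS:
        cluster_index = None
    else:
        cluster_index = _ClusterIndex(problem.strata, problem.psus)
    n = problem.n_used
    failures: Counter[str] = Counter()
    reps = {"te": [], "nde": [], "nie": [], "pm": []}
    for i in range(config.n_replicates):
        rng = replicate_rng(config.seed, i)
        if cluster_index is None:
            idx = rng.integers(0, n, size=n)
        else:
            idx = cluster_index.resample(rng)
        try:
            est, _, _ = problem.estimate(idx, start_m=beta_m, start_o=beta_o,
                                         strict_separation=True)
        except EstimationError as exc:
            failures[str(exc)] += 1
            continue
        reps["te"].append(est.or_te)
        reps["nde"].append(est.or_nde)
        reps["nie"].append(est.or_nie)
        reps["pm"].append(est.pm)
    n_ok = len(reps["te"])
    if n_ok < config.min_success_fraction * config.n_replicates:
        raise EstimationError(
            f"only {n_ok}/{config.n_replicates} bootstrap replicates "
            f"succeeded (minimum fraction {config.min_success_fraction}); "
            f"failure tally: {dict(failures)}")
    point.ci_te = percentile_ci(reps["te"], config.level)
    point.ci_nde = percentile_ci(reps["nde"], config.level)
    point.ci_nie = percentile_ci(reps["nie"], config.level)
    pm_finite = np.asarray(reps["pm"], dtype=float)
    pm_finite = pm_finite[np.isfinite(pm_finite)]
    if point.pm_defined and len(pm_finite) >= max(
            2, int(config.min_success_fraction * n_ok)):
        point.ci_pm = percentile_ci(pm_finite, config.level)
    point.n_bootstrap_ok = n_ok
    point.meta.update({
        "resampling": config.resampling,
        "n_replicates": config.n_replicates,
        "seed": config.seed,
        "level": config.level,
        "percentile_definition": "linear interpolation between order statistics",
        "replicate_failures": dict(failures),
    })
    return point
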